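import numpy as np
import pytest

from panselect.alignment import GeneAlignment


def make_alignment(rows, outgroup, gene_id="toy", population="pop", **kwargs):
    """Alignment from string haplotypes, e.g. make_alignment(["AA","AG"], "AA")."""
    hap = np.array([list(r) for r in rows], dtype="S1")
    out = np.array(list(outgroup), dtype="S1")
    return GeneAlignment(
        gene_id=gene_id,
        population=population,
        haplotypes=hap,
        outgroup=out,
        positions=np.arange(hap.shape[1]),
        **kwargs,
    )


def alignment_from_derived_counts(counts, n, gene_id="toy"):
    """n-haplotype alignment with one derived-G column per requested count;
    outgroup carries the ancestral A everywhere."""
    S = len(counts)
    hap = np.full((n, S), b"A", dtype="S1")
    for j, k in enumerate(counts):
        hap[:k, j] = b"G"
    return GeneAlignment(
        gene_id=gene_id,
        population="pop",
        haplotypes=hap,
        outgroup=np.full(S, b"A", dtype="S1"),
        positions=np.arange(S),
    )


def random_alignment(rng, n=6, L=30, p_var=0.4, p_gap=0.05, p_missing=0.05):
    """Random messy alignment exercising all column classes."""
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    hap = np.empty((n, L), dtype="S1")
    for j in range(L):
        k = rng.choice([1, 2, 2, 3], p=[1 - p_var, p_var * 0.4, p_var * 0.4, p_var * 0.2])
        alleles = rng.choice(4, size=k, replace=False)
        hap[:, j] = bases[rng.choice(alleles, size=n)]
    gaps = rng.random((n, L)) < p_gap
    hap[gaps] = b"-"
    miss = rng.random((n, L)) < p_missing
    hap[miss] = b"N"
    out = bases[rng.integers(0, 4, size=L)]
    return GeneAlignment(
        gene_id="rand", population="pop", haplotypes=hap, outgroup=out, positions=np.arange(L)
    )


@pytest.fixture
def toy_pi_alignment():
    """Four haplotypes over two sites; mean pairwise differences 8/6."""
    return make_alignment(["AA", "AG", "GA", "GG"], "AA")


@pytest.fixture
def fuli_toy_alignment():
    """n=4, four polarized sites with derived counts 1,1,2,3."""
    return alignment_from_derived_counts([1, 1, 2, 3], n=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
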