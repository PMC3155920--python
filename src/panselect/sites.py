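"""Column classification, outgroup polarization and frequency spectra.

Every downstream statistic operates on biallelic single-nucleotide columns
only.  Columns containing an alignment gap are treated as indels, columns
with more than two nucleotide alleles are triallelic-plus, and columns with
any missing haplotype call are excluded wholesale (complete-case per site),
so all statistics for a gene see one fixed sample size ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GAP, MISSING, GeneAlignment

# column status codes
MONOMORPHIC = 0
BIALLELIC = 1
TRIALLELIC_PLUS = 2
INDEL = 3
EXCLUDED_MISSING = 4

STATUS_LABELS = {
    MONOMORPHIC: "monomorphic",
    BIALLELIC: "biallelic_snp",
    TRIALLELIC_PLUS: "triallelic_plus",
    INDEL: "indel",
    EXCLUDED_MISSING: "excluded_missing",
}

#: sentinel for derived counts
UNPOLARIZED = -1
NOT_POLARIZED_YET = -2


@dataclass
class SiteClassification:
    """Per-column status plus allele counts for one alignment.

    ``minor_count`` and the allele codes are defined for biallelic columns
    only; ``derived_count`` is filled by :func:`polarize` and is
    ``UNPOLARIZED`` (-1) where the outgroup carries a gap, an ``N`` or a
    third allele.
    """

    n: int
    status: np.ndarray          # (L,) int8 status codes
    minor_count: np.ndarray     # (L,) int, 0 where not biallelic
    derived_count: np.ndarray   # (L,) int, sentinels above
    effective_n: np.ndarray     # (L,) chromosomes with a called base
    allele_low: np.ndarray      # (L,) smaller allele code of a biallelic column
    allele_high: np.ndarray     # (L,) larger allele code

    @property
    def included(self) -> np.ndarray:
        """Columns that feed the statistics (biallelic SNPs)."""
        return self.status == BIALLELIC

    @property
    def analyzed(self) -> np.ndarray:
        """Columns counted in the analyzed length (monomorphic + biallelic)."""
        return (self.status == BIALLELIC) | (self.status == MONOMORPHIC)

    @property
    def polarized(self) -> np.ndarray:
        return self.included & (self.derived_count >= 1)

    def exclusion_counts(self) -> dict[str, int]:
        return {
            "indel": int(np.sum(self.status == INDEL)),
            "triallelic_plus": int(np.sum(self.status == TRIALLELIC_PLUS)),
            "excluded_missing": int(np.sum(self.status == EXCLUDED_MISSING)),
        }


@dataclass
class UnfoldedSFS:
    """Derived-allele frequency spectrum: ``counts[i-1]`` = sites with
    derived count ``i`` (``i = 1 .. n-1``)."""

    n: int
    counts: np.ndarray

    @property
    def S(self) -> int:
        return int(self.counts.sum())


@dataclass
class FoldedSFS:
    """Minor-allele frequency spectrum: ``counts[j-1]`` = sites with minor
    count ``j`` (``j = 1 .. n//2``)."""

    n: int
    counts: np.ndarray

    @property
    def S(self) -> int:
        return int(self.counts.sum())


def classify_sites(aln: GeneAlignment) -> SiteClassification:
    """Classify every column of an alignment.

    Precedence: gap anywhere -> indel; missing call anywhere -> excluded;
    then by the number of distinct nucleotide alleles among the haplotypes.
    The outgroup does not influence classification (it only matters for
    polarization).
    """
    codes = aln.codes()
    n, L = codes.shape
    counts = np.zeros((6, L), dtype=np.int64)
    for k in range(6):
        counts[k] = np.sum(codes == k, axis=0)
    nuc = counts[:4]
    n_alleles = np.sum(nuc > 0, axis=0)
    status = np.full(L, MONOMORPHIC, dtype=np.int8)
    status[n_alleles == 2] = BIALLELIC
    status[n_alleles > 2] = TRIALLELIC_PLUS
    status[counts[MISSING] > 0] = EXCLUDED_MISSING
    status[counts[GAP] > 0] = INDEL

    biallelic = status == BIALLELIC
    nz = nuc > 0
    # allele codes of the two segregating nucleotides (defined where biallelic)
    allele_low = np.argmax(nz, axis=0).astype(np.int8)
    allele_high = (3 - np.argmax(nz[::-1], axis=0)).astype(np.int8)
    cnt_low = nuc[allele_low, np.arange(L)]
    cnt_high = nuc[allele_high, np.arange(L)]
    minor = np.where(biallelic, np.minimum(cnt_low, cnt_high), 0)

    return SiteClassification(
        n=n,
        status=status,
        minor_count=minor.astype(np.int64),
        derived_count=np.full(L, NOT_POLARIZED_YET, dtype=np.int64),
        effective_n=(n - counts[MISSING] - counts[GAP]).astype(np.int64),
        allele_low=allele_low,
        allele_high=allele_high,
    )


def polarize(aln: GeneAlignment, classification: SiteClassification) -> SiteClassification:
    """Fill derived-allele counts using the outgroup sequence.

    For a biallelic column whose outgroup allele equals one of the two
    segregating alleles, the derived allele is the other one.  Columns whose
    outgroup is a gap, missing, or a third allele stay unpolarized: they are
    kept for folded statistics but dropped from derived-allele statistics.
    """
    codes = aln.codes()
    n, L = codes.shape
    out = aln.outgroup_codes()
    derived = np.full(L, UNPOLARIZED, dtype=np.int64)
    bi = classification.status == BIALLELIC
    lo, hi = classification.allele_low, classification.allele_high
    cnt_hi = np.sum(codes == hi[np.newaxis, :], axis=0)
    cnt_lo = np.sum(codes == lo[np.newaxis, :], axis=0)
    anc_is_lo = bi & (out == lo)
    anc_is_hi = bi & (out == hi)
    derived[anc_is_lo] = cnt_hi[anc_is_lo]
    derived[anc_is_hi] = cnt_lo[anc_is_hi]
    result = SiteClassification(
        n=classification.n,
        status=classification.status,
        minor_count=classification.minor_count,
        derived_count=derived,
        effective_n=classification.effective_n,
        allele_low=lo,
        allele_high=hi,
    )
    return result


def unfolded_sfs(classification: SiteClassification) -> UnfoldedSFS:
    """Spectrum of derived counts over polarized biallelic columns."""
    n = classification.n
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    d = classification.derived_count[classification.polarized]
    counts = np.bincount(d, minlength=n)[1:n] if d.size else np.zeros(n - 1, dtype=np.int64)
    return UnfoldedSFS(n=n, counts=counts.astype(np.int64))


def folded_sfs(classification: SiteClassification) -> FoldedSFS:
    """Spectrum of minor-allele counts over all included biallelic columns."""
    n = classification.n
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    m = classification.minor_count[classification.included]
    k = n // 2
    counts = np.bincount(m, minlength=k + 1)[1 : k + 1] if m.size else np.zeros(k, dtype=np.int64)
    return FoldedSFS(n=n, counts=counts.astype(np.int64))


def fold(sfs: UnfoldedSFS) -> FoldedSFS:
    """Fold an unfolded spectrum: minor count ``j = min(i, n - i)``."""
    n = sfs.n
    k = n // 2
    folded = np.zeros(k, dtype=np.int64)
    for i, c in enumerate(sfs.counts, start=1):
        folded[min(i, n - i) - 1] += c
    return FoldedSFS(n=n, counts=folded)
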