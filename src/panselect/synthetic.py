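"""Synthetic two-population study generator.

Emulates the shape of a resequenced innate-immunity gene panel: ~130 genes
of 1-25 kb surveyed in two population samples (46 and 48 chromosomes),
locus-specific recombination rates, unequal functional-class sizes, a
handful of genes carrying sweep-like or balancing-like frequency-spectrum
distortion, per-gene human-chimp style coding divergence, and (via
:func:`panselect.network.generate_synthetic_network`) a scale-free
interaction network whose hub genes are the least diverse.

Selection is emulated by post-hoc SFS distortion of neutral coalescent
loci rather than forward simulation: with probability ``strength`` each
variant's derived count is resampled toward the rare/high-frequency
extremes (sweep-like) or toward intermediate counts (balancing-like).
The scan consumes only frequency-spectrum signals, so this plants exactly
the footprint the statistics are sensitive to, at a controllable effect
size; haplotype structure (LD) is not preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment import GeneAlignment
from .coalescent import PRESETS, DemographicModel, Epoch, simulate_locus
from .io import FunctionalAnnotation
from .neutrality import ng86_dnds

NEUTRAL, SWEEP, BALANCING = "neutral", "sweep", "balancing"

#: class sizes shaped like a real innate-immunity panel (132 genes)
DEFAULT_CLASS_COUNTS = {
    "Receptors": 19,
    "Adaptors": 10,
    "Modulators": 6,
    "Cytokines": 69,
    "Effector": 23,
    "Unclassified": 5,
}


@dataclass
class StudyDesign:
    """Study-level configuration; defaults mirror the emulated panel."""

    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    populations: dict = field(default_factory=lambda: {"AFR": 48, "EUR": 46})
    n_sweep: int = 10
    n_balanced: int = 10
    sweep_strength: float = 1.0
    balanced_strength: float = 1.0
    locus_length_range: tuple = (1_000, 25_000)
    recomb_rate_range: tuple = (5e-9, 2.5e-8)
    effective_size: float = 10_000.0
    mu: float = 1.5e-8
    demography: dict = field(default_factory=dict)  # population -> preset label
    #: per-class mutation-rate scaling emulating stronger purifying
    #: selection in core (adaptor/modulator) genes
    class_theta_scale: dict = field(default_factory=lambda: {"Adaptors": 0.65, "Modulators": 0.8})
    #: per-class scaling of the accepted nonsynonymous fraction for the
    #: synthetic coding-divergence pairs
    class_omega_scale: dict = field(default_factory=lambda: {"Adaptors": 0.4, "Modulators": 0.6})
    cds_fraction: float = 0.3
    n_codons: int = 300
    divergence: float = 0.012

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        if self.n_sweep + self.n_balanced > sum(self.class_counts.values()):
            raise ValueError("more planted genes than genes in the study")
        for s in (self.sweep_strength, self.balanced_strength):
            if not 0.0 <= s <= 1.0:
                raise ValueError("distortion strength must be in [0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class SyntheticStudy:
    design: StudyDesign
    seed: int
    annotation: FunctionalAnnotation
    alignments: dict  # (gene, population) -> GeneAlignment
    truth: pd.DataFrame  # gene, class, selection label
    diversity: pd.Series  # realized per-gene pi (per site, mean over pops)

    @property
    def genes(self) -> list[str]:
        return list(self.truth["gene"])


def distort_sfs(
    genotypes: np.ndarray, mode: str, strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Resample variant columns of a 0/1 haplotype matrix toward a target
    frequency class.

    ``sweep`` pushes derived counts to 1 (rare) or n-1/n-2 (high-frequency
    derived); ``balancing`` pushes them to the count(s) closest to n/2.
    Each column is distorted independently with probability ``strength``.
    """
    if mode not in (SWEEP, BALANCING):
        raise ValueError(f"unknown distortion mode {mode!r}")
    genotypes = np.asarray(genotypes, dtype=np.uint8).copy()
    n, S = genotypes.shape
    for j in range(S):
        if rng.random() >= strength:
            continue
        if mode == SWEEP:
            target = int(rng.choice([1, n - 1, n - 2], p=[0.5, 0.25, 0.25]))
        else:
            target = n // 2 if n % 2 == 0 else n // 2 + int(rng.integers(0, 2))
        col = np.zeros(n, dtype=np.uint8)
        col[rng.choice(n, size=target, replace=False)] = 1
        genotypes[:, j] = col
    return genotypes


def _integer_positions(frac_positions: np.ndarray, L: int, rng: np.random.Generator) -> np.ndarray:
    pos = np.floor(np.sort(frac_positions) * L).astype(np.int64)
    for i in range(1, pos.size):  # break collisions, keep strictly increasing
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if pos.size and pos[-1] >= L:
        pos -= pos[-1] - (L - 1)
        for i in range(pos.size - 2, -1, -1):
            if pos[i] >= pos[i + 1]:
                pos[i] = pos[i + 1] - 1
    return pos


def _synthetic_coding_pair(n_codons: int, divergence: float, omega: float, rng: np.random.Generator):
    """A pair of in-frame coding sequences at the given raw divergence, with
    nonsynonymous substitutions accepted with probability ``omega``."""
    bases = "TCAG"
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in stops:
            codons.append(c)
    human = "".join(codons)
    from .neutrality import _CODON_TABLE  # local import: shared codon table

    chimp = list(human)
    n_subs = rng.poisson(divergence * 3 * n_codons)
    for _ in range(n_subs):
        site = int(rng.integers(0, 3 * n_codons))
        ci = site // 3
        codon = "".join(chimp[3 * ci : 3 * ci + 3])
        alt = str(rng.choice([b for b in bases if b != chimp[site]]))
        mutant = codon[: site % 3] + alt + codon[site % 3 + 1 :]
        if mutant in stops:
            continue
        synonymous = _CODON_TABLE[mutant] == _CODON_TABLE[codon]
        if synonymous or rng.random() < omega:
            chimp[site] = alt
    return human, "".join(chimp)


def generate_synthetic_study(design: StudyDesign | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full two-population study from a single seed.

    A study-level :class:`numpy.random.SeedSequence` deterministically
    derives per-gene streams, so the same seed reproduces the study
    byte-for-byte and each gene is reproducible in isolation.
    """
    design = design or StudyDesign()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])

    genes, classes = [], []
    for label, count in design.class_counts.items():
        for _ in range(count):
            genes.append(f"g{len(genes) + 1:03d}")
            classes.append(label)
    n_genes = len(genes)

    labels = np.array([NEUTRAL] * n_genes, dtype=object)
    planted = master.choice(n_genes, size=design.n_sweep + design.n_balanced, replace=False)
    labels[planted[: design.n_sweep]] = SWEEP
    labels[planted[design.n_sweep :]] = BALANCING

    lo, hi = design.locus_length_range
    lengths = master.integers(lo, hi + 1, size=n_genes)
    rlo, rhi = design.recomb_rate_range
    rhos = master.uniform(rlo, rhi, size=n_genes)
    omegas = np.array(
        [
            min(1.0, master.lognormal(np.log(0.25), 0.5) * design.class_omega_scale.get(c, 1.0))
            for c in classes
        ]
    )

    pops = sorted(design.populations)
    gene_seeds = ss.spawn(n_genes * (len(pops) + 1))
    alignments: dict = {}
    dnds = np.full(n_genes, np.nan)
    pi_sum = np.zeros(n_genes)

    for gi, gene in enumerate(genes):
        scale = design.class_theta_scale.get(classes[gi], 1.0)
        for pi_idx, pop in enumerate(pops):
            rng = np.random.default_rng(gene_seeds[gi * (len(pops) + 1) + pi_idx])
            n_chrom = design.populations[pop]
            preset = design.demography.get(pop, "constant")
            if preset == "constant":
                model = DemographicModel(
                    epochs=[Epoch(0.0, design.effective_size)],
                    sample_n=n_chrom,
                    mu=design.mu * scale,
                )
            else:
                model = PRESETS[preset](n_chrom, mu=design.mu * scale)
            L = int(lengths[gi])
            locus = simulate_locus(model, L=L, rho=float(rhos[gi]), mode="fixed_theta", rng=rng)
            geno = locus.genotypes
            if labels[gi] == SWEEP:
                geno = distort_sfs(geno, SWEEP, design.sweep_strength, rng)
            elif labels[gi] == BALANCING:
                geno = distort_sfs(geno, BALANCING, design.balanced_strength, rng)
            positions = _integer_positions(locus.positions, L, rng)
            aln = GeneAlignment.from_binary(
                geno,
                gene_id=gene,
                population=pop,
                positions=positions,
                total_length=L,
                recomb_rate=float(rhos[gi]),
            )
            cds_len = int(design.cds_fraction * L)
            start = (L - cds_len) // 2
            cds = np.zeros(L, dtype=bool)
            cds[start : start + cds_len] = True
            aln.cds_mask = cds
            alignments[(gene, pop)] = aln
            k = geno.sum(axis=0).astype(float)
            pi_locus = float(np.sum(k * (n_chrom - k)) / (n_chrom * (n_chrom - 1) / 2.0))
            pi_sum[gi] += pi_locus / L / len(pops)
        div_rng = np.random.default_rng(gene_seeds[gi * (len(pops) + 1) + len(pops)])
        human, chimp = _synthetic_coding_pair(
            design.n_codons, design.divergence, float(omegas[gi]), div_rng
        )
        dnds[gi] = ng86_dnds(human, chimp, gene_id=gene).dnds

    annotation = FunctionalAnnotation(
        table=pd.DataFrame(
            {
                "class": classes,
                "recomb_rate": rhos,
                "dnds": dnds,
                "length": lengths,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    truth = pd.DataFrame({"gene": genes, "class": classes, "selection": labels})
    return SyntheticStudy(
        design=design,
        seed=seed,
        annotation=annotation,
        alignments=alignments,
        truth=truth,
        diversity=pd.Series(pi_sum, index=genes, name="pi_site"),
    )
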