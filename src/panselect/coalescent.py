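"""Backward-in-time coalescent simulator with recombination and
piecewise-constant demography.

The simulator follows the classic ancestral-recombination-graph (ARG)
construction: sampled chromosomes are traced backwards through coalescence
(rate scaled by the epoch's effective size) and crossover events (rate
proportional to the span of ancestral material carried by each lineage).
Mutations are then dropped on branches under the infinite-sites model,
either Poisson with the locus-wide theta (``fixed_theta``) or exactly S
mutations placed proportionally to branch length (``fixed_S``), which
mirrors conditional-on-S neutrality testing.

Time is measured in units of ``4 * N0`` generations, where ``N0`` is the
effective size of the most recent epoch.  With ``k`` active lineages the
coalescence rate is ``k (k - 1) * N0 / N(t)`` and the total crossover rate
is ``R * sum(spans)`` with ``R = 4 N0 rho (L - 1)``; these scalings give the
standard closed-form expectations ``E[S] = theta * a_{n-1}`` and
``E[pi] = theta`` for a constant-size population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import GeneAlignment
from .neutrality import NEUTRALITY_TESTS, NeutralityStatistics, compute_all


@dataclass
class Epoch:
    """One piecewise-constant demographic epoch.

    ``start_time`` is in generations before present; ``size`` is the
    diploid effective population size during the epoch.
    """

    start_time: float
    size: float


@dataclass
class DemographicModel:
    epochs: list[Epoch]
    sample_n: int
    mu: float = 1.5e-8
    label: str = "constant"

    def __post_init__(self) -> None:
        if self.sample_n < 2:
            raise ValueError("sample_n must be >= 2")
        if not self.epochs or self.epochs[0].start_time != 0:
            raise ValueError("first epoch must start at time 0")
        times = [e.start_time for e in self.epochs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(e.size <= 0 for e in self.epochs):
            raise ValueError("all effective sizes must be positive")
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")

    @property
    def N0(self) -> float:
        return self.epochs[0].size


def constant_model(sample_n: int, N: float = 10_000.0, mu: float = 1.5e-8) -> DemographicModel:
    return DemographicModel([Epoch(0.0, N)], sample_n=sample_n, mu=mu, label="constant")


def african_preset(sample_n: int, mu: float = 1.5e-8) -> DemographicModel:
    """Two-epoch approximation of African demographic history: an ancestral
    size of ~7,300 expanding to ~14,000 about 5,000 generations ago."""
    return DemographicModel(
        [Epoch(0.0, 14_000.0), Epoch(5_000.0, 7_300.0)],
        sample_n=sample_n,
        mu=mu,
        label="african_preset",
    )


def european_preset(sample_n: int, mu: float = 1.5e-8) -> DemographicModel:
    """Three-epoch out-of-Africa approximation for Europeans: recent
    expansion to ~10,000, a bottleneck of ~1,500 between 1,000 and 3,500
    generations ago, and an ancestral size of ~7,300."""
    return DemographicModel(
        [Epoch(0.0, 10_000.0), Epoch(1_000.0, 1_500.0), Epoch(3_500.0, 7_300.0)],
        sample_n=sample_n,
        mu=mu,
        label="european_preset",
    )


PRESETS = {
    "constant": constant_model,
    "african_preset": african_preset,
    "european_preset": european_preset,
}


@dataclass
class SimulatedLocus:
    """Binary haplotypes (0 ancestral / 1 derived) for one simulated locus."""

    genotypes: np.ndarray  # (n, S) uint8
    positions: np.ndarray  # (S,) floats in (0, 1)
    seed: int | None = None

    @property
    def S(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class NullDistribution:
    test: str
    values: np.ndarray
    params: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def B(self) -> int:
        return int(self.values.size)


class _Lineage:
    """One active ancestral lineage: non-overlapping segments, each carrying
    the bitmask of the sample chromosomes descending from it there."""

    __slots__ = ("segs", "birth")

    def __init__(self, segs: list[list], birth: float) -> None:
        self.segs = segs  # list of [left, right, mask]
        self.birth = birth

    @property
    def span(self) -> float:
        return self.segs[-1][1] - self.segs[0][0]


def _mask_at(segs: list[list], x: float) -> int:
    for left, right, mask in segs:
        if left <= x < right:
            return mask
    return 0


def _merge_segments(a: list[list], b: list[list], full_mask: int) -> list[list]:
    """Union of two segment lists with descendant masks OR-ed; elementary
    intervals whose mask covers the whole sample have found their MRCA and
    are dropped."""
    pts = sorted({p for s in a for p in (s[0], s[1])} | {p for s in b for p in (s[0], s[1])})
    out: list[list] = []
    for left, right in zip(pts, pts[1:]):
        mid = 0.5 * (left + right)
        mask = _mask_at(a, mid) | _mask_at(b, mid)
        if mask == 0 or mask == full_mask:
            continue
        if out and out[-1][1] == left and out[-1][2] == mask:
            out[-1][1] = right
        else:
            out.append([left, right, mask])
    return out


def _split_segments(segs: list[list], x: float) -> tuple[list[list], list[list]]:
    left_part: list[list] = []
    right_part: list[list] = []
    for left, right, mask in segs:
        if right <= x:
            left_part.append([left, right, mask])
        elif left >= x:
            right_part.append([left, right, mask])
        else:
            left_part.append([left, x, mask])
            right_part.append([x, right, mask])
    return left_part, right_part


def _simulate_branches(
    model: DemographicModel, R: float, rng: np.random.Generator
) -> list[tuple[float, list[list], float]]:
    """Run the ARG back to the locus-wide MRCA.

    Returns closed branches as ``(duration, segments, ancestral_width)``
    tuples; the mutational opportunity of a branch is
    ``duration * ancestral_width``.
    """
    n = model.sample_n
    full_mask = (1 << n) - 1
    N0 = model.N0
    epoch_starts = [e.start_time / (4.0 * N0) for e in model.epochs]
    sizes = [e.size for e in model.epochs]

    lineages = [_Lineage([[0.0, 1.0, 1 << i]], 0.0) for i in range(n)]
    branches: list[tuple[float, list[list], float]] = []
    t = 0.0
    epoch = 0

    def close(lin: _Lineage, now: float) -> None:
        width = sum(r - l for l, r, _ in lin.segs)
        branches.append((now - lin.birth, lin.segs, width))

    while len(lineages) >= 2:
        k = len(lineages)
        while epoch + 1 < len(epoch_starts) and t >= epoch_starts[epoch + 1]:
            epoch += 1
        coal_rate = k * (k - 1) * (N0 / sizes[epoch])
        spans = [lin.span for lin in lineages] if R > 0 else None
        rec_rate = R * sum(spans) if R > 0 else 0.0
        total = coal_rate + rec_rate
        dt = rng.exponential(1.0 / total)
        if epoch + 1 < len(epoch_starts) and t + dt > epoch_starts[epoch + 1]:
            t = epoch_starts[epoch + 1]
            epoch += 1
            continue
        t += dt
        if rng.random() < coal_rate / total:
            i, j = rng.choice(k, size=2, replace=False)
            li, lj = lineages[i], lineages[j]
            close(li, t)
            close(lj, t)
            merged = _merge_segments(li.segs, lj.segs, full_mask)
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            if merged:
                lineages.append(_Lineage(merged, t))
        else:
            w = np.asarray(spans)
            i = int(rng.choice(k, p=w / w.sum()))
            lin = lineages[i]
            lo, hi = lin.segs[0][0], lin.segs[-1][1]
            x = rng.uniform(lo, hi)
            left, right = _split_segments(lin.segs, x)
            if not left or not right:
                continue  # breakpoint at a segment boundary: no-op
            close(lin, t)
            lineages[i] = _Lineage(left, t)
            lineages.append(_Lineage(right, t))
    return branches


def simulate_locus(
    model: DemographicModel,
    L: int,
    rho: float = 0.0,
    mode: str = "fixed_theta",
    fixed_S: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedLocus:
    """Simulate one locus of ``L`` base pairs under the given demography.

    ``rho`` is the per-site per-generation crossover rate.  In
    ``fixed_theta`` mode the number of mutations is Poisson with locus
    theta = ``4 N0 mu L``; in ``fixed_S`` mode exactly ``fixed_S``
    mutations are placed, each proportionally to branch length.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if mode not in ("fixed_theta", "fixed_S"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed_S" and (fixed_S is None or fixed_S < 0):
        raise ValueError("fixed_S mode requires a nonnegative fixed_S")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = model.sample_n
    N0 = model.N0
    R = 4.0 * N0 * rho * max(L - 1, 0)
    branches = _simulate_branches(model, R, rng)

    areas = np.array([dur * width for dur, _, width in branches])
    total_area = float(areas.sum())
    if mode == "fixed_theta":
        theta = 4.0 * N0 * model.mu * L
        n_mut = rng.poisson(theta * total_area) if theta > 0 and total_area > 0 else 0
    else:
        n_mut = int(fixed_S)

    if n_mut == 0 or total_area == 0:
        return SimulatedLocus(np.zeros((n, 0), dtype=np.uint8), np.empty(0), seed)

    probs = areas / total_area
    chosen = rng.choice(len(branches), size=n_mut, p=probs)
    positions = np.empty(n_mut)
    columns = np.empty((n, n_mut), dtype=np.uint8)
    for m, bi in enumerate(chosen):
        _, segs, width = branches[bi]
        u = rng.uniform(0.0, width)
        for left, right, mask in segs:
            w = right - left
            if u <= w:
                positions[m] = left + u
                bits = mask
                break
            u -= w
        col = np.frombuffer(
            int(bits).to_bytes((n + 7) // 8, "little"), dtype=np.uint8
        )
        columns[:, m] = np.unpackbits(col, bitorder="little")[:n]
    order = np.argsort(positions, kind="stable")
    return SimulatedLocus(columns[:, order], positions[order], seed)


def locus_statistics(locus: SimulatedLocus, population: str = "sim") -> NeutralityStatistics:
    """Compute the full statistics record for a simulated locus through the
    same code path used for observed alignments."""
    aln = GeneAlignment.from_binary(locus.genotypes, gene_id="sim", population=population)
    return compute_all(aln, min_segregating=0)


def null_distributions(
    model: DemographicModel,
    L: int,
    rho: float,
    B: int,
    seed: int | None = None,
    mode: str = "fixed_S",
    S: int | None = None,
) -> dict[str, NullDistribution]:
    """Coalescent null distributions of the six neutrality tests.

    ``B`` replicates are simulated with the gene's sample size, length and
    local recombination rate; by default each replicate is conditioned on
    the observed number of segregating sites (``fixed_S``).  Statistics are
    computed by the same code path as observed data; replicates where a
    statistic is undefined are dropped from that statistic's distribution
    (the drop count is recorded).
    """
    if B < 100:
        raise ValueError("need B >= 100 replicates")
    if mode == "fixed_S" and (S is None or S < 1):
        raise ValueError("fixed_S mode requires the observed S")
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {t: [] for t in NEUTRALITY_TESTS}
    for _ in range(B):
        locus = simulate_locus(model, L=L, rho=rho, mode=mode, fixed_S=S, rng=rng)
        stats = locus_statistics(locus)
        for t in NEUTRALITY_TESTS:
            values[t].append(getattr(stats, t))
    params = {"n": model.sample_n, "L": L, "rho": rho, "mode": mode, "S": S, "B": B}
    out = {}
    for t, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        keep = arr[~np.isnan(arr)]
        out[t] = NullDistribution(test=t, values=keep, params=dict(params), n_dropped=int(arr.size - keep.size))
    return out


def empirical_pvalue(observed: float, dist: NullDistribution, tail: str) -> float:
    """One-sided empirical p-value with the (1 + k) / (B + 1) convention."""
    if dist.B == 0:
        raise ValueError("empty null distribution")
    if observed is None or (isinstance(observed, float) and math.isnan(observed)):
        return math.nan
    if tail == "lower":
        k = int(np.sum(dist.values <= observed))
    elif tail == "upper":
        k = int(np.sum(dist.values >= observed))
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (1.0 + k) / (dist.B + 1.0)
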