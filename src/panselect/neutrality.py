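"""Diversity estimators and frequency-spectrum neutrality tests.

Implements, per gene and population: nucleotide diversity (pi), Watterson's
theta, Tajima's D, Fu & Li's D*, F* (folded, no outgroup) and D, F
(outgroup-polarized), and the normalized Fay & Wu's H, plus a Nei-Gojobori
(1986) dN/dS estimator for coding sequence pairs.

Conventions
-----------
* Infinite sites: every included biallelic column counts as one mutation,
  so the total mutation count ``eta`` equals ``S``.
* Fu & Li's starred tests use folded singletons (minor count 1); the
  unstarred tests use derived singletons ("external" mutations).
* Variance constants for the Fu & Li family follow the corrected published
  forms (Simonsen, Churchill & Aquadro 1995).
* The normalized H follows the Zeng, Fu, Shi & Wu (2006) formulation, with
  theta-hat = S/a1 and theta-squared-hat = S(S-1)/(a1^2 + a2).
* Genes with fewer than five segregating sites are reported but flagged
  ``tested = False`` and their test statistics left undefined (NaN).

Undefined values are represented as ``math.nan`` throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import GeneAlignment
from .sites import (
    SiteClassification,
    UnfoldedSFS,
    classify_sites,
    folded_sfs,
    polarize,
    unfolded_sfs,
)

MIN_SEGREGATING_SITES = 5

NEUTRALITY_TESTS = (
    "tajima_d",
    "fuli_d_star",
    "fuli_f_star",
    "fuli_d",
    "fuli_f",
    "faywu_h_norm",
)


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n + 1)))


@dataclass
class NeutralityStatistics:
    gene_id: str
    population: str
    n: int
    L_included: int
    S: int
    eta_s: int
    eta_e: int
    pi_site: float
    pi_locus: float
    theta_w_site: float
    tajima_d: float
    fuli_d_star: float
    fuli_f_star: float
    fuli_d: float
    fuli_f: float
    faywu_h_norm: float
    polarized_fraction: float
    tested: bool


@dataclass
class DivergenceRecord:
    gene_id: str
    dn: float
    ds: float
    dnds: float  # NaN when ds == 0


def pi_from_counts(minor_counts: np.ndarray, n: int) -> float:
    """Mean pairwise difference count from per-site minor allele counts."""
    k = np.asarray(minor_counts, dtype=float)
    pairs = n * (n - 1) / 2.0
    return float(np.sum(k * (n - k)) / pairs)


def nucleotide_diversity(
    aln: GeneAlignment, mask: np.ndarray | None = None
) -> float:
    """Nucleotide diversity pi per analyzed site.

    Equals the mean number of pairwise differences between haplotypes over
    the included columns, divided by the analyzed length (monomorphic plus
    biallelic columns after the indel/triallelic/missing exclusions).
    Returns NaN when no column survives filtering.
    """
    target = aln if mask is None else aln.subset(mask)
    cls = classify_sites(target)
    L_inc = int(np.sum(cls.analyzed))
    if L_inc == 0:
        return math.nan
    pi_locus = pi_from_counts(cls.minor_count[cls.included], target.n)
    return pi_locus / L_inc


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's theta per site: S / a1 / L."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L <= 0:
        return math.nan
    return S / harmonic(n - 1) / L


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d(S: int, pi_locus: float, n: int) -> float:
    """Tajima's (1989) D from segregating sites and locus-level pi."""
    if S <= 0:
        return math.nan
    a1 = harmonic(n - 1)
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_locus - S / a1) / math.sqrt(var)


def fu_li_star(S: int, eta_s: int, pi_locus: float, n: int) -> tuple[float, float]:
    """Fu & Li's D* and F* (folded singletons, no outgroup needed)."""
    if S <= 0 or n < 3:
        return math.nan, math.nan
    a = harmonic(n - 1)
    b = harmonic2(n - 1)
    a1p = harmonic(n)  # a_{n+1} in the published notation
    c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2) / ((n - 1) ** 2) + 2.0 / (n - 1) * (1.5 - (2 * a1p - 3) / (n - 2) - 1.0 / n)

    v_dstar = ((n / (n - 1.0)) ** 2 * b + a * a * d - 2 * n * a * (a + 1) / ((n - 1.0) ** 2)) / (
        a * a + b
    )
    u_dstar = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v_dstar
    var_d = u_dstar * S + v_dstar * S * S
    dstar = ((n / (n - 1.0)) * S - a * eta_s) / math.sqrt(var_d) if var_d > 0 else math.nan

    v_fstar = (
        (2 * n**3 + 110.0 * n**2 - 255.0 * n + 153) / (9.0 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8.0 * b / n
    ) / (a * a + b)
    u_fstar = ((4 * n**2 + 19.0 * n + 3 - 12 * (n + 1) * a1p) / (3.0 * n * (n - 1))) / a - v_fstar
    var_f = u_fstar * S + v_fstar * S * S
    fstar = (pi_locus - (n - 1.0) / n * eta_s) / math.sqrt(var_f) if var_f > 0 else math.nan
    return dstar, fstar


def fu_li_outgroup(eta: int, eta_e: int, pi_locus: float, n: int) -> tuple[float, float]:
    """Fu & Li's D and F using outgroup-polarized external mutations.

    ``eta`` is the total mutation count (= S under infinite sites) and
    ``eta_e`` the number of derived singletons.
    """
    if eta <= 0 or n < 3:
        return math.nan, math.nan
    a = harmonic(n - 1)
    b = harmonic2(n - 1)
    a1p = harmonic(n)
    c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))

    v_d = 1.0 + a * a / (b + a * a) * (c - (n + 1.0) / (n - 1.0))
    u_d = a - 1.0 - v_d
    var_d = u_d * eta + v_d * eta * eta
    d_stat = (eta - a * eta_e) / math.sqrt(var_d) if var_d > 0 else math.nan

    v_f = (c + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a * a + b)
    u_f = (
        1.0 + (n + 1.0) / (3.0 * (n - 1)) - 4.0 * (n + 1) / ((n - 1.0) ** 2) * (a1p - 2.0 * n / (n + 1))
    ) / a - v_f
    var_f = u_f * eta + v_f * eta * eta
    f_stat = (pi_locus - eta_e) / math.sqrt(var_f) if var_f > 0 else math.nan
    return d_stat, f_stat


def faywu_h_normalized(sfs: UnfoldedSFS) -> float:
    """Normalized Fay & Wu's H (Zeng et al. 2006).

    Contrasts pairwise diversity theta_pi with the high-frequency-weighted
    theta_L; strongly negative values indicate an excess of high-frequency
    derived variants, the classic hitchhiking footprint.
    """
    n = sfs.n
    S = sfs.S
    if S <= 0:
        return math.nan
    i = np.arange(1, n, dtype=float)
    xi = sfs.counts.astype(float)
    theta_pi = float(np.sum(xi * i * (n - i)) * 2.0 / (n * (n - 1)))
    theta_l = float(np.sum(xi * i) / (n - 1))
    if n == 2:
        return 0.0 if theta_pi == theta_l else math.nan
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    bnp1 = harmonic2(n)  # sum_{i=1}^{n} 1/i^2
    theta_hat = S / a1
    theta_sq_hat = S * (S - 1.0) / (a1 * a1 + a2)
    var = (n - 2.0) / (6.0 * (n - 1.0)) * theta_hat + (
        18.0 * n * n * (3.0 * n + 2.0) * bnp1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2) * theta_sq_hat
    if var <= 0:
        return math.nan
    return (theta_pi - theta_l) / math.sqrt(var)


def compute_all(
    aln: GeneAlignment,
    mask: np.ndarray | None = None,
    min_segregating: int = MIN_SEGREGATING_SITES,
) -> NeutralityStatistics:
    """Full per-gene statistics record on the (optionally masked) alignment."""
    target = aln if mask is None else aln.subset(mask)
    n = target.n
    cls = polarize(target, classify_sites(target))
    L_inc = int(np.sum(cls.analyzed))
    included = cls.included
    S = int(np.sum(included))
    pi_locus = pi_from_counts(cls.minor_count[included], n) if S else 0.0
    pi_site = pi_locus / L_inc if L_inc else math.nan
    theta_w = watterson_theta(S, n, L_inc) if L_inc else math.nan

    eta_s = int(np.sum(cls.minor_count[included] == 1))
    pol = cls.polarized
    n_pol = int(np.sum(pol))
    eta_e = int(np.sum(cls.derived_count[pol] == 1))
    pol_frac = n_pol / S if S else math.nan

    tested = S >= min_segregating
    taj = dstar = fstar = d_out = f_out = h_norm = math.nan
    if tested:
        taj = tajimas_d(S, pi_locus, n)
        dstar, fstar = fu_li_star(S, eta_s, pi_locus, n)
        if n_pol > 0:
            d_out, f_out = fu_li_outgroup(S, eta_e, pi_locus, n)
            h_norm = faywu_h_normalized(unfolded_sfs(cls))

    return NeutralityStatistics(
        gene_id=target.gene_id,
        population=target.population,
        n=n,
        L_included=L_inc,
        S=S,
        eta_s=eta_s,
        eta_e=eta_e,
        pi_site=pi_site,
        pi_locus=pi_locus,
        theta_w_site=theta_w,
        tajima_d=taj,
        fuli_d_star=dstar,
        fuli_f_star=fstar,
        fuli_d=d_out,
        fuli_f=f_out,
        faywu_h_norm=h_norm,
        polarized_fraction=pol_frac,
        tested=tested,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) dN/dS for coding sequence pairs
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_CODON_TABLE = {}
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODON_TABLE[_a + _b + _c] = _AMINO[_i]


def _syn_sites(codon: str) -> float:
    """Expected number of synonymous sites in a codon (of 3 total).

    Changes producing stop codons count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all
    single-step mutational pathways between two codons.

    Pathways passing through a stop codon are excluded unless every
    pathway does.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*" and nxt != c2:
                through_stop = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        pathways.append((sd, nd, through_stop))
    usable = [p for p in pathways if not p[2]] or pathways
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(seq_a: str, seq_b: str, gene_id: str = "pair") -> DivergenceRecord:
    """Nei-Gojobori (1986) dN and dS with Jukes-Cantor correction.

    Both sequences must be equal-length, gapless, in-frame coding sequence
    without internal stop codons.  ``dnds`` is NaN when ``ds == 0``.
    """
    seq_a, seq_b = seq_a.upper().replace("U", "T"), seq_b.upper().replace("U", "T")
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    if any(ch not in _BASES for ch in seq_a + seq_b):
        raise ValueError("sequences must be gapless A/C/G/T coding sequence")
    syn_sites_a = syn_sites_b = 0.0
    sd = nd = 0.0
    n_codons = len(seq_a) // 3
    for k in range(n_codons):
        ca, cb = seq_a[3 * k : 3 * k + 3], seq_b[3 * k : 3 * k + 3]
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            raise ValueError("internal stop codon")
        syn_sites_a += _syn_sites(ca)
        syn_sites_b += _syn_sites(cb)
        s, n = _pathway_differences(ca, cb)
        sd += s
        nd += n
    S_sites = (syn_sites_a + syn_sites_b) / 2.0
    N_sites = 3.0 * n_codons - S_sites
    ps = sd / S_sites if S_sites > 0 else 0.0
    pn = nd / N_sites if N_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    dnds = dn / ds if (ds and ds > 0 and not math.isnan(dn)) else math.nan
    return DivergenceRecord(gene_id=gene_id, dn=dn, ds=ds, dnds=dnds)
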