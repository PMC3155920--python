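"""Class-level diversity comparisons and selection-call enrichment.

Three procedures, all at the level of a functional class against the rest
of the gene panel:

* an unpaired two-sample t-test of per-gene diversity (pooled variance by
  default, Welch optional);
* a label-permutation test of the class mean (lower tail: the hypothesis is
  that the class is *more constrained*, i.e. less diverse, than the rest);
* a one-sided Fisher exact (hypergeometric tail) test for an excess of
  selection calls in the class, on the 2x2 table
  (in-class selected, in-class not, out-of-class selected, out-of-class not).

The gene universe for the 2x2 table is the full study panel, including
unclassified genes and genes excluded from testing by the S < 5 rule,
which count as "no evidence of selection".  No multiple-testing correction
is applied across classes; results are reported as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class ClassMeanTest:
    class_label: str
    n_class: int
    n_rest: int
    mean_class: float
    mean_rest: float
    t_statistic: float
    p_two_sided: float


@dataclass
class PermutationResult:
    class_label: str
    observed_mean: float
    p_lower: float
    B: int
    exhaustive: bool


@dataclass
class EnrichmentResult:
    class_label: str
    population: str
    mode: str  # positive | balancing | either
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_one_sided: float


def class_mean_test(
    per_gene: pd.Series,
    class_genes,
    class_label: str = "",
    variant: str = "pooled",
) -> ClassMeanTest:
    """Unpaired t-test of a class's per-gene values against all other genes."""
    per_gene = per_gene.dropna()
    class_genes = [g for g in class_genes if g in per_gene.index]
    rest = per_gene.drop(class_genes)
    x = per_gene.loc[class_genes].to_numpy(dtype=float)
    y = rest.to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >= 2 genes")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):  # degenerate (zero variance in both groups)
        t, p = math.nan, math.nan
        if np.ptp(np.concatenate([x, y])) == 0:
            t, p = 0.0, 1.0
    return ClassMeanTest(
        class_label=class_label,
        n_class=x.size,
        n_rest=y.size,
        mean_class=float(x.mean()),
        mean_rest=float(y.mean()),
        t_statistic=t,
        p_two_sided=p,
    )


def permutation_test_class_mean(
    per_gene: pd.Series,
    class_genes,
    class_label: str = "",
    B: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> PermutationResult:
    """Lower-tail label-permutation test of the class mean.

    Draws ``B`` random classes of the same size from the panel and counts
    replicate means at or below the observed one, with the
    ``(1 + k) / (B + 1)`` convention.  When the number of distinct classes
    ``C(m, k)`` is at most ``exhaustive_limit`` the test enumerates all of
    them instead and returns the exact tail fraction.
    """
    per_gene = per_gene.dropna()
    values = per_gene.to_numpy(dtype=float)
    genes = list(per_gene.index)
    k = sum(1 for g in class_genes if g in per_gene.index)
    m = len(genes)
    if k < 1 or m <= k:
        raise ValueError("class must be a nonempty strict subset of the panel")
    observed = float(per_gene.loc[[g for g in class_genes if g in per_gene.index]].mean())
    n_combos = comb(m, k, exact=True)
    if n_combos <= exhaustive_limit:
        count = 0
        for idx in combinations(range(m), k):
            if values[list(idx)].mean() <= observed + 1e-12:
                count += 1
        return PermutationResult(class_label, observed, count / n_combos, n_combos, True)
    rng = np.random.default_rng(seed)
    # uniform random k-subsets, vectorised: smallest-k entries of iid uniforms
    u = rng.random((B, m))
    picks = np.argpartition(u, k - 1, axis=1)[:, :k]
    means = values[picks].mean(axis=1)
    count = int(np.sum(means <= observed + 1e-12))
    return PermutationResult(class_label, observed, (1.0 + count) / (B + 1.0), B, False)


def fisher_enrichment(
    selected_genes,
    class_genes,
    all_genes,
    class_label: str = "",
    population: str = "",
    mode: str = "either",
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher exact test for an excess of selected
    genes in a class.

    The p-value is the exact hypergeometric upper tail P(X >= a).  The odds
    ratio (a d)/(b c) is NaN when a margin is degenerate.
    """
    all_genes = set(all_genes)
    selected = set(selected_genes) & all_genes
    cls = set(class_genes) & all_genes
    if not cls:
        raise ValueError("empty class")
    if not set(selected_genes) <= all_genes or not set(class_genes) <= all_genes:
        raise ValueError("class and selected genes must be subsets of the universe")
    a = len(selected & cls)
    b = len(cls) - a
    c = len(selected) - a
    d = len(all_genes) - a - b - c
    p = float(sps.hypergeom.sf(a - 1, len(all_genes), len(cls), len(selected)))
    odds = (a * d) / (b * c) if b * c > 0 else math.nan
    return EnrichmentResult(
        class_label=class_label,
        population=population,
        mode=mode,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds,
        p_one_sided=p,
    )


def fisher_from_counts(
    a: int,
    b: int,
    c: int,
    d: int,
    class_label: str = "",
    population: str = "",
    mode: str = "either",
) -> EnrichmentResult:
    """Same one-sided enrichment test, built directly from the 2x2 counts
    (in-class selected, in-class not, out-of-class selected, out-of-class
    not)."""
    if min(a, b, c, d) < 0 or a + b == 0:
        raise ValueError("invalid 2x2 counts")
    total = a + b + c + d
    p = float(sps.hypergeom.sf(a - 1, total, a + b, a + c))
    odds = (a * d) / (b * c) if b * c > 0 else math.nan
    return EnrichmentResult(class_label, population, mode, a, b, c, d, odds, p)


def class_diversity_table(
    gene_table: pd.DataFrame,
    class_map: pd.Series,
    value_columns: tuple[str, ...] = ("pi_whole", "pi_cds"),
    B: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-class mean diversity with t-test and permutation p-values.

    ``gene_table`` holds one row per gene x population with the requested
    value columns; ``class_map`` maps gene -> class label.  Returns one row
    per (class, population, value column).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for pop, sub in gene_table.groupby("population", sort=True):
        per_gene_all = sub.set_index("gene")
        for label in sorted(class_map.unique()):
            genes = class_map.index[class_map == label]
            for col in value_columns:
                per_gene = per_gene_all[col]
                in_class = [g for g in genes if g in per_gene.dropna().index]
                if len(in_class) < 2 or len(per_gene.dropna()) - len(in_class) < 2:
                    continue
                tt = class_mean_test(per_gene, genes, class_label=label)
                pm = permutation_test_class_mean(
                    per_gene, genes, class_label=label, B=B,
                    seed=int(rng.integers(2**31 - 1)),
                )
                rows.append(
                    {
                        "class": label,
                        "population": pop,
                        "scope": col,
                        "n_genes": tt.n_class,
                        "mean_class": tt.mean_class,
                        "mean_rest": tt.mean_rest,
                        "t_statistic": tt.t_statistic,
                        "t_p_two_sided": tt.p_two_sided,
                        "perm_p_lower": pm.p_lower,
                        "perm_B": pm.B,
                        "perm_exhaustive": pm.exhaustive,
                    }
                )
    return pd.DataFrame(rows)
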