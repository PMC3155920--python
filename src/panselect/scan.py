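"""Empirical-outlier selection scan over a gene panel.

Because all genes in a panel share one demographic history, a gene's test
statistics are ranked against the rest of the panel rather than against a
parametric null: a gene is called under selection when it falls in the
extreme 5% tail of two or more neutrality tests in the same population and
the same direction.

* POSITIVE (sweep-like) calls come from the lower tail of any of
  Tajima's D, Fu & Li's D*, F*, D, F, and the normalized Fay & Wu's H;
  a positive call supported by H is flagged "unequivocal", since a deficit
  of H has no plausible demographic explanation shared across the panel.
* BALANCING calls come from the upper tail of the five rare-vs-intermediate
  contrasts (H never supports balancing).
* A gene qualifying in both directions takes the direction with more
  supporting tests; ties are reported ambiguous with direction ``none``.

Calls are optionally corroborated against per-gene coalescent null
distributions (one-sided p per supporting test; corroborated when at least
two tests reach p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coalescent import NullDistribution, empirical_pvalue
from .neutrality import NEUTRALITY_TESTS

LOWER_TAIL_TESTS = NEUTRALITY_TESTS  # all six can indicate a sweep
UPPER_TAIL_TESTS = tuple(t for t in NEUTRALITY_TESTS if t != "faywu_h_norm")

DIRECTION_POSITIVE = "positive"
DIRECTION_BALANCING = "balancing"
DIRECTION_NONE = "none"


@dataclass
class SelectionCall:
    gene_id: str
    population: str
    direction: str
    supporting_tests: list = field(default_factory=list)  # (test, percentile, tail)
    unequivocal_positive: bool = False
    ambiguous: bool = False
    reason: str = ""
    sim_pvalues: dict = field(default_factory=dict)
    corroborated: bool | None = None


def empirical_percentiles(values: pd.Series, min_genes: int = 20) -> pd.Series:
    """Percentile rank of each gene's statistic within the panel.

    Mean rank for ties, divided by the number of genes with a defined
    value, giving percentiles in (0, 1].  NaN values get NaN percentiles.
    """
    values = pd.Series(values, dtype=float)
    defined = values.dropna()
    if len(defined) < min_genes:
        warnings.warn(
            f"only {len(defined)} genes with defined values; empirical "
            "percentiles will be coarse",
            stacklevel=2,
        )
    out = pd.Series(np.nan, index=values.index)
    if len(defined):
        ranks = sps.rankdata(defined.to_numpy(), method="average")
        out.loc[defined.index] = ranks / len(defined)
    return out


def call_selection(
    stat_table: pd.DataFrame,
    threshold: float = 0.05,
    min_tests: int = 2,
) -> list[SelectionCall]:
    """Scan one population's statistics table for selection candidates.

    ``stat_table`` has one row per gene with columns ``gene``,
    ``population``, ``tested`` and the six test statistics.  Only tested
    genes (S >= 5) enter the percentile pools; untested genes appear in the
    output with direction ``none`` and a reason code.
    """
    pops = stat_table["population"].unique()
    if len(pops) != 1:
        raise ValueError("call_selection expects a single-population table")
    population = pops[0]
    tested = stat_table[stat_table["tested"].astype(bool)].set_index("gene")
    pct = {
        t: empirical_percentiles(tested[t]) for t in NEUTRALITY_TESTS if t in tested.columns
    }
    calls: list[SelectionCall] = []
    for _, row in stat_table.iterrows():
        gene = row["gene"]
        if not bool(row["tested"]):
            calls.append(
                SelectionCall(gene, population, DIRECTION_NONE, reason="untested_low_S")
            )
            continue
        lower = [
            (t, float(pct[t].loc[gene]), "lower")
            for t in LOWER_TAIL_TESTS
            if t in pct and not math.isnan(pct[t].loc[gene]) and pct[t].loc[gene] <= threshold
        ]
        upper = [
            (t, float(pct[t].loc[gene]), "upper")
            for t in UPPER_TAIL_TESTS
            if t in pct and not math.isnan(pct[t].loc[gene]) and pct[t].loc[gene] >= 1 - threshold
        ]
        pos_ok = len(lower) >= min_tests
        bal_ok = len(upper) >= min_tests
        if pos_ok and bal_ok:
            if len(lower) > len(upper):
                direction, support, ambiguous = DIRECTION_POSITIVE, lower, False
            elif len(upper) > len(lower):
                direction, support, ambiguous = DIRECTION_BALANCING, upper, False
            else:
                direction, support, ambiguous = DIRECTION_NONE, lower + upper, True
        elif pos_ok:
            direction, support, ambiguous = DIRECTION_POSITIVE, lower, False
        elif bal_ok:
            direction, support, ambiguous = DIRECTION_BALANCING, upper, False
        else:
            direction, support, ambiguous = DIRECTION_NONE, [], False
        call = SelectionCall(
            gene_id=gene,
            population=population,
            direction=direction,
            supporting_tests=support,
            unequivocal_positive=(
                direction == DIRECTION_POSITIVE and any(t == "faywu_h_norm" for t, _, _ in support)
            ),
            ambiguous=ambiguous,
            reason="mixed_tails" if ambiguous else "",
        )
        calls.append(call)
    return calls


def corroborate(
    calls: list[SelectionCall],
    stat_table: pd.DataFrame,
    null_dists: dict[str, dict[str, NullDistribution]],
    alpha: float = 0.05,
    min_tests: int = 2,
) -> list[SelectionCall]:
    """Attach coalescent-simulation p-values to called genes.

    ``null_dists`` maps gene -> test -> NullDistribution.  For each
    supporting test the one-sided p in its tail is computed; a call is
    corroborated when at least ``min_tests`` tests reach ``p < alpha``.
    Genes without a distribution keep ``corroborated = None``.
    """
    by_gene = stat_table.set_index("gene")
    for call in calls:
        if call.direction == DIRECTION_NONE or call.gene_id not in null_dists:
            continue
        dists = null_dists[call.gene_id]
        pvals = {}
        for test, _, tail in call.supporting_tests:
            if test not in dists or dists[test].B == 0:
                continue
            observed = float(by_gene.loc[call.gene_id, test])
            pvals[test] = empirical_pvalue(observed, dists[test], tail)
        call.sim_pvalues = pvals
        call.corroborated = sum(1 for p in pvals.values() if p < alpha) >= min_tests
    return calls


def calls_to_table(calls: list[SelectionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.gene_id,
                "population": c.population,
                "direction": c.direction,
                "n_supporting": len(c.supporting_tests),
                "supporting_tests": ";".join(
                    f"{t}@{p:.4f}({tail})" for t, p, tail in c.supporting_tests
                ),
                "unequivocal_positive": c.unequivocal_positive,
                "ambiguous": c.ambiguous,
                "reason": c.reason,
                "sim_pvalues": ";".join(f"{t}={p:.4g}" for t, p in sorted(c.sim_pvalues.items())),
                "corroborated": c.corroborated,
            }
        )
    return pd.DataFrame(rows)


def summarize_calls(
    calls_by_population: dict[str, list[SelectionCall]],
    class_map: pd.Series,
) -> pd.DataFrame:
    """Class x population summary of positive and balancing calls.

    ``class_map`` maps gene -> class (or subclass) label.  Returns one row
    per class with per-population counts and gene lists, suitable as the
    feed for :func:`panselect.enrichment.fisher_enrichment`.
    """
    labels = sorted(class_map.unique())
    rows = []
    for label in labels:
        genes = set(class_map.index[class_map == label])
        row = {"class": label, "n_genes": len(genes)}
        for pop, calls in sorted(calls_by_population.items()):
            for direction in (DIRECTION_POSITIVE, DIRECTION_BALANCING):
                hits = sorted(
                    c.gene_id for c in calls if c.direction == direction and c.gene_id in genes
                )
                row[f"{direction}_{pop}_n"] = len(hits)
                row[f"{direction}_{pop}_genes"] = ",".join(hits) if hits else "-"
        rows.append(row)
    total = {"class": "TOTAL", "n_genes": int(len(class_map))}
    for pop, calls in sorted(calls_by_population.items()):
        for direction in (DIRECTION_POSITIVE, DIRECTION_BALANCING):
            hits = [c.gene_id for c in calls if c.direction == direction]
            total[f"{direction}_{pop}_n"] = len(hits)
            total[f"{direction}_{pop}_genes"] = ""
    rows.append(total)
    return pd.DataFrame(rows)
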