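"""Bundled reference data.

The shipped fixture transcribes the published per-class selection calls of
a 132-gene human antibacterial innate-immunity panel surveyed in an
African- and a European-ancestry sample: the functional grouping sizes and
the genes called under positive or balancing selection in each population.
It lets the enrichment stage run end-to-end on real study counts without
any sequence data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .enrichment import EnrichmentResult, fisher_from_counts

TOTAL_PANEL_GENES = 132


def _read(name: str) -> pd.DataFrame:
    with resources.files("panselect.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def innate_panel_class_sizes() -> pd.Series:
    df = _read("innate_panel_classes.tsv")
    return df.set_index("group")["n_genes"]


def innate_panel_calls() -> pd.DataFrame:
    return _read("innate_panel_calls.tsv")


def innate_panel_enrichment(
    modes: tuple[str, ...] = ("positive", "balancing", "either"),
) -> pd.DataFrame:
    """Fisher enrichment of the bundled panel's calls, per functional group,
    population and direction, over the full 132-gene universe.

    Genes without calls count as "no evidence"; ``either`` pools the
    distinct genes called in either direction within a population.
    """
    sizes = innate_panel_class_sizes()
    calls = innate_panel_calls()
    rows: list[EnrichmentResult] = []
    for pop, sub in calls.groupby("population", sort=True):
        for mode in modes:
            picked = sub if mode == "either" else sub[sub["direction"] == mode]
            selected_total = picked["gene"].nunique()
            for group, n_genes in sizes.items():
                a = picked.loc[picked["group"] == group, "gene"].nunique()
                b = int(n_genes) - a
                c = selected_total - a
                d = TOTAL_PANEL_GENES - int(n_genes) - c
                rows.append(fisher_from_counts(a, b, c, d, group, pop, mode))
    return pd.DataFrame([r.__dict__ for r in rows])
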