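"""End-to-end orchestration: load or generate a study, filter, compute
statistics, scan for selection, corroborate against coalescent nulls,
analyze the interaction network and run the class-level tests.

Every stage writes its table under the output directory; a MANIFEST lists
the completed stages so partial runs are auditable.  Given the same
configuration and seed the output files are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .coalescent import PRESETS, null_distributions
from .enrichment import class_diversity_table, fisher_enrichment
from .network import InteractionGraph, correlate_centrality, generate_synthetic_network
from .neutrality import MIN_SEGREGATING_SITES, compute_all, nucleotide_diversity
from .scan import call_selection, calls_to_table, corroborate, summarize_calls
from .sites import classify_sites
from .synthetic import StudyDesign, generate_synthetic_study

logger = logging.getLogger("panselect")

STAGES = (
    "load",
    "statistics",
    "scan",
    "corroborate",
    "network",
    "class_tests",
    "enrichment",
    "report",
)


@dataclass
class StudyConfig:
    """Pipeline configuration: either real-input paths or a synthetic block.

    Thresholds default to the standard scan settings: 5% percentile tails,
    at least two supporting tests, genes with fewer than five segregating
    sites excluded from testing, 1,000 coalescent replicates per gene and
    10,000 label permutations per class.
    """

    # real inputs
    alignments_dir: str | None = None
    annotation_path: str | None = None
    bed_dir: str | None = None
    edge_list_path: str | None = None
    populations: list = field(default_factory=lambda: ["AFR", "EUR"])
    outgroup_tag: str = "outgroup"
    # synthetic study block (used when alignments_dir is not given)
    synthetic: dict | None = field(default_factory=dict)
    # simulator settings
    demography: dict = field(default_factory=dict)  # population -> preset
    null_B: int = 1000
    null_mode: str = "fixed_S"
    # scan thresholds
    tail_threshold: float = 0.05
    min_tests: int = 2
    min_segregating: int = MIN_SEGREGATING_SITES
    # class tests
    permutations_B: int = 10_000
    # synthetic network shape (used when no edge list is given)
    network_neighbors: int = 1400
    network_coupling: float = 0.2
    network_edges_per_node: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alignments_dir is None and self.synthetic is None:
            raise ValueError("config needs either real-input paths or a synthetic block")
        if not 0 < self.tail_threshold < 0.5:
            raise ValueError("tail_threshold must be in (0, 0.5)")
        if self.min_tests < 1:
            raise ValueError("min_tests must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_real_study(config: StudyConfig):
    annotation = psio.read_gene_table(config.annotation_path)
    alignments = {}
    base = Path(config.alignments_dir)
    for gene in annotation.genes:
        rho = float(annotation.table.loc[gene].get("recomb_rate", 1e-8))
        chrom = str(annotation.table.loc[gene].get("chrom_system", "autosomal"))
        for pop in config.populations:
            fasta = base / f"{gene}_{pop}.fasta"
            if not fasta.exists():
                logger.info("no alignment for %s in %s; skipped", gene, pop)
                continue
            aln = psio.read_haplotype_fasta(
                fasta,
                outgroup_tag=config.outgroup_tag,
                gene_id=gene,
                population=pop,
                recomb_rate=rho,
                chrom_system=chrom if chrom in ("autosomal", "X") else "autosomal",
            )
            if config.bed_dir:
                bed = Path(config.bed_dir) / f"{gene}.bed"
                if bed.exists():
                    aln.cds_mask = psio.read_regions_bed(bed, aln.positions)
            alignments[(gene, pop)] = aln
    return annotation, alignments, None


def run_pipeline(config: StudyConfig, outdir: str | Path) -> dict:
    """Execute all stages in order; returns the result tables keyed by name.

    Any stage failure aborts with a stage-labelled :class:`PipelineError`;
    tables already written and the MANIFEST of completed stages are kept.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    completed: list[str] = []
    results: dict = {}

    def finish_stage(name: str) -> None:
        completed.append(name)
        (outdir / "MANIFEST").write_text("\n".join(completed) + "\n")

    try:
        stage = "load"
        config.to_yaml(outdir / "config.yaml")
        truth = None
        if config.alignments_dir:
            annotation, alignments, truth = _load_real_study(config)
        else:
            design = StudyDesign(**(config.synthetic or {}))
            study = generate_synthetic_study(design, seed=config.seed)
            annotation, alignments, truth = study.annotation, study.alignments, study.truth
            config.populations = sorted(design.populations)
            psio.write_table(truth, outdir / "truth.tsv")
        finish_stage(stage)

        stage = "statistics"
        rows = []
        for (gene, pop), aln in alignments.items():
            stats = compute_all(aln, min_segregating=config.min_segregating)
            rec = dataclasses.asdict(stats)
            rec["gene"] = rec.pop("gene_id")
            rec["class"] = annotation.gene_class(gene)
            rec["pi_whole"] = rec["pi_site"]
            rec["pi_cds"] = (
                nucleotide_diversity(aln, aln.cds_mask) if aln.cds_mask is not None else math.nan
            )
            dnds = annotation.table.loc[gene].get("dnds", math.nan)
            rec["dnds"] = float(dnds) if dnds is not None else math.nan
            rec["exclusions"] = json.dumps(classify_sites(aln).exclusion_counts())
            rows.append(rec)
        stats_table = pd.DataFrame(rows)
        for _, row in stats_table[~stats_table["tested"]].iterrows():
            logger.info("gene %s (%s) excluded from tests: S=%d < %d",
                        row["gene"], row["population"], row["S"], config.min_segregating)
        psio.write_table(stats_table, outdir / "statistics.tsv")
        results["statistics"] = stats_table
        finish_stage(stage)

        stage = "scan"
        calls_by_pop = {}
        for pop in config.populations:
            sub = stats_table[stats_table["population"] == pop]
            calls_by_pop[pop] = call_selection(
                sub, threshold=config.tail_threshold, min_tests=config.min_tests
            )
        results["calls"] = calls_by_pop
        finish_stage(stage)

        stage = "corroborate"
        for pop, calls in calls_by_pop.items():
            sub = stats_table[stats_table["population"] == pop]
            by_gene = sub.set_index("gene")
            dists = {}
            pop_key = sum(pop.encode())  # stable across interpreter runs
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, pop_key]))
            for call in calls:
                if call.direction == "none":
                    continue
                grow = by_gene.loc[call.gene_id]
                preset = config.demography.get(pop, "constant")
                model = PRESETS[preset](int(grow["n"]))
                aln = alignments[(call.gene_id, pop)]
                dists[call.gene_id] = null_distributions(
                    model,
                    L=int(grow["L_included"]),
                    rho=float(aln.recomb_rate),
                    B=config.null_B,
                    seed=int(rng.integers(2**31 - 1)),
                    mode=config.null_mode,
                    S=int(grow["S"]),
                )
            corroborate(calls, sub, dists, min_tests=config.min_tests)
            psio.write_table(calls_to_table(calls), outdir / f"calls_{pop}.tsv")
        summary = summarize_calls(
            calls_by_pop, annotation.table["class"]
        )
        psio.write_table(summary, outdir / "selection_summary.tsv")
        results["selection_summary"] = summary
        finish_stage(stage)

        stage = "network"
        gene_rows = stats_table[["gene", "population", "pi_whole", "pi_cds", "dnds"]]
        if config.edge_list_path:
            graph = psio.read_edge_list(config.edge_list_path, focal=set(annotation.genes))
        else:
            diversity = (
                gene_rows.groupby("gene")["pi_whole"].mean().reindex(annotation.genes).fillna(0.0)
            )
            graph = generate_synthetic_network(
                n_focal=len(annotation.genes),
                n_neighbors=config.network_neighbors,
                diversity=diversity.to_numpy(),
                coupling=config.network_coupling,
                edges_per_node=config.network_edges_per_node,
                focal_names=list(diversity.index),
                seed=config.seed + 1,
            )
        correlations = correlate_centrality(gene_rows, graph)
        psio.write_table(correlations, outdir / "correlations.tsv")
        results["correlations"] = correlations
        results["graph"] = graph
        finish_stage(stage)

        stage = "class_tests"
        class_div = class_diversity_table(
            stats_table[["gene", "population", "pi_whole", "pi_cds"]],
            annotation.table["class"],
            B=config.permutations_B,
            seed=config.seed + 2,
        )
        psio.write_table(class_div, outdir / "class_diversity.tsv")
        results["class_diversity"] = class_div
        finish_stage(stage)

        stage = "enrichment"
        all_genes = set(annotation.genes)
        enr_rows = []
        for pop, calls in sorted(calls_by_pop.items()):
            by_dir = {
                "positive": {c.gene_id for c in calls if c.direction == "positive"},
                "balancing": {c.gene_id for c in calls if c.direction == "balancing"},
            }
            by_dir["either"] = by_dir["positive"] | by_dir["balancing"]
            for label in annotation.class_labels():
                genes = set(annotation.genes_in_class(label))
                if not genes:
                    continue
                for mode, selected in by_dir.items():
                    res = fisher_enrichment(
                        selected, genes, all_genes, class_label=label, population=pop, mode=mode
                    )
                    enr_rows.append(res.__dict__)
        enrichment_table = pd.DataFrame(enr_rows)
        psio.write_table(enrichment_table, outdir / "enrichment.tsv")
        results["enrichment"] = enrichment_table
        finish_stage(stage)

        stage = "report"
        finish_stage(stage)
        return results
    except Exception as exc:  # noqa: BLE001 - stage-labelled re-raise
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
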