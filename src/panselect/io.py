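"""Readers and writers for the external formats the pipeline touches.

FASTA (haplotype panels with a tagged outgroup record), BED coding-region
masks, TSV gene annotation tables, TSV/SIF interaction edge lists and TSV
result tables.  All loaders validate strictly and raise ``FormatError``
on malformed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import GeneAlignment
from .network import InteractionGraph

logger = logging.getLogger("panselect")

MAIN_CLASSES = ("Receptors", "Adaptors", "Modulators", "Cytokines", "Effector", "Unclassified")


class FormatError(ValueError):
    """Malformed input file."""


class AmbiguityError(ValueError):
    """Input admits no unique interpretation (e.g. several outgroup records)."""


# ---------------------------------------------------------------------------
# FASTA haplotype panels
# ---------------------------------------------------------------------------

def read_haplotype_fasta(
    path: str | Path,
    outgroup_tag: str = "outgroup",
    gene_id: str | None = None,
    population: str = "panel",
    recomb_rate: float = 1e-8,
    chrom_system: str = "autosomal",
) -> GeneAlignment:
    """Load a haplotype panel with exactly one outgroup record.

    The outgroup is the single record whose id or description contains
    ``outgroup_tag``.  Symbols are uppercased and anything outside
    ``ACGT-N`` becomes ``N``.  Column coordinates default to ``0..L-1``
    unless a record description carries ``positions=p1,p2,...``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 3:
        raise FormatError(f"{path}: need >= 3 records (2 haplotypes + outgroup)")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"{path}: records have unequal lengths {sorted(lengths)}")
    out_idx = [
        i for i, r in enumerate(records) if outgroup_tag in r.id or outgroup_tag in r.description
    ]
    if len(out_idx) != 1:
        raise AmbiguityError(
            f"{path}: expected exactly one record tagged {outgroup_tag!r}, found {len(out_idx)}"
        )
    positions = None
    for r in records:
        for tok in r.description.split():
            if tok.startswith("positions="):
                pos = np.array([int(p) for p in tok[len("positions=") :].split(",")])
                if positions is not None and not np.array_equal(pos, positions):
                    raise FormatError(f"{path}: conflicting positions= headers")
                positions = pos
    outgroup = records[out_idx[0]]
    haps = [r for i, r in enumerate(records) if i != out_idx[0]]
    L = len(outgroup.seq)
    hap_matrix = np.array([list(str(r.seq)) for r in haps], dtype="S1")
    return GeneAlignment(
        gene_id=gene_id or path.stem,
        population=population,
        haplotypes=hap_matrix,
        outgroup=np.array(list(str(outgroup.seq)), dtype="S1"),
        positions=positions if positions is not None else np.arange(L),
        recomb_rate=recomb_rate,
        chrom_system=chrom_system,
    )


def write_haplotype_fasta(aln: GeneAlignment, path: str | Path, outgroup_tag: str = "outgroup") -> None:
    """Write an alignment back to FASTA (outgroup last, tagged)."""
    default_pos = np.array_equal(aln.positions, np.arange(aln.L))
    pos_note = "" if default_pos else " positions=" + ",".join(map(str, aln.positions))
    records = []
    for i in range(aln.n):
        seq = b"".join(aln.haplotypes[i]).decode()
        records.append(
            SeqRecord(Seq(seq), id=f"{aln.gene_id}_hap{i + 1}", description=f"{aln.population}{pos_note}")
        )
    records.append(
        SeqRecord(
            Seq(b"".join(aln.outgroup).decode()),
            id=f"{aln.gene_id}_{outgroup_tag}",
            description=outgroup_tag,
        )
    )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED coding-region masks
# ---------------------------------------------------------------------------

def read_regions_bed(path: str | Path, positions: np.ndarray) -> np.ndarray:
    """Boolean column mask from 0-based half-open BED intervals.

    A column at physical position ``p`` is masked true when some interval
    satisfies ``start <= p < end``.  Overlapping intervals merge silently.
    """
    positions = np.asarray(positions, dtype=np.int64)
    mask = np.zeros(positions.shape[0], dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer interval") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            mask |= (positions >= start) & (positions < end)
    return mask


# ---------------------------------------------------------------------------
# Interaction edge lists (TSV or SIF)
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, focal: set | None = None) -> InteractionGraph:
    """Load an undirected simple graph from a two-column TSV or a SIF file.

    Duplicate edges and self-loops are dropped (counts logged).
    """
    path = Path(path)
    raw_edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if path.suffix.lower() == ".sif":
                if len(fields) == 1:
                    nodes.add(fields[0])
                    continue
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: SIF needs 'node relation node...'")
                src = fields[0]
                nodes.add(src)
                for tgt in fields[2:]:
                    raw_edges.append((src, tgt))
                    nodes.add(tgt)
            else:
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected two id columns")
                if lineno == 1 and fields[0].lower() in ("source", "node1", "a", "from"):
                    continue  # header row
                raw_edges.append((fields[0], fields[1]))
                nodes.update(fields[:2])
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    n_self = sum(1 for u, v in raw_edges if u == v)
    uniq = {tuple(sorted((u, v))) for u, v in raw_edges if u != v}
    n_dup = len(raw_edges) - n_self - len(uniq)
    if n_self or n_dup:
        logger.info("%s: dropped %d self-loops and %d duplicate edges", path, n_self, n_dup)
    g.add_edges_from(uniq)
    focal = set(focal) if focal else set()
    return InteractionGraph(graph=g, focal=frozenset(focal & set(g.nodes)))


# ---------------------------------------------------------------------------
# Gene annotation tables
# ---------------------------------------------------------------------------

@dataclass
class FunctionalAnnotation:
    """Per-gene functional class (one of the main classes), optional
    subclass, and optional per-gene attributes (recomb_rate, dnds)."""

    table: pd.DataFrame  # indexed by gene

    def __post_init__(self) -> None:
        if "class" not in self.table.columns:
            raise FormatError("annotation needs a 'class' column")
        bad = set(self.table["class"]) - set(MAIN_CLASSES)
        if bad:
            raise FormatError(f"unknown class labels: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def gene_class(self, gene: str) -> str:
        return self.table.loc[gene, "class"]

    def genes_in_class(self, label: str, subclass: bool = False) -> list[str]:
        col = "subclass" if subclass else "class"
        if col not in self.table.columns:
            return []
        return list(self.table.index[self.table[col] == label])

    def class_labels(self) -> list[str]:
        return sorted(self.table["class"].unique())


def read_gene_table(path: str | Path) -> FunctionalAnnotation:
    """Load the gene annotation TSV (columns: gene, class[, subclass,
    recomb_rate, dnds, chrom_system, populations])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicated gene ids")
    return FunctionalAnnotation(table=df.set_index("gene"))


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path) -> None:
    """Write a result table (DataFrame or list of dataclass-like records)
    to TSV, loss-free for round-tripping with :func:`read_table`."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r for r in records])
    records.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
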