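"""Core in-memory container for per-gene haplotype data.

A :class:`GeneAlignment` holds the phased haplotype matrix for one gene in
one population together with a single outgroup sequence used to orient
(ancestral vs derived) the segregating alleles.  Rows are chromosomes, not
individuals; phase is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Recognised alignment symbols.  Anything else is coerced to ``N`` on load.
SYMBOLS = b"ACGT-N"

A, C, G, T, GAP, MISSING = range(6)

_CODE_LUT = np.full(256, MISSING, dtype=np.uint8)
for _i, _ch in enumerate(SYMBOLS):
    _CODE_LUT[_ch] = _i
    _CODE_LUT[ord(chr(_ch).lower())] = _i

_DECODE = np.frombuffer(SYMBOLS, dtype="S1")


def encode(seqs: np.ndarray) -> np.ndarray:
    """Map an ``S1`` byte array onto the internal 0..5 symbol codes."""
    return _CODE_LUT[np.asarray(seqs, dtype="S1").view(np.uint8)]


def decode(codes: np.ndarray) -> np.ndarray:
    return _DECODE[np.asarray(codes, dtype=np.uint8)]


class AlignmentFormatError(ValueError):
    """Raised when input haplotype data violates the container invariants."""


@dataclass
class GeneAlignment:
    """Haplotype matrix plus outgroup for one gene in one population.

    Parameters
    ----------
    haplotypes
        ``(n, L)`` array of single-byte symbols (``ACGT-N``); ``n >= 2``.
    outgroup
        Length-``L`` vector of the same symbols from a close species
        (e.g. chimpanzee), used to polarize derived alleles.
    positions
        Strictly increasing integer physical coordinates, one per column.
    cds_mask
        Optional boolean vector marking coding columns.
    recomb_rate
        Local per-site per-generation crossover rate for the region.
    chrom_system
        ``"autosomal"`` or ``"X"``; recorded for reporting only, no
        effective-size correction is applied.
    """

    gene_id: str
    population: str
    haplotypes: np.ndarray
    outgroup: np.ndarray
    positions: np.ndarray
    cds_mask: np.ndarray | None = None
    recomb_rate: float = 1e-8
    chrom_system: str = "autosomal"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype="S1")
        self.outgroup = np.asarray(self.outgroup, dtype="S1").ravel()
        self.positions = np.asarray(self.positions, dtype=np.int64).ravel()
        if self.haplotypes.ndim != 2:
            raise AlignmentFormatError("haplotypes must be a 2-D matrix")
        n, L = self.haplotypes.shape
        if n < 2:
            raise AlignmentFormatError(f"need >=2 haplotypes, got {n}")
        if self.outgroup.shape[0] != L:
            raise AlignmentFormatError(
                f"outgroup length {self.outgroup.shape[0]} != alignment length {L}"
            )
        if self.positions.shape[0] != L:
            raise AlignmentFormatError("positions length must equal alignment length")
        if L > 1 and not np.all(np.diff(self.positions) > 0):
            raise AlignmentFormatError("positions must be strictly increasing")
        if self.cds_mask is not None:
            self.cds_mask = np.asarray(self.cds_mask, dtype=bool).ravel()
            if self.cds_mask.shape[0] != L:
                raise AlignmentFormatError("cds_mask length must equal alignment length")
        if self.recomb_rate < 0:
            raise AlignmentFormatError("recomb_rate must be >= 0")
        if self.chrom_system not in ("autosomal", "X"):
            raise AlignmentFormatError(f"unknown chrom_system {self.chrom_system!r}")
        # normalise symbols once: uppercase, unknowns -> N
        self.haplotypes = decode(encode(self.haplotypes)).reshape(n, L)
        self.outgroup = decode(encode(self.outgroup))

    @property
    def n(self) -> int:
        """Number of sampled chromosomes."""
        return self.haplotypes.shape[0]

    @property
    def L(self) -> int:
        """Number of aligned columns."""
        return self.haplotypes.shape[1]

    def codes(self) -> np.ndarray:
        """Haplotype matrix as 0..5 integer codes (A,C,G,T,-,N)."""
        return encode(self.haplotypes)

    def outgroup_codes(self) -> np.ndarray:
        return encode(self.outgroup)

    def subset(self, column_mask: np.ndarray) -> "GeneAlignment":
        """Restrict the alignment to the columns where ``column_mask`` is true."""
        column_mask = np.asarray(column_mask, dtype=bool).ravel()
        if column_mask.shape[0] != self.L:
            raise AlignmentFormatError("column mask length must equal alignment length")
        return GeneAlignment(
            gene_id=self.gene_id,
            population=self.population,
            haplotypes=self.haplotypes[:, column_mask],
            outgroup=self.outgroup[column_mask],
            positions=self.positions[column_mask],
            cds_mask=None if self.cds_mask is None else self.cds_mask[column_mask],
            recomb_rate=self.recomb_rate,
            chrom_system=self.chrom_system,
        )

    @classmethod
    def from_binary(
        cls,
        genotypes: np.ndarray,
        gene_id: str = "sim",
        population: str = "sim",
        positions: np.ndarray | None = None,
        total_length: int | None = None,
        recomb_rate: float = 1e-8,
    ) -> "GeneAlignment":
        """Build a nucleotide alignment from a 0/1 (ancestral/derived) matrix.

        Ancestral alleles are written ``A`` and derived ``G``; the outgroup
        carries the ancestral allele everywhere, so simulated data are fully
        polarizable.  When ``total_length`` exceeds the number of variant
        columns, monomorphic ``A`` columns pad the alignment so that per-site
        quantities are on the intended scale.
        """
        genotypes = np.asarray(genotypes)
        n, s = genotypes.shape
        L = int(total_length) if total_length is not None else s
        if L < s:
            raise AlignmentFormatError("total_length smaller than variant count")
        if positions is None:
            # spread variant columns evenly over the locus
            positions = np.linspace(0, max(L - 1, s - 1), num=s, dtype=np.int64) if s else np.empty(0, np.int64)
            positions = np.unique(positions)
            while positions.size < s:  # collisions only for tiny L
                positions = np.arange(s, dtype=np.int64)
        hap = np.full((n, L), b"A", dtype="S1")
        out = np.full(L, b"A", dtype="S1")
        col_pos = np.arange(L, dtype=np.int64)
        if s:
            idx = np.searchsorted(col_pos, np.asarray(positions, dtype=np.int64))
            hap[:, idx] = np.where(genotypes.astype(bool), b"G", b"A")
        return cls(
            gene_id=gene_id,
            population=population,
            haplotypes=hap,
            outgroup=out,
            positions=col_pos,
            recomb_rate=recomb_rate,
        )
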