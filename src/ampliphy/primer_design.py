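"""Conserved-block detection and degenerate consensus primer design.

Given a multiple alignment of homologous marker genes, this module
profiles each column, locates maximal conserved windows (low gap
content, bounded cumulative degeneracy) and turns them into degenerate
IUPAC primers. Coordinates are 1-based inclusive throughout; block
positions can be projected onto a named reference row, skipping gap
columns, which is how "position on the reference gene" is reported.

The module also ships the packaged screening panel: six degenerate
primers targeting the bifidobacterial bile salt hydrolase (*bsh*) gene,
anchored at reference positions 1, 46, 448 and 505. Forward primers are
stored in plus-strand sense; reverse primers are stored 5'->3' on their
strand of synthesis (the reverse complement of the plus-strand
consensus), as primers are conventionally written.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from Bio import AlignIO

from .core_seq import (
    BASES_TO_CODE,
    GAP,
    IUPAC_BASES,
    NucSeq,
    degeneracy,
    revcomp_str,
)

logger = logging.getLogger(__name__)

Orientation = Literal["forward", "reverse"]


class DesignError(ValueError):
    """Primer design constraint violated (e.g. degeneracy cap exceeded)."""


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment of :class:`NucSeq` rows.

    ``reference_id`` optionally names the row used to project alignment
    columns onto ungapped reference coordinates.
    """

    rows: tuple[NucSeq, ...]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        if self.reference_id is not None and self.reference_id not in ids:
            raise ValueError(f"reference row {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        """Residues of 1-based column ``i`` across rows."""
        return "".join(r.residues[i - 1] for r in self.rows)

    @classmethod
    def from_seqs(cls, seqs: Sequence[NucSeq], reference_id: str | None = None) -> "Alignment":
        rows = tuple(
            NucSeq(s.id, s.residues, s.description, allow_gaps=True) for s in seqs
        )
        return cls(rows, reference_id)

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None,
             reference_id: str | None = None) -> "Alignment":
        """Read an aligned FASTA or Clustal (.aln) file."""
        if fmt is None:
            fmt = "clustal" if str(path).endswith((".aln", ".clustal")) else "fasta"
        aln = AlignIO.read(str(path), fmt)
        rows = tuple(
            NucSeq(rec.id, str(rec.seq), allow_gaps=True) for rec in aln
        )
        return cls(rows, reference_id)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column composition summary of an alignment.

    ``is_identical`` flags columns where exactly one concrete base is
    observed and no row has a gap — the columns a by-eye alignment view
    would mark with an asterisk.
    """

    column_index: int  # 1-based
    base_counts: dict[str, int]
    gap_fraction: float
    consensus_code: str
    is_identical: bool

    @property
    def degeneracy(self) -> int:
        return len(IUPAC_BASES[self.consensus_code])


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal conserved window of alignment columns.

    ``start``/``end`` are 1-based inclusive alignment columns;
    ``reference_start`` is the projection of ``start`` onto the ungapped
    reference row. ``degeneracy`` is the product of per-column consensus
    code sizes; ``mean_identity`` the fraction of fully identical columns.
    """

    start: int
    end: int
    reference_start: int
    consensus: str
    degeneracy: int
    mean_identity: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.consensus):
            raise ValueError("block span does not match consensus length")


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named 5'->3' degenerate oligonucleotide.

    ``anchor`` is the 1-based reference position of the 5'-most template
    base of the primer footprint on the plus strand. ``tm_range`` is a
    Wallace-rule melting window over the AT-richest and GC-richest
    expansions.
    """

    name: str
    seq_5to3: str
    orientation: Orientation
    anchor: int | None = None
    tm_range: tuple[float, float] | None = None
    degeneracy: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq_5to3", self.seq_5to3.upper())
        for i, c in enumerate(self.seq_5to3):
            if c not in IUPAC_BASES:
                raise DesignError(
                    f"primer {self.name!r}: invalid residue {c!r} at position {i + 1}"
                )
        object.__setattr__(self, "degeneracy", degeneracy(self.seq_5to3))
        if self.orientation not in ("forward", "reverse"):
            raise DesignError(f"primer {self.name!r}: bad orientation")
        if self.tm_range is None:
            object.__setattr__(self, "tm_range", tm_estimate(self.seq_5to3))

    def __len__(self) -> int:
        return len(self.seq_5to3)

    @property
    def plus_strand(self) -> str:
        """Primer footprint written in plus-strand (template) sense."""
        if self.orientation == "forward":
            return self.seq_5to3
        return revcomp_str(self.seq_5to3)


def tm_estimate(residues: str) -> tuple[float, float]:
    """Wallace-rule melting temperature window, 2(A+T) + 4(G+C) in Celsius.

    Each degenerate position contributes its cheapest base to the minimum
    (an A/T counts 2) and its dearest to the maximum (a G/C counts 4), so
    the bounds are attained by the AT-richest and GC-richest expansions.
    """
    lo = hi = 0.0
    for c in residues.upper():
        weights = [2.0 if b in "AT" else 4.0 for b in IUPAC_BASES[c]]
        lo += min(weights)
        hi += max(weights)
    return lo, hi


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """Profile every alignment column, in order.

    The consensus code is the minimal IUPAC code covering all bases
    observed in the column (degenerate row residues contribute their
    whole base set).
    """
    profiles: list[ColumnProfile] = []
    n = aln.n_rows
    for i in range(1, aln.length + 1):
        col = aln.column(i)
        counts = {b: 0 for b in "ACGT"}
        observed: set[str] = set()
        gaps = 0
        for ch in col:
            if ch == GAP:
                gaps += 1
                continue
            bases = IUPAC_BASES[ch]
            observed |= bases
            if len(bases) == 1:
                counts[ch] += 1
        consensus = BASES_TO_CODE[frozenset(observed)] if observed else "N"
        is_identical = gaps == 0 and len(observed) == 1
        profiles.append(
            ColumnProfile(
                column_index=i,
                base_counts=counts,
                gap_fraction=gaps / n,
                consensus_code=consensus,
                is_identical=is_identical,
            )
        )
    return profiles


def _reference_positions(aln: Alignment) -> list[int]:
    """For each 1-based column, the count of non-gap reference residues up
    to and including that column. Without a reference row, columns map to
    themselves."""
    if aln.reference_id is None:
        return list(range(1, aln.length + 1))
    ref = next(r for r in aln.rows if r.id == aln.reference_id)
    out: list[int] = []
    seen = 0
    for ch in ref.residues:
        if ch != GAP:
            seen += 1
        out.append(seen)
    return out


def find_conserved_blocks(
    aln: Alignment,
    min_len: int = 17,
    max_block_degeneracy: int = 64,
    max_gap_fraction: float = 0.0,
) -> list[ConservedBlock]:
    """Locate maximal conserved windows suitable for primer placement.

    A window is conserved when every column's gap fraction is at most
    ``max_gap_fraction`` and the cumulative consensus degeneracy (product
    of per-column code sizes) stays within ``max_block_degeneracy``.
    Windows are grown greedily left to right to maximal length; reported
    blocks are non-overlapping, sorted, and at least ``min_len`` columns
    long. Ties are resolved leftmost, which makes the result independent
    of row order and reproducible.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    if min_len > aln.length:
        logger.warning(
            "min_len %d exceeds alignment length %d: no blocks", min_len, aln.length
        )
        return []
    profiles = column_profiles(aln)
    ref_pos = _reference_positions(aln)
    ref_is_gap: list[bool] = (
        [False] * aln.length
        if aln.reference_id is None
        else [
            ch == GAP
            for ch in next(r for r in aln.rows if r.id == aln.reference_id).residues
        ]
    )

    blocks: list[ConservedBlock] = []
    i = 0  # 0-based start column under consideration
    L = aln.length
    while i < L:
        if profiles[i].gap_fraction > max_gap_fraction:
            i += 1
            continue
        deg = 1
        j = i
        while j < L and profiles[j].gap_fraction <= max_gap_fraction:
            next_deg = deg * profiles[j].degeneracy
            if next_deg > max_block_degeneracy:
                break
            deg = next_deg
            j += 1
        if j - i >= min_len:
            consensus = "".join(p.consensus_code for p in profiles[i:j])
            ident = sum(p.is_identical for p in profiles[i:j]) / (j - i)
            start = i + 1
            ref_start = ref_pos[i]
            if ref_is_gap[i]:
                ref_start += 1
                logger.info(
                    "block at column %d starts in a reference gap; "
                    "reporting next reference position %d",
                    start,
                    ref_start,
                )
            blocks.append(
                ConservedBlock(
                    start=start,
                    end=j,
                    reference_start=ref_start,
                    consensus=consensus,
                    degeneracy=deg,
                    mean_identity=ident,
                )
            )
            i = j
        else:
            i += 1
    return blocks


def block_to_primer(
    block: ConservedBlock,
    orientation: Orientation,
    name: str,
    max_degeneracy: int = 256,
) -> DegeneratePrimer:
    """Emit a degenerate primer from a conserved block.

    Forward primers take the consensus as-is; reverse primers take its
    reverse complement (the strand of synthesis). The anchor records the
    block's reference start either way, i.e. the 5'-most plus-strand
    template position of the footprint.
    """
    if block.degeneracy > max_degeneracy:
        raise DesignError(
            f"block degeneracy {block.degeneracy} exceeds primer cap {max_degeneracy}"
        )
    seq = block.consensus if orientation == "forward" else revcomp_str(block.consensus)
    return DegeneratePrimer(
        name=name, seq_5to3=seq, orientation=orientation, anchor=block.reference_start
    )


# ---------------------------------------------------------------------------
# Packaged bsh screening panel
# ---------------------------------------------------------------------------

#: Six degenerate primers targeting conserved regions of bifidobacterial
#: bsh genes. Anchors are 1-based positions of the plus-strand footprint
#: start on the B. bifidum ATCC 29521 bsh reference (accession AY604517):
#: forward sites at 1 and 46, reverse sites at 448 and 505. Bif-bshB-2F is
#: stored as a contiguous 23-mer (the published table breaks it with a
#: spurious internal space). Bif-bshE-3F / Bif-bshF-3R are refined internal
#: variants of the position-46 / position-448 primers used for RT-PCR.
PRIMER_PANEL: dict[str, DegeneratePrimer] = {
    p.name: p
    for p in (
        DegeneratePrimer("Bif-bshA-1F", "ATGTGCACWGSYGTYCGTTT", "forward", anchor=1),
        DegeneratePrimer("Bif-bshB-2F", "TTCGGCCGYAAYCTCGAYTGGAG", "forward", anchor=46),
        DegeneratePrimer("Bif-bshC-1R", "TCGAYGACGATGCTDCG", "reverse", anchor=448),
        DegeneratePrimer("Bif-bshD-2R", "GGYTGRTTGGTVAGCACRTC", "reverse", anchor=505),
        DegeneratePrimer("Bif-bshE-3F", "TTCGGCCGYAAYCTYGAYTGG", "forward", anchor=46),
        DegeneratePrimer("Bif-bshF-3R", "TCGAYGACGATGSTDCG", "reverse", anchor=448),
    )
}

_TSV_FIELDS = ["name", "sequence", "orientation", "degeneracy", "anchor", "tm_min", "tm_max"]


def write_panel_tsv(primers: Sequence[DegeneratePrimer], path: str | Path) -> None:
    """Write a primer panel as TSV (name, sequence, orientation, degeneracy,
    anchor, tm_min, tm_max)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_FIELDS)
        for p in primers:
            w.writerow(
                [p.name, p.seq_5to3, p.orientation, p.degeneracy,
                 "" if p.anchor is None else p.anchor,
                 p.tm_range[0], p.tm_range[1]]
            )


def read_panel_tsv(path: str | Path) -> dict[str, DegeneratePrimer]:
    """Read a primer panel TSV back into named primers."""
    out: dict[str, DegeneratePrimer] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            anchor = int(row["anchor"]) if row.get("anchor") else None
            p = DegeneratePrimer(
                row["name"], row["sequence"], row["orientation"], anchor=anchor
            )
            out[p.name] = p
    return out


def write_panel_fasta(primers: Sequence[DegeneratePrimer], path: str | Path) -> None:
    from .core_seq import write_fasta

    write_fasta(
        [NucSeq(p.name, p.seq_5to3, f"{p.orientation} degeneracy={p.degeneracy}")
         for p in primers],
        path,
    )
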