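"""IUPAC nucleotide algebra and FASTA I/O.

This module is the foundation of the toolkit: a validated nucleotide
sequence type over the full 15-letter IUPAC ambiguity alphabet, the
set-algebra operations that make degenerate oligonucleotides work
(reverse complement, expansion, code compatibility), and strict FASTA
round-tripping.

All sequences are canonicalized to upper case on ingest; ``U`` is
transliterated to ``T`` (RNA-derived records) with a logged warning.
The gap character ``-`` is accepted only where an alignment context
explicitly allows it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"

#: The 15 standard IUPAC nucleotide codes mapped to their base sets.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse lookup: base set -> unique IUPAC symbol.
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

#: IUPAC-aware complement (an involution on the 15 codes).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "W": "W", "S": "S",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

# 4-bit encoding (A=1, C=2, G=4, T=8); two codes are compatible iff the
# bitwise AND of their masks is non-zero.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
CODE_BITS: dict[str, int] = {
    code: reduce(lambda acc, b: acc | _BASE_BITS[b], bases, 0)
    for code, bases in IUPAC_BASES.items()
}

ALPHABET = frozenset(IUPAC_BASES) | {GAP}


class AlphabetError(ValueError):
    """A residue outside the declared IUPAC alphabet (or a misplaced gap)."""


class FastaFormatError(ValueError):
    """Malformed FASTA input: duplicate ids or empty records."""


def _canonicalize(residues: str, seq_id: str) -> str:
    out = residues.upper()
    if "U" in out:
        logger.warning("sequence %r: transliterating U -> T (RNA input)", seq_id)
        out = out.replace("U", "T")
    return out


@dataclass(frozen=True)
class NucSeq:
    """An identified nucleotide string over the IUPAC alphabet.

    Parameters
    ----------
    id : str
        Record label; must be unique within any one collection.
    residues : str
        Sequence over ``{A,C,G,T,R,Y,S,W,K,M,B,D,H,V,N}`` plus ``-`` when
        ``allow_gaps`` is set. Lower case and ``U`` are normalized on
        construction.
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    description: str = ""
    allow_gaps: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _canonicalize(self.residues, self.id))
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        allowed = ALPHABET if self.allow_gaps else frozenset(IUPAC_BASES)
        for i, ch in enumerate(self.residues):
            if ch not in allowed:
                raise AlphabetError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def ungapped(self) -> "NucSeq":
        """Copy with gap characters removed (returns self when gap-free)."""
        if GAP not in self.residues:
            return self
        return NucSeq(self.id, self.residues.replace(GAP, ""), self.description)


def _check_no_gaps(residues: str, what: str) -> None:
    pos = residues.find(GAP)
    if pos != -1:
        raise AlphabetError(f"{what}: gap character at position {pos + 1}")


def revcomp_str(residues: str) -> str:
    """Reverse complement of a gap-free IUPAC string (IUPAC-aware)."""
    _check_no_gaps(residues, "revcomp")
    try:
        return "".join(COMPLEMENT[c] for c in reversed(residues.upper()))
    except KeyError as exc:
        bad = exc.args[0]
        raise AlphabetError(
            f"revcomp: invalid residue {bad!r} at position "
            f"{residues.upper().index(bad) + 1}"
        ) from None


def revcomp(seq: NucSeq) -> NucSeq:
    """Reverse complement; complementation maps each code to the code of the
    complemented base set (W<->W, S<->S, Y<->R, K<->M, B<->V, D<->H, N<->N)."""
    return NucSeq(seq.id, revcomp_str(seq.residues), seq.description)


def degeneracy(residues: str) -> int:
    """Number of concrete ACGT strings a degenerate string encodes
    (product of per-position code sizes); computed without enumeration."""
    _check_no_gaps(residues, "degeneracy")
    n = 1
    for c in residues.upper():
        if c not in IUPAC_BASES:
            raise AlphabetError(f"degeneracy: invalid residue {c!r}")
        n *= len(IUPAC_BASES[c])
    return n


def expand_degenerate(residues: str, cap: int = 65536) -> set[str]:
    """All concrete ``{A,C,G,T}`` strings obtainable by substituting each
    ambiguity code with one of its bases.

    Refuses (with the computed cardinality) when the expansion would exceed
    ``cap``, so a stray N-rich input cannot blow up memory.
    """
    residues = residues.upper()
    card = degeneracy(residues)
    if card > cap:
        raise ValueError(
            f"expansion cardinality {card} exceeds safety cap {cap}"
        )
    out = [""]
    for c in residues:
        bases = sorted(IUPAC_BASES[c])
        out = [prefix + b for prefix in out for b in bases]
    return set(out)


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect (symmetric)."""
    try:
        return (CODE_BITS[a.upper()] & CODE_BITS[b.upper()]) != 0
    except KeyError as exc:
        raise AlphabetError(f"iupac_match: invalid code {exc.args[0]!r}") from None


def encode_bits(residues: str) -> list[int]:
    """4-bit mask encoding of a gap-free IUPAC string (A=1,C=2,G=4,T=8)."""
    _check_no_gaps(residues, "encode_bits")
    try:
        return [CODE_BITS[c] for c in residues.upper()]
    except KeyError as exc:
        raise AlphabetError(f"encode_bits: invalid residue {exc.args[0]!r}") from None


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[NucSeq]:
    """Read a multi-record FASTA file into validated :class:`NucSeq` records.

    Raises :class:`FastaFormatError` on duplicate ids or empty records,
    naming the offending record.
    """
    records: list[NucSeq] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seen:
            raise FastaFormatError(f"record {idx}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FastaFormatError(f"record {idx} ({rec.id!r}): empty sequence")
        records.append(
            NucSeq(rec.id, str(rec.seq), rec.description.removeprefix(rec.id).strip(),
                   allow_gaps=allow_gaps)
        )
    return records


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    seqs = list(seqs)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise FastaFormatError("duplicate ids in output collection")
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def iter_windows(residues: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield (0-based offset, substring) for every length-k window."""
    for i in range(len(residues) - k + 1):
        yield i, residues[i : i + k]
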