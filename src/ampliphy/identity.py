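"""Pairwise global alignment and percent-identity matrices.

"Similarity" between two marker-gene fragments is operationalized as
the percent identity of an optimal end-to-end (Needleman-Wunsch) affine
gap alignment, with terminal gap overhangs excluded from the column
count — the statistic behind the printed percentages of marker-gene
surveys. Alignments are computed with Biopython's ``PairwiseAligner``
(match +1, mismatch -1, first gap residue -2, each further gap residue
-1 by default); the first optimal alignment in the aligner's
deterministic enumeration order is used, so results are reproducible.
Percentages are reported to one decimal place.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .core_seq import GAP, NucSeq

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedPair:
    """One global pairwise alignment with its identity statistic."""

    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows have unequal lengths")


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric matrix of pairwise percent identities (diagonal 100)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.all(np.diag(v) == 100.0):
            raise ValueError("diagonal must be exactly 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        # printed at the survey's one-decimal reporting precision
        self.to_dataframe().to_csv(path, sep="\t", index_label="id",
                                   float_format="%.1f")

    def summary(self) -> dict:
        """Off-diagonal minimum/maximum and the pairs attaining them."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        vals = self.values[iu]
        kmin, kmax = int(np.argmin(vals)), int(np.argmax(vals))
        return {
            "min": float(vals[kmin]),
            "max": float(vals[kmax]),
            "argmin": (self.labels[iu[0][kmin]], self.labels[iu[1][kmin]]),
            "argmax": (self.labels[iu[0][kmax]], self.labels[iu[1][kmax]]),
        }


def _aligner(match: float, mismatch: float, gap_open: float,
             gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def global_align(
    a: NucSeq,
    b: NucSeq,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> AlignedPair:
    """Optimal global alignment of two gap-free sequences.

    ``gap_open`` is the score of the first residue of a gap and
    ``gap_extend`` of each subsequent one, so a length-k gap scores
    ``gap_open + (k-1)*gap_extend``.
    """
    for s in (a, b):
        if GAP in s.residues:
            raise ValueError(f"sequence {s.id!r} contains gaps")
        if not s.residues:
            raise ValueError(f"sequence {s.id!r} is empty")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    ga, gb = aln[0], aln[1]
    pair = AlignedPair(a.id, b.id, ga, gb, float(aln.score), 0.0)
    pct = percent_identity(pair)
    return AlignedPair(a.id, b.id, ga, gb, float(aln.score), pct)


def percent_identity(
    pair: AlignedPair, mode: str = "exclude_terminal_gaps",
    decimals: int | None = 1,
) -> float:
    """Percent identity of an aligned pair, reported to one decimal place
    by default (``decimals=None`` keeps full precision, used internally
    when identities feed distance calculations).

    Columns inside a terminal gap overhang of either row are excluded
    (``exclude_terminal_gaps``, the default) or included (``all``);
    matches require identical concrete symbols.
    """
    ga, gb = pair.gapped_a, pair.gapped_b
    n = len(ga)
    if mode == "exclude_terminal_gaps":
        def core(s: str) -> tuple[int, int]:
            first = n - len(s.lstrip(GAP))
            last = len(s.rstrip(GAP)) - 1
            return first, last

        a0, a1 = core(ga)
        b0, b1 = core(gb)
        lo, hi = max(a0, b0), min(a1, b1)
    elif mode == "all":
        lo, hi = 0, n - 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if hi < lo:
        raise ValueError("no countable columns after terminal-gap exclusion")
    cols = hi - lo + 1
    matches = sum(
        1 for x, y in zip(ga[lo : hi + 1], gb[lo : hi + 1]) if x == y and x != GAP
    )
    pct = 100.0 * matches / cols
    return pct if decimals is None else round(pct, decimals)


def identity_matrix(seqs: Sequence[NucSeq], **align_kwargs) -> IdentityMatrix:
    """Percent-identity matrix over all unordered pairs of sequences.

    Extra keyword arguments are passed through to :func:`global_align`.
    Entries carry full precision (rounding happens on output) so that
    downstream distance calculations lose no resolution. The
    off-diagonal range and its attaining pairs are logged, which is
    usually the headline number of a survey ("identities ranged from x
    to y percent").
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    vals = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        pair = global_align(seqs[i], seqs[j], **align_kwargs)
        vals[i, j] = vals[j, i] = percent_identity(pair, decimals=None)
    m = IdentityMatrix(tuple(ids), vals)
    s = m.summary()
    logger.info(
        "identity range %.1f%% (%s vs %s) to %.1f%% (%s vs %s)",
        s["min"], *s["argmin"], s["max"], *s["argmax"],
    )
    return m
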