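"""In-silico PCR: binding-site search and amplicon prediction.

A degenerate primer binds a template window when, position by position,
the primer code and the template code share at least one concrete base
(so sequencing ambiguities in the template still count as compatible).
A site is accepted when its total mismatch count and its mismatch count
inside the 3'-terminal window both stay within the configured bounds —
the 3' anchor mirrors the polymerase's requirement for a matched
extension end; by default the last 3 bases must match exactly.

Products are reported for every forward-site/reverse-site pair in the
allowed size range; the product length counts both primer footprints
inclusively, so a forward footprint at 1-20 paired with a reverse
footprint at 505-524 yields a 524 bp product. Coordinates are 1-based
inclusive on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_seq import NucSeq, encode_bits, revcomp_str
from .primer_design import DegeneratePrimer


@dataclass(frozen=True)
class PCRConfig:
    """Stringency settings for the in-silico reaction."""

    max_mismatch: int = 2
    three_prime_window: int = 3
    three_prime_max_mismatch: int = 0
    min_product: int = 50
    max_product: int = 5000

    def __post_init__(self) -> None:
        for name in ("max_mismatch", "three_prime_window",
                     "three_prime_max_mismatch", "min_product", "max_product"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_product > self.max_product:
            raise ValueError("min_product must be <= max_product")


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on the plus strand of a template.

    ``start``/``end`` are 1-based inclusive template coordinates; on the
    minus strand the primer's 3' end sits at ``start``.
    """

    template_id: str
    start: int
    end: int
    strand: Literal["plus", "minus"]
    mismatches: int
    three_prime_mismatches: int
    primer_name: str


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product delimited inclusively by two footprints."""

    template_id: str
    start: int
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite
    sequence: NucSeq

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _scan(template_bits: np.ndarray, primer_bits: np.ndarray,
          three_prime_cols: slice) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mismatch counts for every window of the template against one primer
    reading frame; returns (offsets, total mismatches, 3'-window mismatches)."""
    k = len(primer_bits)
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, k)
    mism = (windows & primer_bits) == 0
    total = mism.sum(axis=1)
    tp = mism[:, three_prime_cols].sum(axis=1)
    offsets = np.arange(len(total))
    return offsets, total, tp


def find_binding_sites(
    template: NucSeq, primer: DegeneratePrimer, cfg: PCRConfig = PCRConfig()
) -> list[BindingSite]:
    """All acceptable footprints of ``primer`` on both strands of ``template``.

    The plus strand is scanned with the primer in forward sense and the
    minus strand with the primer in reverse sense (i.e. the primer's
    reverse complement against the plus strand). Sites are sorted by
    start coordinate. A primer longer than the template has no sites.
    """
    k = len(primer)
    if k > len(template):
        return []
    tmpl_bits = np.asarray(encode_bits(template.residues), dtype=np.uint8)
    w = min(cfg.three_prime_window, k)
    sites: list[BindingSite] = []

    # plus strand: primer 3' end at the window's right edge
    fwd_bits = np.asarray(encode_bits(primer.seq_5to3), dtype=np.uint8)
    for off, total, tp in zip(*_scan(tmpl_bits, fwd_bits, slice(k - w, k))):
        if total <= cfg.max_mismatch and tp <= cfg.three_prime_max_mismatch:
            sites.append(
                BindingSite(template.id, int(off) + 1, int(off) + k, "plus",
                            int(total), int(tp), primer.name)
            )

    # minus strand: primer 3' end at the window's left edge
    rev_bits = np.asarray(encode_bits(revcomp_str(primer.seq_5to3)), dtype=np.uint8)
    for off, total, tp in zip(*_scan(tmpl_bits, rev_bits, slice(0, w))):
        if total <= cfg.max_mismatch and tp <= cfg.three_prime_max_mismatch:
            sites.append(
                BindingSite(template.id, int(off) + 1, int(off) + k, "minus",
                            int(total), int(tp), primer.name)
            )

    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    template: NucSeq,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    cfg: PCRConfig = PCRConfig(),
) -> list[Amplicon]:
    """Predicted products of a primer pair on one template.

    Every plus-strand site of the forward primer is paired with every
    downstream minus-strand site of the reverse primer; pairs whose
    inclusive span falls within ``[min_product, max_product]`` become
    amplicons. Templates with no compatible site pair (e.g. a gene the
    panel does not target) yield an empty list.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("predict_amplicons needs a forward and a reverse primer")
    fwd_sites = [s for s in find_binding_sites(template, fwd, cfg) if s.strand == "plus"]
    rev_sites = [s for s in find_binding_sites(template, rev, cfg) if s.strand == "minus"]
    out: list[Amplicon] = []
    for fs in fwd_sites:
        for rs in rev_sites:
            if fs.start >= rs.start:
                continue
            length = rs.end - fs.start + 1
            if not (cfg.min_product <= length <= cfg.max_product):
                continue
            seq = NucSeq(
                f"{template.id}:{fs.start}-{rs.end}",
                template.residues[fs.start - 1 : rs.end],
                f"{fwd.name}/{rev.name} product {length} bp",
            )
            out.append(Amplicon(template.id, fs.start, rs.end, fs, rs, seq))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def virtual_gel(amplicons_by_template: Mapping[str, Sequence[Amplicon]]) -> pd.DataFrame:
    """Tabular stand-in for an agarose gel.

    One row per template: sorted unique band lengths (duplicates collapse,
    as co-migrating products would) and a presence/absence flag. Row order
    follows the input mapping, so the table is deterministic.
    """
    rows = []
    for tid, amps in amplicons_by_template.items():
        bands = sorted({a.length for a in amps})
        rows.append(
            {
                "template_id": tid,
                "n_products": len(amps),
                "bands_bp": ",".join(str(b) for b in bands),
                "positive": bool(bands),
            }
        )
    return pd.DataFrame(rows, columns=["template_id", "n_products", "bands_bp", "positive"])
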