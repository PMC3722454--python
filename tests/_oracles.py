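"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained (own IUPAC
table, recursive enumeration, exhaustive scans) so that agreement with
the package is evidence, not circularity.
"""

from __future__ import annotations

import functools
import itertools

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def enumerate_expansions(s: str) -> list[str]:
    """All concrete strings of a degenerate string, by recursion."""
    if not s:
        return [""]
    rest = enumerate_expansions(s[1:])
    return [b + r for b in ORACLE_IUPAC[s[0]] for r in rest]


def oracle_revcomp(s: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def comp_code(code: str) -> str:
        bases = frozenset(comp[b] for b in ORACLE_IUPAC[code])
        for k, v in ORACLE_IUPAC.items():
            if frozenset(v) == bases:
                return k
        raise AssertionError(code)

    return "".join(comp_code(c) for c in reversed(s))


def codes_compatible(a: str, b: str) -> bool:
    return bool(set(ORACLE_IUPAC[a]) & set(ORACLE_IUPAC[b]))


# ---------------------------------------------------------------------------
# binding sites: exhaustive expansion scan
# ---------------------------------------------------------------------------

def oracle_binding_sites(template: str, primer: str, max_mismatch: int,
                         tp_window: int, tp_max: int) -> list[tuple[int, int, str]]:
    """(start, end, strand) of every acceptable footprint, 1-based, by
    comparing every window against every concrete primer expansion.

    The mismatch count of a window is the minimum Hamming distance over
    expansions; the 3' count likewise (positions are independent, so the
    per-window minima are attained jointly).
    """
    k = len(primer)
    exps = enumerate_expansions(primer)
    rc_exps = enumerate_expansions(oracle_revcomp(primer))
    w = min(tp_window, k)
    out = []
    for off in range(len(template) - k + 1):
        win = template[off : off + k]
        # plus strand: 3' end of primer at right edge of window
        mm = min(sum(x != y for x, y in zip(e, win)) for e in exps)
        tp = min(sum(x != y for x, y in zip(e[k - w :], win[k - w :])) for e in exps)
        if mm <= max_mismatch and tp <= tp_max:
            out.append((off + 1, off + k, "plus"))
        # minus strand: primer 3' end at left edge
        mm = min(sum(x != y for x, y in zip(e, win)) for e in rc_exps)
        tp = min(sum(x != y for x, y in zip(e[:w], win[:w])) for e in rc_exps)
        if mm <= max_mismatch and tp <= tp_max:
            out.append((off + 1, off + k, "minus"))
    return out


# ---------------------------------------------------------------------------
# global alignment: exhaustive path enumeration / independent recursion
# ---------------------------------------------------------------------------

def _score_gapped(ga: str, gb: str, match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> float:
    """Score a gapped pair: each maximal gap run costs open + (k-1)*extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ga, gb):
        if x == "-":
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every (gapped_a, gapped_b) global alignment (no gap-gap column)."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb


def oracle_align_score_exhaustive(a: str, b: str, match=1.0, mismatch=-1.0,
                                  gap_open=-2.0, gap_extend=-1.0) -> float:
    """Optimal global score by scoring every alignment path (lengths <= 6)."""
    return max(
        _score_gapped(ga, gb, match, mismatch, gap_open, gap_extend)
        for ga, gb in enumerate_alignments(a, b)
    )


def oracle_align_score_recursive(a: str, b: str, match=1.0, mismatch=-1.0,
                                 gap_open=-2.0, gap_extend=-1.0) -> float:
    """Optimal global affine score by memoized three-state recursion,
    written independently of the package's aligner."""

    @functools.cache
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        opts = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            opts.append(s + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "A" else gap_open
            opts.append(cost + best(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "B" else gap_open
            opts.append(cost + best(i, j + 1, "B"))
        return max(opts)

    return best(0, 0, "M")


def oracle_identity_pct(ga: str, gb: str) -> float:
    """Percent identity excluding terminal-gap overhangs, recounted by hand."""
    n = len(ga)
    lo = max(n - len(ga.lstrip("-")), n - len(gb.lstrip("-")))
    hi = min(len(ga.rstrip("-")), len(gb.rstrip("-"))) - 1
    cols = list(range(lo, hi + 1))
    matches = sum(1 for c in cols if ga[c] == gb[c] and ga[c] != "-")
    return round(100.0 * matches / len(cols), 1)


# ---------------------------------------------------------------------------
# trees: four-point condition on 4-taxon additive matrices
# ---------------------------------------------------------------------------

def four_point_split(labels, d) -> frozenset:
    """The valid split {x,y}|{z,w} of a 4-taxon additive matrix: the
    pairing whose within-pair distance sum is strictly smallest."""
    a, b, c, e = labels
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, e])]): d[(a, b)] + d[(c, e)],
        frozenset([frozenset([a, c]), frozenset([b, e])]): d[(a, c)] + d[(b, e)],
        frozenset([frozenset([a, e]), frozenset([b, c])]): d[(a, e)] + d[(b, c)],
    }
    return min(sums, key=sums.get)


def oracle_conserved_windows(cols_ok: list[bool], col_deg: list[int],
                             min_len: int, max_deg: int) -> list[tuple[int, int]]:
    """All (start, end) 1-based maximal feasible windows found by checking
    every (start, length) pair, then replaying the greedy left-to-right
    non-overlap rule."""
    L = len(cols_ok)

    def feasible(i: int, j: int) -> bool:  # 0-based [i, j)
        deg = 1
        for k in range(i, j):
            if not cols_ok[k]:
                return False
            deg *= col_deg[k]
            if deg > max_deg:
                return False
        return True

    out = []
    i = 0
    while i < L:
        best_j = None
        for j in range(L, i, -1):
            if feasible(i, j):
                best_j = j
                break
        if best_j is not None and best_j - i >= min_len:
            out.append((i + 1, best_j))
            i = best_j
        else:
            i += 1
    return out
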