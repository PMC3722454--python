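"""Synthetic marker-gene families with planted primer sites.

The generator emulates the situation a universal-primer screen faces:
a family of homologous genes that has diverged along a phylogeny, yet
retains short conserved footprints where the primers anneal. A root
sequence (default 950 nt, the scale of a bile-salt-hydrolase gene) is
evolved down a tree under the Jukes-Cantor (JC69) substitution model;
afterwards the planted footprints — by default the four conserved
regions of the packaged bsh panel, at reference positions 1, 46, 448
and 505 — are overwritten in every leaf with an independently sampled
concrete expansion of their IUPAC pattern, so primer sites stay
amplifiable while the flanks diverge. Every dataset ships with a truth
record: the generating tree, exact planted-site coordinates per leaf
and the true tip-to-tip distances, which is what makes each downstream
stage testable offline.

Indels are off by default so truth coordinates stay exact; an optional
per-site indel process (geometric lengths, flanks only) shifts
downstream anchors in the truth record when enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core_seq import IUPAC_BASES, NucSeq, write_fasta
from .primer_design import PRIMER_PANEL

_BASES = np.array(list("ACGT"))

#: Plus-strand footprints of the packaged bsh screening panel at their
#: reference anchors (the two RT-PCR variants share the 46/448 sites).
DEFAULT_PLANTED_BLOCKS: tuple[tuple[int, str], ...] = (
    (1, PRIMER_PANEL["Bif-bshA-1F"].plus_strand),
    (46, PRIMER_PANEL["Bif-bshB-2F"].plus_strand),
    (448, PRIMER_PANEL["Bif-bshC-1R"].plus_strand),
    (505, PRIMER_PANEL["Bif-bshD-2R"].plus_strand),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``tree`` carries branch lengths in expected substitutions per site;
    ``planted_blocks`` are (1-based reference anchor, IUPAC pattern)
    pairs that must fit, without overlap, inside ``root_length``.
    """

    tree: TreeNode
    root_length: int = 950
    planted_blocks: tuple[tuple[int, str], ...] = DEFAULT_PLANTED_BLOCKS
    mutation_model: str = "jc69"
    indel_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mutation_model != "jc69":
            raise ValueError("only the jc69 mutation model is supported")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must be in [0, 1)")
        spans = sorted(
            (a, a + len(pat) - 1) for a, pat in self.planted_blocks
        )
        prev_end = 0
        for s, e in spans:
            if s <= prev_end:
                raise ValueError(f"planted blocks overlap near position {s}")
            if e > self.root_length:
                raise ValueError(f"planted block at {s} exceeds root_length")
            prev_end = e
        for node in self.tree.traverse(include_self=False):
            if node.length is None or node.length < 0:
                raise ValueError("every tree edge needs a branch length >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth emitted alongside a synthetic dataset."""

    templates: tuple[NucSeq, ...]
    tree: TreeNode
    #: per-leaf planted sites: leaf id -> list of (start, end, pattern)
    planted_sites: dict[str, list[tuple[int, int, str]]]
    true_distances: DistanceMatrix

    def to_json(self) -> str:
        from .phylo import write_newick  # avoid cycle at import time

        return json.dumps(
            {
                "leaves": [t.id for t in self.templates],
                "planted_sites": {
                    leaf: [{"start": s, "end": e, "pattern": p} for s, e, p in sites]
                    for leaf, sites in self.planted_sites.items()
                },
                "tree_newick": str(self.tree),
                "true_distances": {
                    "ids": list(self.true_distances.ids),
                    "matrix": self.true_distances.data.tolist(),
                },
            },
            indent=2,
        )


def jc69_p_different(t: float) -> float:
    """Probability a site differs from its ancestor after branch length
    ``t`` (expected substitutions/site) under JC69:
    ``p = (3/4)(1 - exp(-4t/3))``."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def evolve_jc69(parent: NucSeq, branch_length: float, rng: np.random.Generator) -> NucSeq:
    """Evolve a sequence along one branch under JC69.

    Each site independently substitutes to one of the three other bases
    (uniformly) with probability ``jc69_p_different(branch_length)``.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    arr = np.array(list(parent.residues))
    p = jc69_p_different(branch_length)
    hit = rng.random(len(arr)) < p
    if hit.any():
        idx = {b: i for i, b in enumerate("ACGT")}
        cur = np.array([idx[b] for b in arr[hit]])
        # shift by 1..3 modulo 4: uniform over the three other bases
        shift = rng.integers(1, 4, size=cur.size)
        arr[hit] = _BASES[(cur + shift) % 4]
    return NucSeq(parent.id, "".join(arr), parent.description)


def _sample_expansion(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_BASES[c])[rng.integers(0, len(IUPAC_BASES[c]))] for c in pattern
    )


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    edge_length_range: tuple[float, float] = (0.02, 0.15),
    prefix: str = "T",
) -> TreeNode:
    """A random unrooted binary topology by sequential random joins, with
    every edge length drawn uniformly from ``edge_length_range``."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    lo, hi = edge_length_range
    nodes = [TreeNode(name=f"{prefix}{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b]))
    root = TreeNode(children=nodes)
    for node in root.traverse(include_self=False):
        node.length = float(rng.uniform(lo, hi))
    return root


def _apply_indels(
    residues: str,
    protected: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Apply geometric-length indels outside protected spans.

    Returns the mutated string and, for each original 1-based position,
    its shift (new_pos - old_pos) — used to relocate downstream anchors.
    """
    is_protected = np.zeros(len(residues), dtype=bool)
    for s, e in protected:
        is_protected[s - 1 : e] = True
    out: list[str] = []
    shifts: list[int] = []
    delta = 0
    i = 0
    while i < len(residues):
        shifts.append(delta)
        if is_protected[i]:
            out.append(residues[i])
            i += 1
            continue
        u = rng.random()
        if u < rate / 2.0:  # deletion of a geometric run (flank only)
            dlen = int(rng.geometric(0.5))
            j = i
            while j < len(residues) and j - i < dlen and not is_protected[j]:
                j += 1
            for _ in range(i + 1, j):
                shifts.append(delta)
            delta -= j - i
            i = j
        elif u < rate:  # insertion after this site
            out.append(residues[i])
            ilen = int(rng.geometric(0.5))
            out.append("".join(_BASES[rng.integers(0, 4, size=ilen)]))
            delta += ilen
            i += 1
        else:
            out.append(residues[i])
            i += 1
    return "".join(out), shifts


def generate_dataset(cfg: SimConfig) -> TruthRecord:
    """Evolve a root sequence down the tree and plant primer footprints.

    Leaf order follows the tree's tip order. The planted footprints are
    overwritten after evolution with per-leaf concrete expansions, so
    they match their IUPAC pattern with zero mismatches in every leaf.
    """
    rng = np.random.default_rng(cfg.seed)
    root_seq = "".join(_BASES[rng.integers(0, 4, size=cfg.root_length)])
    seqs: dict[int, str] = {id(cfg.tree): root_seq}
    for node in cfg.tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        child = evolve_jc69(NucSeq("tmp", parent_seq), float(node.length), rng)
        seqs[id(node)] = child.residues

    blocks = sorted(cfg.planted_blocks)
    templates: list[NucSeq] = []
    planted_sites: dict[str, list[tuple[int, int, str]]] = {}
    for tip in cfg.tree.tips():
        residues = list(seqs[id(tip)])
        sites: list[tuple[int, int, str]] = []
        for anchor, pattern in blocks:
            concrete = _sample_expansion(pattern, rng)
            residues[anchor - 1 : anchor - 1 + len(pattern)] = list(concrete)
            sites.append((anchor, anchor + len(pattern) - 1, pattern))
        leaf_seq = "".join(residues)
        if cfg.indel_rate > 0:
            protected = [(s, e) for s, e, _ in sites]
            leaf_seq, shifts = _apply_indels(leaf_seq, protected, cfg.indel_rate, rng)
            sites = [
                (s + shifts[s - 1], e + shifts[s - 1], p) for s, e, p in sites
            ]
        planted_sites[tip.name] = sites
        templates.append(NucSeq(tip.name, leaf_seq, "synthetic marker-gene template"))

    true_d = cfg.tree.tip_tip_distances()
    return TruthRecord(tuple(templates), cfg.tree, planted_sites, true_d)


def write_dataset(truth: TruthRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write templates.fasta, truth.json and tree.nwk under ``out_dir``."""
    from .phylo import write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "templates": out / "templates.fasta",
        "truth": out / "truth.json",
        "tree": out / "tree.nwk",
    }
    write_fasta(truth.templates, paths["templates"])
    paths["truth"].write_text(truth.to_json())
    write_newick(truth.tree, paths["tree"])
    return paths
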