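"""Distance conversion, neighbor joining, bootstrap and Newick I/O."""

from __future__ import annotations

import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from ampliphy.core_seq import NucSeq
from ampliphy.identity import IdentityMatrix
from ampliphy.phylo import (
    NewickParseError,
    bipartitions,
    bootstrap_supports,
    nj_tree,
    p_distance_from_alignment,
    read_newick,
    rf_distance,
    to_distance,
    write_newick,
)
from ampliphy.simulate import random_tree

from ._oracles import four_point_split


def _identity(labels, pct_offdiag):
    n = len(labels)
    v = np.full((n, n), 100.0)
    for (i, j), pct in pct_offdiag.items():
        v[i, j] = v[j, i] = pct
    return IdentityMatrix(tuple(labels), v)


class TestToDistance:
    def test_full_identity_gives_zero_under_both_corrections(self):
        m = _identity(("a", "b"), {(0, 1): 100.0})
        for corr in ("none", "jukes_cantor"):
            assert to_distance(m, corr)["a", "b"] == 0.0

    def test_identity_90_closed_forms(self):
        m = _identity(("a", "b"), {(0, 1): 90.0})
        assert to_distance(m, "none")["a", "b"] == pytest.approx(0.1)
        expected = -0.75 * math.log(1 - 0.4 / 3)
        assert to_distance(m, "jukes_cantor")["a", "b"] == pytest.approx(expected)

    def test_corrections_agree_to_first_order_for_small_p(self):
        for pct in (99.9, 99.0, 97.5, 95.0):
            m = _identity(("a", "b"), {(0, 1): pct})
            p = 1 - pct / 100
            d_jc = to_distance(m, "jukes_cantor")["a", "b"]
            assert abs(d_jc - p) <= p ** 2

    def test_jc_undefined_beyond_three_quarters(self):
        m = _identity(("a", "b"), {(0, 1): 20.0})
        with pytest.raises(ValueError, match="0.75"):
            to_distance(m, "jukes_cantor")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]], ids=list("abc")
        )
        t = nj_tree(d)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))
        assert len(list(t.tips())) == 3

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # known quartet ((a,b),(c,d)) with random positive edges, checked
        # against the four-point-condition oracle
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, e, mid = rng.uniform(0.05, 0.5, size=5)
            labels = list("abcd")
            dd = {
                ("a", "b"): a + b, ("c", "d"): c + e,
                ("a", "c"): a + mid + c, ("a", "d"): a + mid + e,
                ("b", "c"): b + mid + c, ("b", "d"): b + mid + e,
            }
            sym = {(x, y): v for (x, y), v in dd.items()} | {
                (y, x): v for (x, y), v in dd.items()
            }
            mat = [[0.0 if x == y else sym[(x, y)] for y in labels] for x in labels]
            dm = DistanceMatrix(mat, ids=labels)
            t = nj_tree(dm)
            split = four_point_split(labels, sym)
            assert split == frozenset(
                [frozenset(["a", "b"]), frozenset(["c", "d"])]
            )
            assert bipartitions(t) == {frozenset(["c", "d"])} or bipartitions(t) == {
                frozenset(["a", "b"])
            }
            # exact branch-length recovery on additive input
            tips = {tip.name: tip.length for tip in t.tips()}
            assert tips["a"] == pytest.approx(a)
            assert tips["d"] == pytest.approx(e)

    def test_additive_matrices_from_random_trees_recovered(self):
        # NJ is exact on additive matrices: 50 instances, 4-8 taxa
        for seed in range(50):
            rng = np.random.default_rng(2000 + seed)
            n = int(rng.integers(4, 9))
            true = random_tree(n, rng, edge_length_range=(0.05, 0.4))
            dm = true.tip_tip_distances()
            est = nj_tree(dm)
            assert rf_distance(est, true) == 0
            # and the induced tip-to-tip distances match (additivity)
            est_d = est.tip_tip_distances().filter(list(dm.ids))
            assert np.allclose(est_d.data, dm.data, atol=1e-9)

    def test_matches_reference_nj_topology(self, sim_truth):
        from skbio.tree import nj as skbio_nj

        dm = sim_truth.true_distances
        assert rf_distance(nj_tree(dm), skbio_nj(dm)) == 0

    def test_leaf_set_equals_matrix_labels(self, sim_truth):
        dm = sim_truth.true_distances
        t = nj_tree(dm)
        assert {tip.name for tip in t.tips()} == set(dm.ids)

    def test_rejects_fewer_than_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0.0, 0.1], [0.1, 0.0]], ids=["a", "b"]))

    def test_negative_branch_lengths_clamped(self):
        # a strongly non-additive matrix that forces a negative estimate
        d = DistanceMatrix(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.45],
                [0.4, 0.4, 0.0, 0.05],
                [0.4, 0.45, 0.05, 0.0],
            ],
            ids=list("abcd"),
        )
        t = nj_tree(d)
        for node in t.traverse(include_self=False):
            assert node.length >= 0.0


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(n_fixed=12, length=300, seed=5):
        """Two 4-leaf clades separated by >= n_fixed fixed differences."""
        rng = np.random.default_rng(seed)
        base = rng.choice(list("ACGT"), size=length)
        other = base.copy()
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        cols = rng.choice(length, size=n_fixed, replace=False)
        for c in cols:
            other[c] = flip[str(base[c])]
        rows = []
        for k in range(4):
            noise = base.copy()
            j = rng.integers(0, length)
            noise[j] = flip[str(noise[j])]
            rows.append(NucSeq(f"A{k}", "".join(noise)))
        for k in range(4):
            noise = other.copy()
            j = rng.integers(0, length)
            noise[j] = flip[str(noise[j])]
            rows.append(NucSeq(f"B{k}", "".join(noise)))
        return rows

    def test_separated_clades_get_high_support(self):
        rows = self._two_clade_alignment()
        t = bootstrap_supports(rows, n_replicates=200, seed=1)
        clade = frozenset(f"B{k}" for k in range(4))
        supports = {}
        leaves = frozenset(r.id for r in rows)
        anchor = min(leaves)
        for node in t.non_tips(include_self=False):
            side = frozenset(tip.name for tip in node.tips())
            if anchor in side:
                side = leaves - side
            supports[side] = int(node.name)
        assert supports[clade] >= 95

    def test_single_replicate_supports_are_all_or_nothing(self):
        rows = self._two_clade_alignment()
        t = bootstrap_supports(rows, n_replicates=1, seed=2)
        vals = {int(n.name) for n in t.non_tips(include_self=False)
                if n.name is not None}
        assert vals <= {0, 100}

    def test_same_seed_reproducible_and_seeds_agree_within_sampling_error(self):
        rows = self._two_clade_alignment()

        def support_vector(seed, reps=300):
            t = bootstrap_supports(rows, n_replicates=reps, seed=seed)
            return sorted(
                int(n.name) for n in t.non_tips(include_self=False) if n.name
            )

        assert support_vector(7) == support_vector(7)
        v1, v2 = support_vector(7), support_vector(8)
        assert all(abs(x - y) <= 5 for x, y in zip(v1, v2))

    def test_supports_invariant_to_leaf_input_order(self):
        rows = self._two_clade_alignment()
        t1 = bootstrap_supports(rows, n_replicates=50, seed=3)
        t2 = bootstrap_supports(rows[::-1], n_replicates=50, seed=3)
        # compare by bipartition: same splits found in both full trees
        assert bipartitions(t1) == bipartitions(t2)


class TestNewickIO:
    def test_three_leaf_round_trip(self, tmp_path):
        d = DistanceMatrix(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]], ids=list("abc")
        )
        t = nj_tree(d)
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(path)
        assert {tip.name for tip in back.tips()} == set("abc")
        for tip in back.tips():
            orig = next(x for x in t.tips() if x.name == tip.name)
            assert tip.length == pytest.approx(orig.length, rel=1e-5)

    def test_random_trees_round_trip_bipartitions(self, tmp_path):
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            t = random_tree(10, rng)
            path = tmp_path / f"t{seed}.nwk"
            write_newick(t, path)
            back = read_newick(path)
            assert bipartitions(back) == bipartitions(t)

    def test_supports_survive_round_trip(self, tmp_path):
        rows = TestBootstrap._two_clade_alignment()
        t = bootstrap_supports(rows, n_replicates=50, seed=4)
        path = tmp_path / "s.nwk"
        write_newick(t, path)
        back = read_newick(path)
        names = {n.name for n in back.non_tips(include_self=False)}
        assert any(n is not None and n.isdigit() for n in names)

    def test_unbalanced_parentheses_reported_with_offset(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((a,b),(c,d);")
        with pytest.raises(NewickParseError, match="unclosed"):
            read_newick(path)
        path.write_text("(a,b)),c;")
        with pytest.raises(NewickParseError, match="character 5"):
            read_newick(path)


def test_p_distance_from_alignment_counts_gap_free_columns():
    rows = [
        NucSeq("a", "ACGTAC-TAC", allow_gaps=True),
        NucSeq("b", "ACGTACGTCC", allow_gaps=True),
        NucSeq("c", "ACGAACGTAC", allow_gaps=True),
    ]
    dm = p_distance_from_alignment(rows)
    # a vs b: 9 shared gap-free columns, 1 difference (col 9: A vs C)
    assert dm["a", "b"] == pytest.approx(1 / 9)
    assert dm["a", "c"] == pytest.approx(1 / 9)
    assert dm["b", "c"] == pytest.approx(2 / 10)
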