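"""p-distance, neighbor joining, bootstrap and Newick export."""

import itertools

import numpy as np
import pytest

from genefam.phylo import (
    DistanceMatrix,
    bootstrap,
    internal_splits,
    neighbor_joining,
    p_distance,
    path_length_matrix,
)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        dm = p_distance(["a", "b"], ["ACDE", "ACDE"])
        assert dm.d[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        dm = p_distance(["a", "b"], ["AAAA", "AAAT"])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded_pairwise(self):
        dm = p_distance(["a", "b"], ["A-CT", "AGCT"])
        assert dm.d[0, 1] == 0.0  # only 3 comparable columns, all equal

    def test_all_gap_overlap_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(["a", "b"], ["AA--", "--TT"])

    def test_ragged_alignment_raises(self):
        with pytest.raises(ValueError):
            p_distance(["a", "b"], ["AAA", "AAAA"])


def _additive_matrix():
    """Distances generated from the tree ((a:1,b:2):3,(c:4,d:5)) with the
    internal edge of length 3."""
    ids = ["a", "b", "c", "d"]
    bl = {"a": 1.0, "b": 2.0, "c": 4.0, "d": 5.0}
    d = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        x, y = ids[i], ids[j]
        same = {x, y} <= {"a", "b"} or {x, y} <= {"c", "d"}
        d[i, j] = d[j, i] = bl[x] + bl[y] + (0.0 if same else 3.0)
    return DistanceMatrix(ids, d)


def _ls_topology_oracle(dm):
    """Independent oracle: enumerate the three unrooted 4-taxon topologies,
    least-squares-fit the five branch lengths, return the zero-residual split."""
    ids = dm.ids
    best = None
    for split in ([0, 1], [0, 2], [0, 3]):
        pair1 = split
        pair2 = [k for k in range(4) if k not in split]
        # design matrix: columns = branches (4 leaf + 1 internal)
        rows, y = [], []
        for i, j in itertools.combinations(range(4), 2):
            row = [0.0] * 5
            row[i] = row[j] = 1.0
            crosses = (i in pair1) != (j in pair1)
            row[4] = 1.0 if crosses else 0.0
            rows.append(row)
            y.append(dm.d[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        residual = float(np.sum((np.array(rows) @ sol - np.array(y)) ** 2))
        if residual < 1e-12:
            best = frozenset({ids[pair1[0]], ids[pair1[1]]})
    return best


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_topology(self):
        dm = _additive_matrix()
        tree = neighbor_joining(dm)
        expected = _ls_topology_oracle(dm)
        assert expected == frozenset({"a", "b"})  # sanity of the oracle itself
        assert internal_splits(tree) == {expected}

    def test_reproduces_additive_path_lengths(self):
        dm = _additive_matrix()
        tree = neighbor_joining(dm)
        plm = path_length_matrix(tree)
        order = [plm.ids.index(i) for i in dm.ids]
        assert np.allclose(plm.d[np.ix_(order, order)], dm.d, atol=1e-9)

    def test_two_taxa_edge_length(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = neighbor_joining(dm)
        total = sum(bl for _, bl in tree.root.children)
        assert total == pytest.approx(0.6)

    def test_three_taxa_three_point_formula(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        bl = {c.name: l for c, l in tree.root.children}
        assert bl["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert bl["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert bl["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_topology_invariant_under_uniform_scaling(self):
        dm = _additive_matrix()
        scaled = DistanceMatrix(dm.ids, dm.d * 7.3)
        assert internal_splits(neighbor_joining(dm)) == internal_splits(
            neighbor_joining(scaled)
        )

    def test_matches_scikit_bio_on_random_matrices(self):
        """Independent implementation cross-check on random additive-ish input."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(31)
        for _ in range(5):
            n = 6
            coords = rng.uniform(0, 1, size=(n, 8))
            d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            ids = [f"t{i}" for i in range(n)]
            ours = neighbor_joining(DistanceMatrix(ids, d))
            theirs = skbio_nj(SkbioDM(d, ids))
            their_splits = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    all_ids = frozenset(ids)
                    other = all_ids - side
                    their_splits.add(
                        min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
                    )
            assert internal_splits(ours) == their_splits


class TestBootstrap:
    def _clean_alignment(self):
        # two clearly separated clades, strong signal in every column
        block_a, block_b = "A" * 30, "T" * 30
        return (
            ["x1", "x2", "y1", "y2"],
            [block_a, block_a[:-1] + "C", block_b, block_b[:-1] + "G"],
        )

    def test_congruent_alignment_gives_high_support(self):
        ids, seqs = self._clean_alignment()
        tree = bootstrap(ids, seqs, n_replicates=100, seed=3)
        split = frozenset({"x1", "x2"})
        assert tree.supports[split] >= 95.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        ids, seqs = self._clean_alignment()
        tree = bootstrap(ids, seqs, n_replicates=1, seed=5)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_is_bit_identical(self):
        ids, seqs = self._clean_alignment()
        t1 = bootstrap(ids, seqs, n_replicates=25, seed=9)
        t2 = bootstrap(ids, seqs, n_replicates=25, seed=9)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_newick_contains_supports_and_all_leaves(self):
        ids, seqs = self._clean_alignment()
        nwk = bootstrap(ids, seqs, n_replicates=10, seed=1).to_newick()
        for leaf in ids:
            assert leaf in nwk
        assert nwk.endswith(";")
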