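"""Distances, neighbor joining, Newick export, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alfasnp.genotyping import GenotypeMatrix, core_set
from alfasnp.filtering import call_variants
from alfasnp.io import MISSING, STATE_AA, STATE_AB, STATE_BB, DataError
from alfasnp.simulate import default_panel_config, simulate_panel
from alfasnp.structure import (
    DistanceMatrix,
    TreeNode,
    neighbor_joining,
    newick_string,
    pca,
    simple_matching_distance,
    tree_splits,
    write_newick,
)

A, B, H, M = STATE_AA, STATE_BB, STATE_AB, MISSING


def matrix_of(codes, ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    ids = ids or [f"g{j}" for j in range(codes.shape[1])]
    sites = pd.DataFrame({"contig": ["c1"] * len(codes), "pos0": range(len(codes))})
    return GenotypeMatrix(sites, ids, codes, {g: 4 for g in ids})


class TestSimpleMatching:
    def test_identical_columns_zero(self):
        m = matrix_of([[A, A], [H, H], [B, B]])
        d = simple_matching_distance(m)
        assert d.values[0, 1] == 0.0

    def test_fully_mismatched_columns_one(self):
        m = matrix_of([[A, B], [A, B], [A, B]])
        assert simple_matching_distance(m).values[0, 1] == 1.0

    def test_missing_excluded_pairwise(self):
        m = matrix_of([[A, M], [A, A], [B, A]])
        d = simple_matching_distance(m)
        assert d.values[0, 1] == pytest.approx(0.5)
        assert d.n_compared[0, 1] == 2

    def test_no_comparable_sites_error(self):
        m = matrix_of([[A, M], [M, A]])
        with pytest.raises(DataError, match="g0"):
            simple_matching_distance(m)

    def test_matches_per_site_comparison_oracle(self, rng):
        codes = rng.integers(-1, 3, size=(20, 5)).astype(np.int8)
        codes[0] = A  # guarantee comparability
        m = matrix_of(codes)
        d = simple_matching_distance(m)
        for i, j in itertools.combinations(range(5), 2):
            same = comp = 0
            for s in range(20):
                if codes[s, i] != M and codes[s, j] != M:
                    comp += 1
                    same += codes[s, i] == codes[s, j]
            assert d.values[i, j] == pytest.approx(1 - same / comp)


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree with uniform branch lengths, plus its
    additive leaf-to-leaf distance matrix (the NJ consistency oracle)."""
    nodes = [TreeNode(f"t{i}") for i in range(3)]
    root = TreeNode()
    root.children = [(nd, float(rng.uniform(0.1, 1.0))) for nd in nodes]
    leaves = {f"t{i}" for i in range(3)}
    for i in range(3, n_taxa):
        # split a random edge and hang a new leaf off the midpoint
        parents = []

        def collect(node):
            for k, (child, bl) in enumerate(node.children):
                parents.append((node, k))
                collect(child)

        collect(root)
        node, k = parents[rng.integers(0, len(parents))]
        child, bl = node.children[k]
        mid = TreeNode()
        split = float(rng.uniform(0.2, 0.8))
        mid.children = [
            (child, bl * split),
            (TreeNode(f"t{i}"), float(rng.uniform(0.1, 1.0))),
        ]
        node.children[k] = (mid, bl * (1 - split))
        leaves.add(f"t{i}")
    ids = sorted(leaves)
    pair = root.leaf_distances()
    d = np.zeros((len(ids), len(ids)))
    for (x, y), v in pair.items():
        i, j = ids.index(x), ids.index(y)
        d[i, j] = d[j, i] = v
    return ids, d, root


def ls_oracle_four_taxa(ids, d):
    """Exhaustive 4-taxon oracle: enumerate the 3 unrooted topologies,
    fit the 5 branch lengths by least squares, return the best fit as
    (split, lengths, residual)."""
    best = None
    a, b, c, e = range(4)
    for pair in [(a, b), (a, c), (a, e)]:
        left = list(pair)
        right = [k for k in range(4) if k not in pair]
        # unknowns: x_left0, x_left1, x_right0, x_right1, internal m
        rows, y = [], []
        for i, j in itertools.combinations(range(4), 2):
            coef = [0.0] * 5
            order = left + right
            coef[order.index(i)] = 1.0
            coef[order.index(j)] = 1.0
            crosses = (i in left) != (j in left)
            if crosses:
                coef[4] = 1.0
            rows.append(coef)
            y.append(d[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = float(((np.array(rows) @ sol - np.array(y)) ** 2).sum())
        split = frozenset({ids[left[0]], ids[left[1]]})
        if best is None or resid < best[2]:
            best = (split, sol, resid)
    return best


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(ids, vals, np.ones((3, 3), int)))
        limbs = {child.name: bl for child, bl in tree.children}
        assert limbs["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert limbs["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert limbs["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrix_reproduced_exactly(self, n_taxa, rng):
        ids, d, _ = random_additive_tree(n_taxa, rng)
        tree = neighbor_joining(DistanceMatrix(ids, d, np.ones_like(d, dtype=int)))
        got = tree.leaf_distances()
        for (x, y), v in got.items():
            i, j = ids.index(x), ids.index(y)
            assert v == pytest.approx(d[i, j], abs=1e-9)
        assert tree.n_edges() == 2 * n_taxa - 3

    def test_four_taxon_topology_and_lengths_match_ls_oracle(self, rng):
        for _ in range(10):
            ids, d, _ = random_additive_tree(4, rng)
            tree = neighbor_joining(DistanceMatrix(ids, d, np.ones_like(d, dtype=int)))
            split, sol, resid = ls_oracle_four_taxa(ids, d)
            assert resid < 1e-18
            njsplits = tree_splits(tree)
            assert split in njsplits or frozenset(ids) - split in njsplits
            got = tree.leaf_distances()
            order = sorted(ids)
            # LS limb/internal lengths must reproduce identical pairwise sums
            for (x, y), v in got.items():
                i, j = ids.index(x), ids.index(y)
                assert v == pytest.approx(d[i, j], abs=1e-9)

    def test_column_order_invariance(self, rng):
        ids, d, _ = random_additive_tree(6, rng)
        t1 = neighbor_joining(DistanceMatrix(ids, d, np.ones_like(d, dtype=int)))
        perm = rng.permutation(len(ids))
        ids2 = [ids[k] for k in perm]
        t2 = neighbor_joining(
            DistanceMatrix(ids2, d[np.ix_(perm, perm)], np.ones_like(d, dtype=int))
        )
        assert tree_splits(t1) == tree_splits(t2)
        d1, d2 = t1.leaf_distances(), t2.leaf_distances()
        for key, v in d1.items():
            assert v == pytest.approx(d2[key], abs=1e-9)

    def test_asymmetric_input_rejected(self):
        vals = np.array([[0.0, 0.1, 0.2], [0.3, 0.0, 0.1], [0.2, 0.1, 0.0]])
        with pytest.raises(DataError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], vals, np.ones((3, 3), int)))

    def test_group_monophyly_on_divergent_panel(self):
        cfg = default_panel_config(
            seed=5, n_contigs=120, sites_per_contig=10,
            group_divergence=(0.3, 0.3, 0.3),
        )
        counts, _, groups, _ = simulate_panel(cfg)
        calls = call_variants(counts)
        m = core_set(calls, counts, groups)
        tree = neighbor_joining(simple_matching_distance(m))
        splits = tree_splits(tree)
        everything = frozenset(m.genotypes)
        for name in ("Group1", "Group2", "Group3"):
            gset = frozenset(groups.groups[name])
            assert gset in splits or (everything - gset) in splits, name

    def test_skbio_cross_check_on_additive_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        ids, d, _ = random_additive_tree(6, rng)
        ours = neighbor_joining(DistanceMatrix(ids, d, np.ones_like(d, dtype=int)))
        theirs = sknj(SkDM(d, ids))
        ours_d = ours.leaf_distances()
        for (x, y), v in ours_d.items():
            assert v == pytest.approx(theirs.find(x).distance(theirs.find(y)), abs=1e-6)


class TestNewick:
    def test_three_leaf_shape(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]])
        tree = neighbor_joining(DistanceMatrix(ids, vals, np.ones((3, 3), int)))
        s = newick_string(tree)
        assert s.startswith("(") and s.endswith(");")
        assert all(f"{x}:" in s for x in ids)

    def test_round_trip_isomorphic_via_skbio(self, tmp_path, rng):
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        ids, d, _ = random_additive_tree(7, rng)
        tree = neighbor_joining(DistanceMatrix(ids, d, np.ones_like(d, dtype=int)))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        for (x, y), v in tree.leaf_distances().items():
            assert parsed.find(x).distance(parsed.find(y)) == pytest.approx(v, abs=5e-5)

    def test_labels_with_spaces_quoted(self):
        tree = TreeNode()
        tree.children = [
            (TreeNode("wild falcata"), 0.1),
            (TreeNode("b"), 0.2),
            (TreeNode("c"), 0.3),
        ]
        assert "'wild falcata':0.100000" in newick_string(tree)


class TestPCA:
    def test_identical_genotypes_coincident_scores(self):
        m = matrix_of([[A, A, B], [H, H, A], [B, B, B], [A, A, H]])
        res = pca(m)
        assert np.allclose(res.scores[0], res.scores[1])

    def test_variance_fractions_sum_to_one_at_full_rank(self, rng):
        codes = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        res = pca(matrix_of(codes))
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_three_by_three_closed_form_eigenvalues(self):
        # genotypes x sites (centered) Gram matrix is diag(2, 8/3) by hand:
        # variance fractions 4/7 and 3/7
        m = matrix_of([[A, H, B], [A, B, A]])
        res = pca(m)
        assert res.variance_fraction[:2] == pytest.approx([4 / 7, 3 / 7])
        total_var = (res.scores**2).sum()
        assert total_var == pytest.approx(2 + 8 / 3)

    def test_constant_matrix_zero(self):
        m = matrix_of([[H, H, H], [H, H, H]])
        res = pca(m)
        assert np.all(res.scores == 0) and np.all(res.variance_fraction == 0)

    def test_missing_imputed_with_site_mean(self):
        m = matrix_of([[A, B, M], [A, B, A]])
        res = pca(m)  # must not raise; imputed genotype sits between the others
        assert np.isfinite(res.scores).all()

    def test_group_separation_silhouette_positive(self):
        sk = pytest.importorskip("sklearn.metrics")
        cfg = default_panel_config(
            seed=5, n_contigs=120, sites_per_contig=10,
            group_divergence=(0.3, 0.3, 0.3),
        )
        counts, _, groups, _ = simulate_panel(cfg)
        m = core_set(call_variants(counts), counts, groups)
        res = pca(m)
        labels = []
        for g in m.genotypes:
            labels.append(next(k for k, ids in groups.groups.items()
                               if k.startswith("Group") and g in ids))
        score = sk.silhouette_score(res.scores[:, :2], labels)
        assert score > 0
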