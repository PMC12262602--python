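"""PCA, neighbour joining, F_ST estimators and the resampling null."""

import itertools

import numpy as np
import pytest

from sweepscan import (
    fst_resampling_null,
    hudson_fst,
    mann_whitney_u,
    neighbor_joining,
    pairwise_distance_matrix,
    patterson_fst,
    pca,
    select_cohort,
)
from sweepscan.simulate import SimDesign, simulate_cohorts

from conftest import make_diploset, make_frame


# ---------------------------------------------------------------------------
# additive-tree machinery for the NJ oracle


def random_additive_tree(n_taxa, rng):
    """Random binary topology with positive branch lengths; returns the
    exact leaf-to-leaf path-length matrix."""
    # start from 3 leaves on a star, then repeatedly split a random edge;
    # internal node ids start above the leaf range
    center = n_taxa
    adjacency = {center: {}}  # node -> {neighbor: length}
    for leaf in range(3):
        length = rng.uniform(0.5, 3.0)
        adjacency[center][leaf] = length
        adjacency[leaf] = {center: length}
    next_node = n_taxa + 1
    for leaf in range(3, n_taxa):
        edges = [
            (a, b) for a in adjacency for b in adjacency[a] if a < b
        ]
        a, b = edges[rng.integers(len(edges))]
        w = adjacency[a].pop(b)
        adjacency[b].pop(a)
        mid = next_node
        next_node += 1
        split = rng.uniform(0.2, 0.8) * w
        adjacency[mid] = {a: split, b: w - split}
        adjacency[a][mid] = split
        adjacency[b][mid] = w - split
        length = rng.uniform(0.5, 3.0)
        adjacency[mid][leaf] = length
        adjacency[leaf] = {mid: length}
    # all-pairs path lengths among leaves by BFS/DFS accumulation
    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adjacency[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            dist[src, dst] = seen[dst]
    return dist


def tree_leaf_distances(tree, labels):
    """Path lengths between leaves of a TreeNode tree."""
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    dist = np.zeros((n, n))

    def walk(node):
        """Returns {leaf_index: distance to this node}."""
        if node.is_leaf():
            return {index[node.label]: 0.0}
        below = []
        for child in node.children:
            d = walk(child)
            below.append({k: v + child.length for k, v in d.items()})
        for a, b in itertools.combinations(below, 2):
            for i, di in a.items():
                for j, dj in b.items():
                    dist[i, j] = dist[j, i] = di + dj
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    walk(tree)
    return dist


def tree_splits(tree, labels):
    """Set of non-trivial leaf bipartitions (as frozensets of the smaller side)."""
    all_leaves = frozenset(labels)
    splits = set()

    def walk(node):
        if node.is_leaf():
            return {node.label}
        members = set()
        for child in node.children:
            sub = walk(child)
            if 1 < len(sub) < len(labels) - 1:
                side = frozenset(sub)
                other = frozenset(all_leaves - side)
                splits.add(min(side, other, key=sorted))
            members |= sub
        return members

    walk(tree)
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        lengths = {leaf.label: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_taxa", [4, 6, 8, 12])
    def test_recovers_additive_trees_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            dist = random_additive_tree(n_taxa, rng)
            labels = [f"t{i}" for i in range(n_taxa)]
            tree = neighbor_joining(dist, labels)
            recovered = tree_leaf_distances(tree, labels)
            np.testing.assert_allclose(recovered, dist, atol=1e-9)

    def test_newick_round_trips_through_skbio(self):
        import io

        import skbio

        rng = np.random.default_rng(0)
        dist = random_additive_tree(6, rng)
        labels = [f"t{i}" for i in range(6)]
        tree = neighbor_joining(dist, labels)
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(labels)
        # branch lengths survive serialisation
        tip_lengths = {t.name: t.length for t in parsed.tips()}
        for leaf in tree.leaves():
            assert tip_lengths[leaf.label] == pytest.approx(leaf.length, abs=1e-9)

    def test_topology_matches_skbio_nj(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(5)
        dist = random_additive_tree(8, rng)
        dist = (dist + dist.T) / 2  # exact symmetry for skbio
        labels = [f"t{i}" for i in range(8)]
        ours = tree_splits(neighbor_joining(dist, labels), labels)
        theirs_tree = nj(DistanceMatrix(dist, labels))
        theirs = set()
        for node in theirs_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(labels) - 1:
                other = frozenset(set(labels) - side)
                theirs.add(min(side, other, key=sorted))
        assert ours == theirs

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, list("ABC"))


class TestDistances:
    def test_direct_sum_example(self):
        diplo = make_diploset(np.array([[0, 2], [1, 1], [2, 0]]))
        d = pairwise_distance_matrix(diplo)
        assert d[0, 1] == 4

    def test_identical_samples_zero(self):
        diplo = make_diploset(np.array([[1, 1], [2, 2], [0, 0]]))
        assert pairwise_distance_matrix(diplo)[0, 1] == 0

    def test_missing_handled_pairwise_complete(self):
        diplo = make_diploset(np.array([[0, 2, 1], [-1, 1, 0], [2, 0, -1]]))
        d = pairwise_distance_matrix(diplo)
        assert d[0, 1] == 4  # middle site missing in sample 0
        assert d[1, 2] == 2  # last site missing in sample 2

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        diplo = make_diploset(rng.integers(0, 3, size=(40, 8)))
        d = pairwise_distance_matrix(diplo)
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestFstEstimators:
    def ac(self, *pairs):
        return np.array(pairs, dtype=float)

    def test_fixed_difference_is_one(self):
        a = self.ac((10, 0))
        b = self.ac((0, 10))
        assert hudson_fst(a, b)[2] == pytest.approx(1.0)
        assert patterson_fst(a, b)[2] == pytest.approx(1.0)

    def test_hudson_plugin_arithmetic(self):
        # p1 = p2 = 0.5 with n = 6 alleles each: N = -0.1, D = 0.5
        a = self.ac((3, 3))
        b = self.ac((3, 3))
        num, den, fst = hudson_fst(a, b)
        assert num[0] == pytest.approx(-0.1)
        assert den[0] == pytest.approx(0.5)
        assert fst == pytest.approx(-0.2)

    def test_identical_large_populations_near_zero(self):
        a = self.ac((5000, 5000))
        b = self.ac((5000, 5000))
        assert patterson_fst(a, b)[2] == pytest.approx(0.0, abs=1e-3)

    def test_symmetric_in_population_order(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 30, size=(50, 2)).astype(float)
        b = rng.integers(1, 30, size=(50, 2)).astype(float)
        for fn in (hudson_fst, patterson_fst):
            assert fn(a, b)[2] == pytest.approx(fn(b, a)[2], rel=1e-12)

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 30, size=(50, 2)).astype(float)
        b = rng.integers(1, 30, size=(50, 2)).astype(float)
        for fn in (hudson_fst, patterson_fst):
            assert fn(a, b)[2] == pytest.approx(
                fn(a[:, ::-1], b[:, ::-1])[2], rel=1e-12
            )

    def test_estimators_agree_on_diverged_demes(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 2000)
        shift = rng.normal(0, 0.1, 2000)
        p1 = np.clip(p + shift, 0.01, 0.99)
        p2 = np.clip(p - shift, 0.01, 0.99)
        n = 200  # alleles per deme
        c1 = rng.binomial(n, p1)
        c2 = rng.binomial(n, p2)
        a = np.stack([n - c1, c1], axis=1).astype(float)
        b = np.stack([n - c2, c2], axis=1).astype(float)
        assert hudson_fst(a, b)[2] == pytest.approx(patterson_fst(a, b)[2], abs=0.01)


class TestMannWhitney:
    def test_separated_samples_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(2 / 20)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 1, 2], [1, 1, 2])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_all_equal_degenerate(self):
        u, p = mann_whitney_u([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_approximation_close_to_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            from scipy import stats

            exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
            assert abs(exact.pvalue - approx.pvalue) < 0.05


class TestResamplingNull:
    def test_deterministic_under_seed(self, neutral_sim):
        dip = neutral_sim.diplotypes("2RL")
        kwargs = dict(
            pop_a_query="region == 'East'",
            pop_b_query="region == 'West'",
            n_snps=200,
            n_iter=50,
            seed=4,
        )
        a = fst_resampling_null(dip, neutral_sim.frame, **kwargs)
        b = fst_resampling_null(dip, neutral_sim.frame, **kwargs)
        np.testing.assert_array_equal(a.between, b.between)
        assert a.p_within_a_vs_between == b.p_within_a_vs_between

    def test_diverged_demes_detected(self):
        design = SimDesign(
            n_per_cell=15,
            contigs={"2RL": (1_000_000, 1_500)},
            d=3.0,
            sigma_h=0.0,
            sweeps=[],
            seed=21,
        )
        sim = simulate_cohorts(design)
        null = fst_resampling_null(
            sim.diplotypes("2RL"),
            sim.frame,
            "region == 'East'",
            "region == 'West'",
            n_snps=500,
            n_iter=200,
            seed=0,
        )
        assert null.between.mean() > null.within_a.mean()
        assert null.p_within_a_vs_between < 1e-3
        assert null.p_within_b_vs_between < 1e-3

    def test_population_too_small_rejected(self, neutral_sim):
        with pytest.raises(ValueError, match="at least 2"):
            fst_resampling_null(
                neutral_sim.diplotypes("2RL"),
                neutral_sim.frame,
                "sample_id == 'S00001'",
                "region == 'West'",
                n_snps=100,
                n_iter=10,
            )


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(100, 6))
        base[:, 1] = base[:, 0]
        diplo = make_diploset(base)
        result = pca(diplo, n_components=2)
        np.testing.assert_allclose(
            result.coordinates[0], result.coordinates[1], atol=1e-9
        )

    def test_diverged_demes_separate_on_pc1(self):
        design = SimDesign(
            n_per_cell=10,
            contigs={"2RL": (1_000_000, 2_000)},
            d=3.0,
            sigma_h=0.0,
            sweeps=[],
            seed=13,
        )
        sim = simulate_cohorts(design)
        dip = sim.diplotypes("2RL")
        result = pca(dip, n_components=2)
        regions = sim.frame.table["region"].to_numpy()
        pc1 = result.coordinates[:, 0]
        from sklearn.metrics import silhouette_score

        assert silhouette_score(pc1.reshape(-1, 1), regions) > 0.8

    def test_explained_variance_monotone(self, neutral_sim):
        result = pca(neutral_sim.diplotypes("2RL"), n_components=5)
        assert np.all(np.diff(result.explained_variance) <= 1e-9)
        assert result.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_excess_components_rejected(self):
        diplo = make_diploset(np.array([[0, 1], [1, 2], [2, 0]]))
        with pytest.raises(ValueError, match="rank"):
            pca(diplo, n_components=5)
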