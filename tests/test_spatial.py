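"""Voronoi adjacency graphs and cell-to-cell interaction matrices."""

import itertools

import numpy as np
import pytest

from mibitime import (
    AdjacencyGraph,
    DataError,
    MarkerPanel,
    centroids,
    interaction_matrix,
    subset_features,
    voronoi_adjacency,
)
from mibitime.quant import CellRecord, ExtractedCell
from mibitime.spatial import radius_adjacency


def brute_force_adjacency(points: dict[int, tuple[float, float]]) -> set[frozenset]:
    """Independent oracle: (i, j) share a positive-length Voronoi border iff
    some point on their perpendicular bisector is strictly closer to both
    than to every other site (an open interval of empty-circumcircle
    centers).  Searched on a dense tan-spaced grid along the bisector."""
    ids = sorted(points)
    pts = {i: np.asarray(points[i], dtype=float) for i in ids}
    scale = max(
        np.linalg.norm(pts[a] - pts[b]) for a, b in itertools.combinations(ids, 2)
    )
    edges = set()
    thetas = np.linspace(-np.pi / 2 + 1e-6, np.pi / 2 - 1e-6, 4001)
    ts = np.tan(thetas) * scale
    for a, b in itertools.combinations(ids, 2):
        mid = (pts[a] + pts[b]) / 2
        d = pts[b] - pts[a]
        perp = np.array([-d[1], d[0]]) / np.linalg.norm(d)
        centers = mid[None, :] + ts[:, None] * perp[None, :]
        r2 = np.sum((centers - pts[a]) ** 2, axis=1)
        others = [k for k in ids if k not in (a, b)]
        if not others:
            edges.add(frozenset((a, b)))
            continue
        other_d2 = np.min(
            [np.sum((centers - pts[k]) ** 2, axis=1) for k in others], axis=0
        )
        if np.any(r2 * (1 + 1e-9) < other_d2):
            edges.add(frozenset((a, b)))
    return edges


class TestCentroids:
    def _cell(self, cid, pixels):
        return ExtractedCell(cid, "T", np.array(pixels))

    def test_square_block(self):
        c = centroids([self._cell(1, [(0, 0), (0, 1), (1, 0), (1, 1)])])
        assert c[1] == (0.5, 0.5)

    def test_single_pixel(self):
        assert centroids([self._cell(1, [(7, 3)])])[1] == (7.0, 3.0)

    def test_translation_equivariance(self, rng):
        pix = rng.integers(0, 20, size=(9, 2))
        base = centroids([self._cell(1, pix)])[1]
        moved = centroids([self._cell(1, pix + np.array([5, 11]))])[1]
        assert moved == pytest.approx((base[0] + 5, base[1] + 11))


class TestVoronoiAdjacency:
    def test_triangle_all_adjacent(self):
        g = voronoi_adjacency({1: (0, 0), 2: (4, 0), 3: (0, 4)})
        assert g.edges == frozenset(
            {frozenset((1, 2)), frozenset((1, 3)), frozenset((2, 3))}
        )

    def test_unit_square_diagonals_not_adjacent(self):
        """Cocircular degeneracy: the four corners' diagonal regions meet
        only at the center point — a point contact is not a border."""
        g = voronoi_adjacency({1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)})
        sides = {frozenset((1, 2)), frozenset((1, 3)), frozenset((2, 4)), frozenset((3, 4))}
        assert g.edges == frozenset(sides)

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            pts = {i + 1: tuple(rng.uniform(0, 100, 2)) for i in range(n)}
            g = voronoi_adjacency(pts)
            assert set(g.edges) == brute_force_adjacency(pts)

    def test_duplicate_centroids_error_names_cells(self):
        with pytest.raises(DataError, match="3"):
            voronoi_adjacency({1: (0, 0), 2: (1, 1), 3: (1, 1), 4: (2, 0)})

    def test_collinear_fallback_chains_neighbors(self):
        g = voronoi_adjacency({1: (0, 0), 2: (2, 0), 3: (1, 0), 4: (3, 0)})
        assert g.edges == frozenset(
            {frozenset((1, 3)), frozenset((3, 2)), frozenset((2, 4))}
        )

    def test_two_points_adjacent(self):
        g = voronoi_adjacency({5: (0, 0), 9: (3, 3)})
        assert g.edges == frozenset({frozenset((5, 9))})

    def test_similarity_invariance(self, rng):
        pts = rng.uniform(0, 10, size=(10, 2))
        base = voronoi_adjacency({i: tuple(p) for i, p in enumerate(pts)})
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pts @ R.T * 3.5 + np.array([100, -40])
        trans = voronoi_adjacency({i: tuple(p) for i, p in enumerate(moved)})
        assert base.edges == trans.edges

    def test_mean_degree_near_six_for_large_n(self, rng):
        pts = {i: tuple(rng.uniform(0, 1000, 2)) for i in range(500)}
        g = voronoi_adjacency(pts)
        mean_degree = 2 * len(g.edges) / len(g.nodes)
        assert 5.0 <= mean_degree <= 7.0


def make_record(cid, positive):
    r = CellRecord(cid, "p", "T", 1, (0.0, 0.0), mean_expression=np.zeros(1))
    r.positive_markers = set(positive)
    return r


MARKERS = ("IDO", "Lag3", "PD-1", "PD-L1")


class TestInteractionMatrix:
    def _graph(self, edges, nodes):
        return AdjacencyGraph(tuple(nodes), frozenset(frozenset(e) for e in edges))

    def test_cartesian_product_of_positive_sets(self):
        """Adjacency of a PD-L1+/Lag3+ cell and a PD-1+/IDO+ cell tallies
        the four combinations PD-L1+PD-1, PD-L1+IDO, Lag3+PD-1, Lag3+IDO."""
        recs = [make_record(1, {"PD-L1", "Lag3"}), make_record(2, {"PD-1", "IDO"})]
        m = interaction_matrix(self._graph([(1, 2)], [1, 2]), recs, MARKERS)
        df = m.to_frame()
        assert df.loc["PD-L1", "PD-1"] == 1
        assert df.loc["PD-L1", "IDO"] == 1
        assert df.loc["Lag3", "PD-1"] == 1
        assert df.loc["Lag3", "IDO"] == 1
        assert df.to_numpy().sum() == 8  # the 4 pairs, symmetric

    def test_homotypic_interaction_hits_diagonal(self):
        recs = [make_record(1, {"IDO"}), make_record(2, {"IDO"})]
        m = interaction_matrix(self._graph([(1, 2)], [1, 2]), recs, MARKERS)
        assert m.to_frame().loc["IDO", "IDO"] == 1
        assert m.counts.sum() == 1

    def test_matches_brute_force_oracle(self, rng):
        n = 30
        recs = [
            make_record(i, rng.choice(MARKERS, rng.integers(0, 5), replace=False))
            for i in range(n)
        ]
        all_pairs = list(itertools.combinations(range(n), 2))
        chosen = [all_pairs[k] for k in rng.choice(len(all_pairs), 60, replace=False)]
        g = self._graph(chosen, range(n))
        m = interaction_matrix(g, recs, MARKERS)
        P = len(MARKERS)
        oracle = np.zeros((P, P), dtype=int)
        for u, v in chosen:
            for a in recs[u].positive_markers:
                for b in recs[v].positive_markers:
                    i, j = MARKERS.index(a), MARKERS.index(b)
                    oracle[i, j] += 1
                    if i != j:
                        oracle[j, i] += 1
        np.testing.assert_array_equal(m.counts, oracle)

    def test_tally_mass_conservation(self, rng):
        recs = [
            make_record(i, rng.choice(MARKERS, rng.integers(0, 5), replace=False))
            for i in range(12)
        ]
        pts = {i: tuple(rng.uniform(0, 50, 2)) for i in range(12)}
        g = voronoi_adjacency(pts)
        m = interaction_matrix(g, recs, MARKERS)
        mass = np.triu(m.counts).sum()
        expected = sum(
            len(recs[u].positive_markers) * len(recs[v].positive_markers)
            for e in g.edges
            for u, v in [tuple(e)]
        )
        assert mass == expected


class TestSubsetFeatures:
    @pytest.fixture
    def panel(self):
        names = ["IDO", "Lag3", "PD-L1", "PD-1", "Ki67", "CD45RO", "CD45"]
        cats = ["functional"] * 6 + ["lineage"]
        return MarkerPanel.from_names(names, cats)

    @pytest.fixture
    def matrix(self, panel, rng):
        recs = [
            make_record(i, rng.choice(panel.names, rng.integers(0, 4), replace=False))
            for i in range(20)
        ]
        pts = {i: tuple(rng.uniform(0, 80, 2)) for i in range(20)}
        return interaction_matrix(voronoi_adjacency(pts), recs, panel.names)

    def test_immunoregulatory_submatrix_has_ten_entries(self, matrix, panel):
        feats = subset_features(matrix, "immunoregulatory", panel=panel)
        assert len(feats) == 10  # 4×4 upper triangle with diagonal

    def test_homotypic_diagonal_length(self, rng):
        markers18 = tuple(f"M{i:02d}" for i in range(18))
        from mibitime.coexpression import PairCountMatrix

        m = PairCountMatrix(markers18, np.zeros((18, 18), dtype=int), "interaction")
        assert len(subset_features(m, "homotypic_diagonal")) == 18

    def test_ablation_of_absent_marker_gives_zero_vector(self, panel):
        recs = [make_record(1, {"IDO"}), make_record(2, {"Lag3"})]
        g = AdjacencyGraph((1, 2), frozenset({frozenset((1, 2))}))
        m = interaction_matrix(g, recs, panel.names)
        feats = subset_features(m, "single_marker_ablation", target="Ki67")
        assert (feats == 0).all()

    def test_ablation_includes_target_diagonal(self, panel):
        recs = [make_record(1, {"IDO"}), make_record(2, {"IDO", "PD-1"})]
        g = AdjacencyGraph((1, 2), frozenset({frozenset((1, 2))}))
        m = interaction_matrix(g, recs, panel.names)
        feats = subset_features(m, "single_marker_ablation", target="IDO")
        assert feats["IDO+IDO"] == 1
        assert feats["IDO+PD-1"] == 1


def test_radius_adjacency_comparison_mode():
    pts = {1: (0.0, 0.0), 2: (0.0, 5.0), 3: (0.0, 20.0)}
    g = radius_adjacency(pts, radius=6.0)
    assert g.edges == frozenset({frozenset((1, 2))})
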