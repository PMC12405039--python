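"""Convex diagnosis subspaces: hulls, membership, separation, trajectories."""

import itertools

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from brainspaces import (
    build_subspace,
    classify_trajectory,
    contains,
    distance_to_subspace,
    hulls_disjoint,
)
from brainspaces.brain_space import Embedding
from brainspaces.state_builder import BrainState, ConnectivityMatrix
from brainspaces.subspaces import SubspaceModel


def dummy_state(state_id, diagnosis="x", subject_id=None, timepoint="baseline"):
    m = ConnectivityMatrix(("a", "b"), np.array([[1.0, 0.0], [0.0, 1.0]]))
    return BrainState(
        state_id=state_id,
        subject_id=subject_id or state_id,
        timepoint=timepoint,
        diagnosis=diagnosis,
        matrix=m,
    )


def embedding_of(coords, ids):
    coords = np.asarray(coords, dtype=float)
    return Embedding(
        state_ids=tuple(ids),
        coords=coords,
        dims=coords.shape[1],
        stress=0.0,
        method="classical",
    )


def subspace_from_points(points, label="x"):
    points = np.asarray(points, dtype=float)
    ids = [f"{label}{i}" for i in range(len(points))]
    emb = embedding_of(points, ids)
    states = [dummy_state(i, diagnosis=label) for i in ids]
    return build_subspace(emb, states, label)


class TestBuildSubspace:
    def test_four_affinely_independent_points_form_a_tetrahedron(self):
        s = subspace_from_points(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        )
        assert not s.degenerate
        assert len(s.hull_vertices) == 4

    def test_single_member_is_a_point_region(self):
        s = subspace_from_points([[2.0, 3.0, 4.0]])
        assert s.degenerate
        assert np.array_equal(s.hull_vertices, [[2.0, 3.0, 4.0]])
        assert contains(s, np.array([2.0, 3.0, 4.0]))

    def test_unknown_label_rejected(self):
        emb = embedding_of([[0.0, 0.0]], ["a"])
        with pytest.raises(ValueError, match="no state"):
            build_subspace(emb, [dummy_state("a", diagnosis="x")], "y")

    def test_interior_points_are_not_hull_vertices(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((10, 2))
        s = subspace_from_points(pts)
        poly = Polygon(s.hull_vertices).convex_hull
        # every member point lies inside the reported hull (oracle: shapely)
        for p in pts:
            assert poly.distance(Point(p)) <= 1e-9

    def test_all_members_contained(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((8, 3))
        s = subspace_from_points(pts)
        for p in pts:
            assert contains(s, p)


class TestContains:
    def test_triangle_centroid_inside(self):
        s = subspace_from_points([[0, 0], [1, 0], [0, 1]])
        assert contains(s, np.array([1 / 3, 1 / 3]))

    def test_point_beyond_face_is_outside(self):
        s = subspace_from_points([[0, 0], [1, 0], [0, 1]])
        tol = 1e-6
        assert not contains(s, np.array([0.5, -10 * tol]), tol=tol)

    def test_matches_shapely_membership_oracle_on_2d_hulls(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((12, 2))
        s = subspace_from_points(pts)
        poly = Polygon(pts).convex_hull
        probes = rng.uniform(-2.5, 2.5, size=(60, 2))
        for q in probes:
            oracle = poly.distance(Point(q)) <= 1e-9
            assert contains(s, q, tol=1e-9) == oracle

    def test_distance_matches_shapely_for_outside_points(self):
        rng = np.random.default_rng(21)
        pts = rng.standard_normal((7, 2))
        s = subspace_from_points(pts)
        poly = Polygon(pts).convex_hull
        for q in rng.uniform(-4, 4, size=(20, 2)):
            assert distance_to_subspace(s, q) == pytest.approx(
                poly.distance(Point(q)), abs=1e-6
            )

    def test_degenerate_segment_uses_affine_distance(self):
        s = subspace_from_points([[0.0, 0.0], [1.0, 0.0]])  # 2 points in 2D
        assert s.degenerate
        assert contains(s, np.array([0.5, 0.0]))
        assert distance_to_subspace(s, np.array([0.5, 2.0])) == pytest.approx(2.0, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        s = subspace_from_points([[0, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="shape"):
            contains(s, np.array([0.1, 0.1, 0.1]))


class TestHullsDisjoint:
    def test_collinear_segments_with_unit_gap(self):
        a = subspace_from_points([[0.0, 0.0], [1.0, 0.0]], "a")
        b = subspace_from_points([[2.0, 0.0], [3.0, 0.0]], "b")
        disjoint, witness = hulls_disjoint(a, b, tol=1e-9)
        assert disjoint
        assert witness["distance"] == pytest.approx(1.0, abs=1e-6)

    def test_triangles_sharing_a_vertex_are_not_disjoint(self):
        a = subspace_from_points([[0, 0], [1, 0], [0, 1]], "a")
        b = subspace_from_points([[0, 0], [-1, 0], [0, -1]], "b")
        disjoint, witness = hulls_disjoint(a, b, tol=1e-6)
        assert not disjoint
        assert witness["distance"] <= 1e-6

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = subspace_from_points(rng.standard_normal((5, 2)), "a")
        b = subspace_from_points(rng.standard_normal((5, 2)) + 5.0, "b")
        dis_ab, w_ab = hulls_disjoint(a, b)
        dis_ba, w_ba = hulls_disjoint(b, a)
        assert dis_ab == dis_ba
        assert w_ab["distance"] == pytest.approx(w_ba["distance"], abs=1e-6)

    def test_matches_shapely_distance_on_separated_clusters(self):
        rng = np.random.default_rng(17)
        pa = rng.standard_normal((6, 2))
        pb = rng.standard_normal((6, 2)) + np.array([6.0, 0.0])
        a = subspace_from_points(pa, "a")
        b = subspace_from_points(pb, "b")
        disjoint, witness = hulls_disjoint(a, b)
        assert disjoint
        expected = Polygon(pa).convex_hull.distance(Polygon(pb).convex_hull)
        assert witness["distance"] == pytest.approx(expected, abs=1e-5)


class TestClassifyTrajectory:
    @staticmethod
    def truth_table_verdict(inside):
        """Independent statement of the three rules."""
        if all(inside):
            return "healthy-stable"
        flips = sum(a != b for a, b in zip(inside, inside[1:]))
        if flips >= 2:
            return "oscillating"
        return "diseased"

    def _run(self, inside_sequence):
        healthy = subspace_from_points([[0, 0], [1, 0], [0, 1]], "healthy")
        coords, ids, states = [], [], []
        for t, inside in enumerate(inside_sequence):
            coords.append([0.25, 0.25] if inside else [5.0, 5.0])
            sid = f"subj@t{t}"
            ids.append(sid)
            states.append(
                dummy_state(sid, diagnosis="?", subject_id="subj", timepoint=f"t{t}")
            )
        emb = embedding_of(coords, ids)
        return classify_trajectory(emb, healthy, states)

    def test_all_inside_is_healthy_stable(self):
        assert self._run([True, True, True]).verdict == "healthy-stable"

    def test_alternating_is_oscillating(self):
        v = self._run([True, False, True, False])
        assert v.verdict == "oscillating"
        assert v.regions == ("healthy", "outside", "healthy", "outside")

    def test_exhaustive_sequences_up_to_length_four(self):
        for length in range(1, 5):
            for inside in itertools.product([True, False], repeat=length):
                assert self._run(inside).verdict == self.truth_table_verdict(inside), inside

    def test_multiple_subjects_rejected(self):
        healthy = subspace_from_points([[0, 0], [1, 0], [0, 1]], "h")
        emb = embedding_of([[0, 0], [1, 1]], ["a@t0", "b@t0"])
        states = [dummy_state("a@t0", subject_id="a"), dummy_state("b@t0", subject_id="b")]
        with pytest.raises(ValueError, match="multiple subjects"):
            classify_trajectory(emb, healthy, states)
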