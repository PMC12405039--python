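"""Convex subspace models of diagnoses in the embedded brain space.

Each diagnosis label defines a region: the convex hull of its member
states' MDS coordinates — with a handful of states this is a simplex, a
point, or a segment.  Membership in the healthy region is the primitive
behind the stability criterion: a brain is healthy-stable when all of
its states over time lie inside the healthy subspace; disease shows up
as states outside it, and relapsing-remitting conditions as repeated
crossings of its boundary.

Geometry is done on the member points themselves: a point is inside a
region iff it is a convex combination of the members (a linear
feasibility problem), and distances to/between regions are small convex
least-squares problems over the probability simplex.  This treats
degenerate hulls (fewer than D+1 affinely independent members — the
typical small-cohort regime) uniformly, with no special casing beyond a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog, minimize
from scipy.spatial import ConvexHull, QhullError

from .brain_space import Embedding
from .state_builder import BrainState

__all__ = [
    "SubspaceModel",
    "TrajectoryVerdict",
    "build_subspace",
    "contains",
    "distance_to_subspace",
    "hulls_disjoint",
    "classify_trajectory",
]

#: Default geometric tolerance for membership and disjointness tests.
GEOM_TOL = 1e-9


@dataclass(frozen=True)
class SubspaceModel:
    """Convex region spanned by the embedded states of one diagnosis."""

    label: str
    member_state_ids: tuple[str, ...]
    points: np.ndarray  # (V, D) member coordinates (hull generators)
    hull_vertices: np.ndarray  # (H, D) extreme points
    dims: int
    degenerate: bool  # fewer than D+1 affinely independent members

    @property
    def n_members(self) -> int:
        return len(self.member_state_ids)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class TrajectoryVerdict:
    """Per-timepoint region membership of one subject, plus the verdict."""

    subject_id: str
    timepoints: tuple[str, ...]
    regions: tuple[str, ...]  # region label or "outside" per timepoint
    verdict: str  # "healthy-stable" | "diseased" | "oscillating"


def build_subspace(
    emb: Embedding, states: Sequence[BrainState], label: str
) -> SubspaceModel:
    """Convex hull of the embedded states carrying ``label``.

    One member yields a point region, two a segment; sets that do not
    span full dimension are flagged degenerate and represented by their
    member points directly (the convex operations below never need a
    facet description).
    """
    members = [s for s in states if s.diagnosis == label]
    if not members:
        raise ValueError(f"no state carries diagnosis label {label!r}")
    ids = tuple(s.state_id for s in members)
    pts = np.stack([emb.coords_of(s.state_id) for s in members])
    dims = emb.dims
    degenerate = True
    vertices = np.unique(pts, axis=0)
    if pts.shape[0] >= dims + 1:
        try:
            hull = ConvexHull(pts)
            vertices = pts[hull.vertices]
            degenerate = False
        except QhullError:
            degenerate = True  # affinely dependent members
    return SubspaceModel(
        label=label,
        member_state_ids=ids,
        points=pts,
        hull_vertices=vertices,
        dims=dims,
        degenerate=degenerate,
    )


def _in_convex_hull(points: np.ndarray, x: np.ndarray, tol: float) -> bool:
    """Exact membership: is x a convex combination of the rows of points?

    Solved as an LP feasibility problem; reliable in any dimension and
    for degenerate point sets.
    """
    v, d = points.shape
    a_eq = np.vstack([points.T, np.ones((1, v))])
    b_eq = np.concatenate([x, [1.0]])
    res = linprog(
        c=np.zeros(v),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(0.0, 1.0)] * v,
        method="highs",
    )
    if not res.success:
        return False
    recon = points.T @ res.x
    return bool(np.linalg.norm(recon - x) <= max(tol, 1e-8))


def distance_to_subspace(s: SubspaceModel, point: np.ndarray) -> float:
    """Euclidean distance from a point to the convex region (0 if inside)."""
    point = np.asarray(point, dtype=float)
    if point.shape != (s.dims,):
        raise ValueError(f"point has shape {point.shape}, expected ({s.dims},)")
    pts = s.points
    if _in_convex_hull(pts, point, GEOM_TOL):
        return 0.0
    v = pts.shape[0]
    if v == 1:
        return float(np.linalg.norm(pts[0] - point))

    def objective(lam: np.ndarray) -> float:
        r = pts.T @ lam - point
        return float(r @ r)

    def grad(lam: np.ndarray) -> np.ndarray:
        return 2.0 * (pts @ (pts.T @ lam - point))

    res = minimize(
        objective,
        x0=np.full(v, 1.0 / v),
        jac=grad,
        bounds=[(0.0, 1.0)] * v,
        constraints=[{"type": "eq", "fun": lambda l: l.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return float(np.sqrt(max(res.fun, 0.0)))


def contains(s: SubspaceModel, point: np.ndarray, tol: float = GEOM_TOL) -> bool:
    """True iff the point lies inside, on, or within ``tol`` of the region."""
    point = np.asarray(point, dtype=float)
    if point.shape != (s.dims,):
        raise ValueError(f"point has shape {point.shape}, expected ({s.dims},)")
    if _in_convex_hull(s.points, point, tol):
        return True
    return distance_to_subspace(s, point) <= tol


def hulls_disjoint(
    a: SubspaceModel, b: SubspaceModel, tol: float = GEOM_TOL
) -> tuple[bool, dict]:
    """Separation test between two convex regions.

    Returns (disjoint, witness): disjoint iff the minimum distance
    between the regions exceeds ``tol``; the witness carries the closest
    point pair and the achieved distance (an intersection point when the
    regions overlap).
    """
    if a.dims != b.dims:
        raise ValueError("subspaces have different dimensions")
    pa, pb = a.points, b.points
    va, vb = pa.shape[0], pb.shape[0]

    def objective(z: np.ndarray) -> float:
        r = pa.T @ z[:va] - pb.T @ z[va:]
        return float(r @ r)

    def grad(z: np.ndarray) -> np.ndarray:
        r = pa.T @ z[:va] - pb.T @ z[va:]
        return np.concatenate([2.0 * (pa @ r), -2.0 * (pb @ r)])

    res = minimize(
        objective,
        x0=np.concatenate([np.full(va, 1.0 / va), np.full(vb, 1.0 / vb)]),
        jac=grad,
        bounds=[(0.0, 1.0)] * (va + vb),
        constraints=[
            {"type": "eq", "fun": lambda z: z[:va].sum() - 1.0},
            {"type": "eq", "fun": lambda z: z[va:].sum() - 1.0},
        ],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    pt_a = pa.T @ res.x[:va]
    pt_b = pb.T @ res.x[va:]
    dist = float(np.linalg.norm(pt_a - pt_b))
    witness = {
        "point_a": pt_a,
        "point_b": pt_b,
        "distance": dist,
        "label_a": a.label,
        "label_b": b.label,
    }
    return dist > tol, witness


def classify_trajectory(
    emb: Embedding,
    healthy: SubspaceModel,
    subject_states: Sequence[BrainState],
    tol: float = GEOM_TOL,
) -> TrajectoryVerdict:
    """Verdict on one subject's time-ordered sequence of states.

    healthy-stable: every timepoint inside the healthy region.
    oscillating: the inside/outside indicator flips at least twice
    (relapsing-remitting pattern).  diseased: anything else — the
    trajectory leaves (or never enters) the healthy region without the
    back-and-forth signature; a single exit ending outside, and a single
    entry not yet shown to be stable, both land here.
    """
    if not subject_states:
        raise ValueError("need at least one timepoint")
    subjects = {s.subject_id for s in subject_states}
    if len(subjects) != 1:
        raise ValueError(f"states span multiple subjects: {sorted(subjects)}")
    inside = [
        contains(healthy, emb.coords_of(s.state_id), tol=tol)
        for s in subject_states
    ]
    regions = tuple(healthy.label if i else "outside" for i in inside)
    if all(inside):
        verdict = "healthy-stable"
    else:
        flips = sum(1 for x, y in zip(inside, inside[1:]) if x != y)
        verdict = "oscillating" if flips >= 2 else "diseased"
    return TrajectoryVerdict(
        subject_id=subject_states[0].subject_id,
        timepoints=tuple(s.timepoint for s in subject_states),
        regions=regions,
        verdict=verdict,
    )
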