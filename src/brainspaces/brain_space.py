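"""The brain space: pairwise Frobenius distances and their MDS embedding.

Each harmonized brain state is a point; the dissimilarity between two
states is the Frobenius norm of the difference of their connectivity
matrices, taken over off-diagonal entries only (the diagonal is
identically 1 and carries no information).  Multidimensional scaling of
the resulting distance matrix arranges the states in a low-dimensional
space — by default 3 dimensions — in which proximity means similarity of
the underlying connectomes.

Two MDS flavours are provided: classical (Torgerson double-centering +
spectral factorization; fully deterministic) and SMACOF stress
majorization (seeded).  MDS coordinates are defined only up to rotation
and reflection; comparisons should use inter-point distances or a
Procrustes alignment, never raw axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.manifold import smacof as _sk_smacof

from .state_builder import BrainStateCollection, ConnectivityMatrix

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "frobenius_distance",
    "distance_matrix",
    "embed_mds",
]

#: Fraction of negative eigenvalue mass above which a distance matrix is
#: flagged as badly non-Euclidean.
NEGATIVE_MASS_WARN = 0.30


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative inter-state distances with zero diagonal."""

    state_ids: tuple[str, ...]
    values: np.ndarray  # shape (M, M)
    metric_name: str = "frobenius"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "state_ids", tuple(self.state_ids))
        m = len(self.state_ids)
        if v.shape != (m, m):
            raise ValueError(f"shape {v.shape} does not match {m} state ids")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class Embedding:
    """Coordinates of each state in the reduced brain space.

    ``stress`` is Kruskal stress-1: sqrt(sum (d_hat - d)^2 / sum d^2),
    zero when the embedded configuration reproduces the input distances
    exactly (and by convention zero for an all-zero distance matrix).
    """

    state_ids: tuple[str, ...]
    coords: np.ndarray  # shape (M, D)
    dims: int
    stress: float
    method: str
    seed: int | None = None
    eigenvalues: np.ndarray | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_ids", tuple(self.state_ids))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (len(self.state_ids), self.dims):
            raise ValueError("coords shape does not match state_ids x dims")

    def coords_of(self, state_id: str) -> np.ndarray:
        try:
            i = self.state_ids.index(state_id)
        except ValueError:
            raise KeyError(f"state {state_id!r} not in embedding") from None
        return self.coords[i]

    def embedded_distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def distance_fidelity(self, d: DistanceMatrix) -> float:
        """Spearman correlation between input and embedded distances."""
        iu = np.triu_indices(len(self.state_ids), k=1)
        rho = spearmanr(d.values[iu], self.embedded_distances()[iu]).statistic
        return float(rho)


def frobenius_distance(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Frobenius distance between two connectomes, off-diagonal entries only.

    Equals ``sqrt(2) * ||triu(a - b)||_F`` — i.e. both symmetric copies of
    each ROI pair count, matching the full-matrix Frobenius norm since the
    diagonal difference is identically zero.
    """
    if a.roi_labels != b.roi_labels:
        for la, lb in zip(a.roi_labels, b.roi_labels):
            if la != lb:
                raise ValueError(f"ROI label mismatch: {la!r} vs {lb!r}")
        raise ValueError(
            f"ROI label count mismatch: {len(a.roi_labels)} vs {len(b.roi_labels)}"
        )
    va, vb = a.values, b.values
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValueError("matrices must have no missing entries (harmonize first)")
    diff = va - vb
    np.fill_diagonal(diff, 0.0)  # diff is a fresh array; diagonal carries no signal
    return float(np.linalg.norm(diff))


def distance_matrix(c: BrainStateCollection) -> DistanceMatrix:
    """All-pairs Frobenius distance over a harmonized collection."""
    if len(c) < 2:
        raise ValueError("need at least 2 states")
    if not c.common_rois:
        raise ValueError("collection is not harmonized (no common_rois)")
    stack = c.matrices()
    if np.isnan(stack).any():
        raise ValueError("collection contains missing entries; harmonize first")
    m = len(c)
    n = stack.shape[1]
    mask = ~np.eye(n, dtype=bool)
    flat = stack[:, mask]  # (M, N(N-1)) off-diagonal entries
    d = np.sqrt(
        np.maximum(
            ((flat[:, None, :] - flat[None, :, :]) ** 2).sum(axis=-1), 0.0
        )
    )
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(tuple(c.state_ids), d)


def _classical_mds(d: np.ndarray, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling: returns (coords, full eigenvalue spectrum)."""
    m = d.shape[0]
    d2 = d**2
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    # descending eigenvalues; stable tie-break by original (ascending) index
    order = np.argsort(-eigval, kind="stable")
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(lam)
    return coords, eigval


def _stress1(coords: np.ndarray, d: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    dhat = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(d.shape[0], k=1)
    denom = (d[iu] ** 2).sum()
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((dhat[iu] - d[iu]) ** 2).sum() / denom))


def embed_mds(
    d: DistanceMatrix,
    dims: int = 3,
    method: str = "classical",
    seed: int | None = None,
    n_init: int = 4,
) -> Embedding:
    """Embed states into ``dims`` dimensions by multidimensional scaling.

    ``classical`` is deterministic and exact for Euclidean-realizable
    distance matrices; ``smacof`` iteratively minimises raw stress from a
    seeded random initialisation (``n_init`` restarts, best kept).
    """
    m = d.n_states
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > m - 1:
        raise ValueError(f"dims={dims} exceeds M-1={m - 1} for {m} states")
    warnings: list[str] = []
    if method == "classical":
        coords, eigval = _classical_mds(d.values, dims)
        total = np.abs(eigval).sum()
        if total > 0 and np.abs(eigval[eigval < 0]).sum() > NEGATIVE_MASS_WARN * total:
            warnings.append(
                "negative eigenvalue mass exceeds 30% of spectrum; "
                "distances are badly non-Euclidean"
            )
        stress = _stress1(coords, d.values)
        return Embedding(
            state_ids=d.state_ids,
            coords=coords,
            dims=dims,
            stress=stress,
            method="classical",
            seed=seed,
            eigenvalues=eigval,
            warnings=tuple(warnings),
        )
    if method == "smacof":
        if d.values.max() == 0.0:
            coords = np.zeros((m, dims))
        else:
            coords, _ = _sk_smacof(
                d.values,
                n_components=dims,
                n_init=n_init,
                random_state=seed,
                normalized_stress=False,
                max_iter=1000,
                eps=1e-12,
            )
        stress = _stress1(coords, d.values)
        return Embedding(
            state_ids=d.state_ids,
            coords=coords,
            dims=dims,
            stress=stress,
            method="smacof",
            seed=seed,
            warnings=tuple(warnings),
        )
    raise ValueError(f"unknown MDS method {method!r}")
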