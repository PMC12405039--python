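"""Build validated brain states from ROI time series or precomputed matrices.

A *brain state* is one subject's functional connectome at one timepoint:
a symmetric, correlation-valued matrix over a labelled set of regions of
interest (ROIs), plus the clinical metadata (diagnosis, age, sex) needed
downstream.  This module turns raw inputs into such states and harmonizes
a cohort onto the ROI set present in *every* state, which is the
precondition for any inter-state distance.

Missing ROIs (e.g. parcels outside a subject's field of view) are
represented as entirely-NaN rows/columns; a partially observed ROI is an
input error, not a missing ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "BrainState",
    "BrainStateCollection",
    "compute_connectivity",
    "harmonize_rois",
]

#: Symmetry tolerance for validating connectivity matrices.
SYMMETRY_TOL = 1e-12
#: Entries this close to +/-1 are clamped; anything further outside errors.
CLAMP_TOL = 1e-9


def _check_unique_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(l).strip() for l in labels]
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dupes = sorted({l for l in labels if l in seen or seen.add(l)})
        raise ValueError(f"duplicate ROI labels: {dupes}")
    return labels


@dataclass(frozen=True)
class ROITimeSeries:
    """Per-ROI signal, rows = time points, columns = ROIs.

    A column may be entirely NaN (missing ROI) but not partially NaN.
    """

    state_id: str
    roi_labels: tuple[str, ...]
    samples: np.ndarray  # shape (T, N)
    sampling_note: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        labels = tuple(_check_unique_labels(self.roi_labels))
        object.__setattr__(self, "roi_labels", labels)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (T, N)")
        T, N = samples.shape
        if N != len(labels):
            raise ValueError(f"{len(labels)} labels but {N} signal columns")
        if N < 2:
            raise ValueError("need at least 2 ROIs")
        if T < 3:
            raise ValueError(f"need at least 3 time points, got {T}")
        nan_counts = np.isnan(samples).sum(axis=0)
        partial = (nan_counts > 0) & (nan_counts < T)
        if partial.any():
            bad = [labels[i] for i in np.flatnonzero(partial)]
            raise ValueError(f"partially missing ROI columns: {bad}")

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[0]

    @property
    def missing_rois(self) -> tuple[str, ...]:
        mask = np.isnan(self.samples).all(axis=0)
        return tuple(l for l, m in zip(self.roi_labels, mask) if m)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Labelled symmetric connectivity matrix with unit diagonal.

    Entries lie in [-1, 1] (Pearson) unless ``fisher_z`` is set, in which
    case off-diagonal entries are unbounded z-values.  A missing ROI is an
    entirely-NaN row and column.
    """

    roi_labels: tuple[str, ...]
    values: np.ndarray  # shape (N, N)
    fisher_z: bool = False

    def __post_init__(self) -> None:
        labels = tuple(_check_unique_labels(self.roi_labels))
        object.__setattr__(self, "roi_labels", labels)
        v = np.array(self.values, dtype=float)
        n = len(labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        finite = ~np.isnan(v)
        if not np.allclose(
            np.where(finite & finite.T, v, 0.0),
            np.where(finite & finite.T, v.T, 0.0),
            atol=SYMMETRY_TOL,
            rtol=0.0,
        ):
            raise ValueError(f"matrix not symmetric within {SYMMETRY_TOL}")
        row_nan = np.isnan(v).all(axis=1)
        col_nan = np.isnan(v).all(axis=0)
        if not np.array_equal(row_nan, col_nan):
            raise ValueError("missing ROI must blank both its row and column")
        # NaNs outside fully-missing rows/columns are invalid
        present = ~row_nan
        sub = v[np.ix_(present, present)]
        if np.isnan(sub).any():
            raise ValueError("NaN entries outside fully-missing rows/columns")
        if not self.fisher_z:
            over = np.abs(sub) - 1.0
            if (over > CLAMP_TOL).any():
                raise ValueError(
                    f"entries outside [-1, 1] beyond tolerance: max excess {over.max():.3g}"
                )
            np.clip(v[np.ix_(present, present)], -1.0, 1.0, out=sub)
            v[np.ix_(present, present)] = sub
        diag = np.diag(v)[present]
        if not np.allclose(diag, 1.0, atol=1e-9):
            raise ValueError("diagonal of present ROIs must be 1")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def missing_rois(self) -> tuple[str, ...]:
        mask = np.isnan(self.values).all(axis=1)
        return tuple(l for l, m in zip(self.roi_labels, mask) if m)

    @property
    def present_rois(self) -> tuple[str, ...]:
        missing = set(self.missing_rois)
        return tuple(l for l in self.roi_labels if l not in missing)

    def restrict(self, labels: Sequence[str]) -> "ConnectivityMatrix":
        """Slice to the given ROI labels, in the given order."""
        labels = [str(l).strip() for l in labels]
        index = {l: i for i, l in enumerate(self.roi_labels)}
        try:
            idx = [index[l] for l in labels]
        except KeyError as exc:
            raise KeyError(f"ROI {exc.args[0]!r} not in matrix") from None
        return ConnectivityMatrix(
            roi_labels=tuple(labels),
            values=self.values[np.ix_(idx, idx)],
            fisher_z=self.fisher_z,
        )


@dataclass(frozen=True)
class BrainState:
    """One subject-at-timepoint connectome with its metadata."""

    state_id: str
    subject_id: str
    timepoint: str
    diagnosis: str
    matrix: ConnectivityMatrix
    age: float | None = None
    sex: str | None = None

    def with_matrix(self, matrix: ConnectivityMatrix) -> "BrainState":
        return replace(self, matrix=matrix)


@dataclass
class BrainStateCollection:
    """A harmonized cohort: every matrix restricted to ``common_rois``."""

    states: list[BrainState]
    common_rois: tuple[str, ...]
    removed_per_state: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]

    def get(self, state_id: str) -> BrainState:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(f"no state with id {state_id!r}")

    def matrices(self) -> np.ndarray:
        """Stack all matrices into an (M, N, N) array."""
        return np.stack([s.matrix.values for s in self.states])


def compute_connectivity(
    ts: ROITimeSeries,
    transform: Literal["raw_pearson", "fisher_z"] = "raw_pearson",
) -> ConnectivityMatrix:
    """Pearson functional connectivity of an ROI time series.

    Entry (i, j) is the Pearson correlation of the two ROI signals;
    ``fisher_z`` applies arctanh to off-diagonal entries (variance
    stabilisation), leaving the diagonal at 1 by convention.  Missing
    ROIs propagate to all-NaN rows/columns.  A present ROI with zero
    signal variance has no defined correlation and is a hard error.
    """
    if transform not in ("raw_pearson", "fisher_z"):
        raise ValueError(f"unknown transform {transform!r}")
    X = ts.samples
    T, N = X.shape
    missing = np.isnan(X).all(axis=0)
    present = np.flatnonzero(~missing)
    if present.size < 2:
        raise ValueError("need at least 2 non-missing ROIs")
    sub = X[:, present]
    std = sub.std(axis=0)
    zero_var = np.flatnonzero(std == 0.0)
    if zero_var.size:
        bad = [ts.roi_labels[present[i]] for i in zero_var]
        raise ValueError(f"zero-variance ROI signal: {bad}")
    corr_sub = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(corr_sub, 1.0)
    corr_sub = np.clip((corr_sub + corr_sub.T) / 2.0, -1.0, 1.0)
    values = np.full((N, N), np.nan)
    values[np.ix_(present, present)] = corr_sub
    if transform == "fisher_z":
        off = ~np.eye(N, dtype=bool)
        with np.errstate(divide="ignore"):
            values[off] = np.arctanh(np.clip(values[off], -1.0, 1.0))
        return ConnectivityMatrix(ts.roi_labels, values, fisher_z=True)
    return ConnectivityMatrix(ts.roi_labels, values)


def harmonize_rois(states: Sequence[BrainState]) -> BrainStateCollection:
    """Restrict every state to the ROIs present in *all* states.

    The retained set is ordered as in the first state.  The ROIs dropped
    from each state are logged and recorded on the collection, so the
    "kept K out of N atlas regions" bookkeeping is reproducible.
    """
    if len(states) < 2:
        raise ValueError("harmonization needs at least 2 states")
    ids = [s.state_id for s in states]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate state_id in cohort")
    key_pairs = [(s.subject_id, s.timepoint) for s in states]
    if len(set(key_pairs)) != len(key_pairs):
        raise ValueError("duplicate (subject_id, timepoint) in cohort")
    present_sets = [set(s.matrix.present_rois) for s in states]
    common = set.intersection(*present_sets)
    ordered = tuple(l for l in states[0].matrix.roi_labels if l in common)
    if len(ordered) < 2:
        raise ValueError(
            f"only {len(ordered)} ROI(s) present in all states; cannot build a space"
        )
    removed: dict[str, tuple[str, ...]] = {}
    harmonized = []
    for s in states:
        dropped = tuple(l for l in s.matrix.roi_labels if l not in common)
        removed[s.state_id] = dropped
        if dropped:
            logger.info("state %s: removed %d ROI(s)", s.state_id, len(dropped))
        harmonized.append(s.with_matrix(s.matrix.restrict(ordered)))
    logger.info(
        "harmonized %d states onto %d common ROIs", len(states), len(ordered)
    )
    return BrainStateCollection(
        states=harmonized, common_rois=ordered, removed_per_state=removed
    )
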