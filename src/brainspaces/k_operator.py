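"""Disease-progression operators between brain states.

The K-operator maps a subject's connectome at one timepoint to the next:
K applied to the baseline state yields the follow-up state.  Between two
measured states K has a concrete numerical form — here a finite
difference.  In additive mode K is the element-wise change in link
weights (target - source); positive cells are strengthened connections,
negative cells weakened ones.  The ideal healing is the inverse
operator, which in additive mode is simply the negated change.

The same path can be read in the reduced MDS space: per-dimension
percentage variation of the coordinates (100 * |delta| / |baseline|),
plus a decomposition of the path along one axis into per-pair
contributions, each the pair's connectivity change scaled by its
correlation with that axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import pair_index
from .brain_space import Embedding
from .state_builder import BrainState

__all__ = [
    "KOperator",
    "ReducedPath",
    "compute_k",
    "invert_k",
    "apply_k",
    "reduced_path",
    "pair_contributions",
]

#: A reduced-space source coordinate below this magnitude has no defined
#: percentage variation; the absolute change is reported instead.
ZERO_COORD_TOL = 1e-12


@dataclass(frozen=True)
class KOperator:
    """Link-weight change between two harmonized brain states."""

    source_state_id: str
    target_state_id: str
    mode: str  # "additive" | "multiplicative"
    values: np.ndarray  # (N, N); NaN marks undefined cells (multiplicative)
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        n = len(self.roi_labels)
        if v.shape != (n, n):
            raise ValueError("operator shape does not match ROI labels")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass(frozen=True)
class ReducedPath:
    """A state-to-state path in MDS coordinates, per-dimension."""

    source_state_id: str
    target_state_id: str
    source_coords: np.ndarray
    target_coords: np.ndarray
    abs_change: np.ndarray
    pct_variation: np.ndarray  # NaN where the source coordinate is ~0

    def as_dict(self) -> dict:
        return {
            "source": self.source_state_id,
            "target": self.target_state_id,
            "source_coords": self.source_coords.tolist(),
            "target_coords": self.target_coords.tolist(),
            "abs_change": self.abs_change.tolist(),
            "pct_variation": [
                None if np.isnan(x) else x for x in self.pct_variation
            ],
        }


def compute_k(
    source: BrainState, target: BrainState, mode: str = "additive"
) -> KOperator:
    """Numerical K-operator between two states over the same ROI set.

    Additive: values = target - source, so source + K reproduces the
    target exactly.  Multiplicative: element-wise target / source, with
    zero-source cells masked as NaN (and counted in ``n_undefined``).
    """
    if source.matrix.roi_labels != target.matrix.roi_labels:
        raise ValueError("states are not harmonized to the same ROI set")
    a, b = source.matrix.values, target.matrix.values
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("states contain missing entries; harmonize first")
    if mode == "additive":
        values = b - a
    elif mode == "multiplicative":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(a != 0.0, b / a, np.nan)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return KOperator(
        source_state_id=source.state_id,
        target_state_id=target.state_id,
        mode=mode,
        values=values,
        roi_labels=source.matrix.roi_labels,
    )


def apply_k(k: KOperator, matrix: np.ndarray) -> np.ndarray:
    """Apply the operator to a connectivity matrix (element-wise)."""
    if k.mode == "additive":
        return matrix + k.values
    if k.n_undefined:
        raise ValueError("multiplicative operator has undefined cells")
    return matrix * k.values


def invert_k(k: KOperator) -> KOperator:
    """The healing operator: undoes K, swapping source and target."""
    if k.mode == "additive":
        values = -k.values
    else:
        if k.n_undefined or (k.values == 0.0).any():
            raise ValueError(
                "multiplicative inversion needs all cells defined and nonzero"
            )
        values = 1.0 / k.values
    return KOperator(
        source_state_id=k.target_state_id,
        target_state_id=k.source_state_id,
        mode=k.mode,
        values=values,
        roi_labels=k.roi_labels,
    )


def reduced_path(emb: Embedding, source_id: str, target_id: str) -> ReducedPath:
    """Per-dimension percentage variation of the path between two states.

    pct_variation[d] = 100 * |target[d] - source[d]| / |source[d]|;
    dimensions whose source coordinate is (numerically) zero report NaN
    there, with the absolute change carrying the information.
    """
    src = emb.coords_of(source_id)
    tgt = emb.coords_of(target_id)
    delta = tgt - src
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(delta) / np.abs(src)
    pct = np.where(np.abs(src) < ZERO_COORD_TOL, np.nan, pct)
    # source == target on a zero coordinate is a zero-percent change
    pct = np.where(
        (np.abs(src) < ZERO_COORD_TOL) & (np.abs(delta) < ZERO_COORD_TOL), 0.0, pct
    )
    return ReducedPath(
        source_state_id=source_id,
        target_state_id=target_id,
        source_coords=src.copy(),
        target_coords=tgt.copy(),
        abs_change=np.abs(delta),
        pct_variation=pct,
    )


def pair_contributions(
    k: KOperator,
    pair_corr: np.ndarray,
    axis: int,
    top_k: int | None = None,
    roi_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Decompose an additive K along one MDS axis, pair by pair.

    For each ROI pair, the estimated contribution to the axis is the
    pair's connectivity change times its pair-axis correlation; since
    |correlation| <= 1 the contribution never exceeds the raw change in
    magnitude.  Rows are ranked by |contribution| descending.  Signs are
    meaningful only within the embedding the correlations came from
    (MDS axes have arbitrary orientation).
    """
    if k.mode != "additive":
        raise ValueError("pair contributions require an additive operator")
    pair_corr = np.asarray(pair_corr, dtype=float)
    if not 0 <= axis < pair_corr.shape[1]:
        raise ValueError(f"axis {axis} out of range for {pair_corr.shape[1]} dims")
    labels = roi_labels if roi_labels is not None else k.roi_labels
    pairs = pair_index(len(labels))
    if len(pairs) != pair_corr.shape[0]:
        raise ValueError("pair_corr rows do not match the operator's ROI pairs")
    changes = np.array([k.values[i, j] for i, j in pairs])
    corr = pair_corr[:, axis]
    contrib = changes * corr
    df = pd.DataFrame(
        {
            "roi_i": [labels[i] for i, _ in pairs],
            "roi_j": [labels[j] for _, j in pairs],
            "connectivity_change": changes,
            "axis_corr": corr,
            "estimated_contribution": contrib,
        }
    )
    df = df.reindex(
        df["estimated_contribution"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
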