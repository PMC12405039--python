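"""Attribute MDS axes to ROI pairs and individual ROIs.

Each MDS axis is, implicitly, a weighted combination of connectivity
entries; this module makes the weights explicit.  For every ROI pair
(i, j), i < j, the pair's connectivity value across states is correlated
(Pearson) with each axis coordinate — a high |correlation| means the
pair discriminates between brain states along that axis.  Pairs are also
ranked by the plain cross-state sample variance of their connectivity
entry (influence regardless of axis).  The individual impact of an ROI
on an axis is half the sum of the correlations of all pairs containing
it — the 1/2 factor splits each pair's contribution evenly between its
two endpoints so that no pair is counted twice; per axis, the ROI
impacts therefore sum exactly to the sum of pair correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brain_space import Embedding
from .state_builder import BrainStateCollection

__all__ = [
    "AttributionTable",
    "pair_features",
    "pair_index",
    "pair_axis_correlation",
    "pair_variance_ranking",
    "roi_impact",
    "top_rois",
    "attribute",
]


def pair_index(n: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j) pairs, i < j, over n ROIs."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def pair_features(c: BrainStateCollection) -> np.ndarray:
    """Vectorize each state's strict upper triangle into an (M, P) matrix.

    Column p holds entry (i, j) of every state's matrix, pairs ordered
    lexicographically — the feature matrix every attribution statistic
    is computed from.
    """
    stack = c.matrices()
    if np.isnan(stack).any():
        raise ValueError("collection has missing entries; harmonize first")
    n = stack.shape[1]
    iu = np.triu_indices(n, k=1)
    return stack[:, iu[0], iu[1]]


def pair_axis_correlation(features: np.ndarray, emb: Embedding) -> np.ndarray:
    """Pearson correlation of each pair's values with each axis: (P, D).

    Zero-variance pairs (constant across states) get correlation 0 by
    convention so downstream sums stay defined.
    """
    features = np.asarray(features, dtype=float)
    m, p = features.shape
    if m < 3:
        raise ValueError("pair-axis correlation needs at least 3 states")
    if emb.coords.shape[0] != m:
        raise ValueError("feature rows do not match embedding states")
    x = features - features.mean(axis=0)
    y = emb.coords - emb.coords.mean(axis=0)
    sx = np.sqrt((x**2).sum(axis=0))
    sy = np.sqrt((y**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (x.T @ y) / np.outer(sx, sy)
    corr[~np.isfinite(corr)] = 0.0
    return np.clip(corr, -1.0, 1.0)


def pair_variance_ranking(
    features: np.ndarray, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Cross-state sample variance (ddof=1) of each pair, sorted descending.

    Ties are broken lexicographically by pair so rankings are stable.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("variance needs at least 2 states")
    var = features.var(axis=0, ddof=1)
    if pairs is None:
        pairs = [(str(i), str(j)) for i, j in pair_index_from_p(features.shape[1])]
    df = pd.DataFrame(
        {
            "roi_i": [p[0] for p in pairs],
            "roi_j": [p[1] for p in pairs],
            "variance": var,
        }
    )
    df = df.sort_values(
        ["variance", "roi_i", "roi_j"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return df


def pair_index_from_p(p: int) -> list[tuple[int, int]]:
    """Invert P = N(N-1)/2 and return the lexicographic pair list."""
    n = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if n * (n - 1) // 2 != p:
        raise ValueError(f"{p} is not a triangular number")
    return pair_index(n)


def roi_impact(pair_corr: np.ndarray, n_rois: int | None = None) -> np.ndarray:
    """Per-ROI axis impact: half-sum of correlations of incident pairs.

    impact[i, d] = 1/2 * sum over pairs p containing ROI i of corr[p, d].
    Summing over ROIs recovers the total pair correlation per axis
    exactly (each pair contributes 1/2 to each endpoint).
    """
    pair_corr = np.asarray(pair_corr, dtype=float)
    pairs = pair_index_from_p(pair_corr.shape[0])
    if n_rois is None:
        n_rois = max(j for _, j in pairs) + 1
    impact = np.zeros((n_rois, pair_corr.shape[1]))
    for p, (i, j) in enumerate(pairs):
        impact[i] += 0.5 * pair_corr[p]
        impact[j] += 0.5 * pair_corr[p]
    return impact


def top_rois(
    impact: np.ndarray, labels: list[str], k: int = 5, normalize: bool = False
) -> dict[int, pd.DataFrame]:
    """Per-axis top-k ROIs by |impact|, signed values retained.

    ``normalize`` divides each ROI's half-sum by its number of incident
    pairs (N - 1), yielding a mean-contribution scale comparable across
    cohort sizes.
    """
    impact = np.asarray(impact, dtype=float)
    n, d = impact.shape
    if k > n:
        raise ValueError(f"k={k} exceeds {n} ROIs")
    if normalize:
        impact = impact / max(n - 1, 1)
    out: dict[int, pd.DataFrame] = {}
    for axis in range(d):
        df = pd.DataFrame({"roi": labels, "impact": impact[:, axis]})
        df["abs_impact"] = df["impact"].abs()
        df = df.sort_values(
            ["abs_impact", "roi"], ascending=[False, True], kind="stable"
        ).head(k)
        out[axis] = df.drop(columns="abs_impact").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class AttributionTable:
    """Full axis-attribution bundle for one fitted embedding."""

    pairs: list[tuple[str, str]]
    pair_axis_corr: np.ndarray  # (P, D)
    pair_variance: pd.DataFrame  # ranked
    roi_impacts: np.ndarray  # (N, D)
    roi_labels: list[str]

    def top_pairs_by_variance(self, k: int = 5) -> pd.DataFrame:
        return self.pair_variance.head(k).reset_index(drop=True)

    def top_rois(self, k: int = 5, normalize: bool = False) -> dict[int, pd.DataFrame]:
        return top_rois(self.roi_impacts, self.roi_labels, k=k, normalize=normalize)

    def pair_corr_frame(self) -> pd.DataFrame:
        d = self.pair_axis_corr.shape[1]
        df = pd.DataFrame(
            {
                "roi_i": [p[0] for p in self.pairs],
                "roi_j": [p[1] for p in self.pairs],
            }
        )
        for axis in range(d):
            df[f"dim_{axis + 1}"] = self.pair_axis_corr[:, axis]
        return df

    def roi_impact_frame(self) -> pd.DataFrame:
        d = self.roi_impacts.shape[1]
        df = pd.DataFrame({"roi": self.roi_labels})
        for axis in range(d):
            df[f"dim_{axis + 1}"] = self.roi_impacts[:, axis]
        return df


def attribute(c: BrainStateCollection, emb: Embedding) -> AttributionTable:
    """Run the full attribution stack for a harmonized cohort + embedding."""
    feats = pair_features(c)
    labels = list(c.common_rois)
    pairs = [(labels[i], labels[j]) for i, j in pair_index(len(labels))]
    corr = pair_axis_correlation(feats, emb)
    var_rank = pair_variance_ranking(feats, pairs)
    impacts = roi_impact(corr, n_rois=len(labels))
    return AttributionTable(
        pairs=pairs,
        pair_axis_corr=corr,
        pair_variance=var_rank,
        roi_impacts=impacts,
        roi_labels=labels,
    )
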