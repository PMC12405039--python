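"""End-to-end pipeline: cohort manifest in, brain-space artefacts out.

Stage order follows the two-stage construction of the framework: first
each input becomes a single validated brain state; then the cohort of
states becomes the space (distances, embedding), which is attributed,
traversed (K-operators for longitudinal pairs) and partitioned
(per-diagnosis convex subspaces).  Every artefact is written in the
formats of :mod:`brainspaces.io` and is re-readable by this package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as bsio
from .attribution import attribute
from .brain_space import distance_matrix, embed_mds
from .k_operator import compute_k, pair_contributions, reduced_path
from .state_builder import BrainState, harmonize_rois
from .subspaces import build_subspace, classify_trajectory, hulls_disjoint

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "longitudinal_pairs"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending state."""

    def __init__(self, stage: str, message: str, state_id: str | None = None):
        self.stage = stage
        self.state_id = state_id
        where = f" (state {state_id})" if state_id else ""
        super().__init__(f"[{stage}]{where} {message}")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the framework's choices
    (3 embedding dimensions, Frobenius metric, top-5 attribution tables)."""

    manifest_path: str | Path
    output_dir: str | Path
    dims: int = 3
    mds_method: str = "classical"
    seed: int | None = 0
    connectivity_transform: str = "raw_pearson"
    k_mode: str = "additive"
    top_k: int = 5
    geom_tol: float = 1e-9
    healthy_label: str | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)  # explicit (src, tgt)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


_TIMEPOINT_FIRST = ("baseline", "bl", "t0", "screening")


def _timepoint_key(tp: str) -> tuple[int, str]:
    return (0 if tp.lower() in _TIMEPOINT_FIRST else 1, tp)


def longitudinal_pairs(states: list[BrainState]) -> list[tuple[str, str]]:
    """Consecutive (source, target) state pairs per subject, time-ordered.

    Baseline-like labels sort first; remaining timepoints sort
    lexicographically (FU1 < FU2 ...).
    """
    by_subject: dict[str, list[BrainState]] = {}
    for s in states:
        by_subject.setdefault(s.subject_id, []).append(s)
    pairs = []
    for subject in sorted(by_subject):
        seq = sorted(by_subject[subject], key=lambda s: _timepoint_key(s.timepoint))
        for a, b in zip(seq, seq[1:]):
            pairs.append((a.state_id, b.state_id))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artefact set; returns a summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)

    try:
        states = bsio.load_cohort(
            config.manifest_path, transform=config.connectivity_transform
        )
    except FileNotFoundError as exc:
        raise PipelineError("load", str(exc)) from exc
    except (ValueError, KeyError) as exc:
        raise PipelineError("load", str(exc)) from exc
    if not states:
        raise PipelineError("load", "manifest lists no states")

    out.mkdir(parents=True, exist_ok=True)

    try:
        collection = harmonize_rois(states)
    except ValueError as exc:
        raise PipelineError("harmonize", str(exc)) from exc

    try:
        d = distance_matrix(collection)
        emb = embed_mds(
            d, dims=config.dims, method=config.mds_method, seed=config.seed
        )
    except ValueError as exc:
        raise PipelineError("embed", str(exc)) from exc

    try:
        attr = attribute(collection, emb)
    except ValueError as exc:
        raise PipelineError("attribute", str(exc)) from exc

    bsio.write_distance_matrix(d, out / "distance_matrix.csv")
    bsio.write_embedding(emb, out / "embedding.csv")
    attr.pair_corr_frame().to_csv(out / "pair_axis_correlations.csv", index=False)
    attr.pair_variance.to_csv(out / "pair_variances.csv", index=False)
    attr.roi_impact_frame().to_csv(out / "roi_impacts.csv", index=False)
    for axis, df in attr.top_rois(k=min(config.top_k, len(collection.common_rois))).items():
        df.to_csv(out / f"top_rois_dim_{axis + 1}.csv", index=False)
        logger.info("top ROIs, dim %d:\n%s", axis + 1, df.to_string(index=False))

    pairs = config.pairs or longitudinal_pairs(collection.states)
    k_summaries = []
    for src_id, tgt_id in pairs:
        try:
            src = collection.get(src_id)
            tgt = collection.get(tgt_id)
            k = compute_k(src, tgt, mode=config.k_mode)
            rp = reduced_path(emb, src_id, tgt_id)
        except (KeyError, ValueError) as exc:
            raise PipelineError("k_operator", str(exc), state_id=src_id) from exc
        stem = f"K_{src_id}_to_{tgt_id}".replace("/", "_").replace("@", "_")
        bsio.write_k_operator(k, out / f"{stem}.csv")
        bsio.write_reduced_path(rp, out / f"{stem}_reduced_path.json")
        if config.k_mode == "additive":
            for axis in range(config.dims):
                contrib = pair_contributions(
                    k, attr.pair_axis_corr, axis=axis, top_k=config.top_k
                )
                contrib.to_csv(out / f"{stem}_contrib_dim_{axis + 1}.csv", index=False)
        k_summaries.append(
            {"source": src_id, "target": tgt_id, "reduced_path": rp.as_dict()}
        )

    labels = sorted({s.diagnosis for s in collection.states})
    subspaces = {}
    for label in labels:
        try:
            sub = build_subspace(emb, collection.states, label)
        except ValueError as exc:
            raise PipelineError("subspaces", str(exc)) from exc
        subspaces[label] = sub
        bsio.write_subspace(sub, out / f"subspace_{label}.json")
    separations = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            disjoint, witness = hulls_disjoint(
                subspaces[la], subspaces[lb], tol=config.geom_tol
            )
            separations.append(
                {
                    "label_a": la,
                    "label_b": lb,
                    "disjoint": bool(disjoint),
                    "min_distance": witness["distance"],
                }
            )

    verdicts = []
    if config.healthy_label is not None:
        if config.healthy_label not in subspaces:
            raise PipelineError(
                "subspaces", f"healthy label {config.healthy_label!r} not in cohort"
            )
        healthy = subspaces[config.healthy_label]
        by_subject: dict[str, list[BrainState]] = {}
        for s in collection.states:
            by_subject.setdefault(s.subject_id, []).append(s)
        for subject in sorted(by_subject):
            seq = sorted(
                by_subject[subject], key=lambda s: _timepoint_key(s.timepoint)
            )
            verdicts.append(
                classify_trajectory(emb, healthy, seq, tol=config.geom_tol)
            )
        bsio.write_verdicts(verdicts, out / "trajectory_verdicts.csv")

    summary = {
        "n_states": len(collection),
        "n_common_rois": len(collection.common_rois),
        "removed_per_state": {
            k: len(v) for k, v in collection.removed_per_state.items()
        },
        "mds": {
            "method": emb.method,
            "dims": emb.dims,
            "seed": emb.seed,
            "stress": emb.stress,
            "metric": "frobenius",
            "warnings": list(emb.warnings),
        },
        "longitudinal_pairs": k_summaries,
        "subspace_separations": separations,
        "verdicts": [
            {"subject_id": v.subject_id, "verdict": v.verdict} for v in verdicts
        ],
    }
    (out / "run_log.json").write_text(json.dumps(summary, indent=2))
    logger.info(
        "pipeline complete: %d states, %d common ROIs, stress %.4g",
        len(collection),
        len(collection.common_rois),
        emb.stress,
    )
    return summary
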