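"""End-to-end pipeline: simulate → segment → metrics → estimate → agree.

A :class:`PipelineConfig` (YAML/JSON-loadable, schema-validated, unknown
keys rejected) drives all stages; a run manifest records inputs, seed,
per-stage outputs and SHA-256 checksums, so identical config + seed yields
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .agreement import predict_cohort, summarize_table2
from .io import write_cohort, write_ct_nifti, write_labels
from .metrics import aggregate_slices, compute_metrics
from .phantom import CohortSpec, PhantomSpec, generate_cohort, generate_phantom
from .segmentation import ThresholdSet, derive_compartments, segment

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class PipelineConfig(BaseModel):
    """Validated configuration for :func:`run_pipeline`."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "bodycomp_run"
    seed: int = 0
    height: float = Field(default=1.70, description="subject height in m")
    phantom: dict[str, Any] = Field(default_factory=dict)
    cohort: dict[str, Any] = Field(default_factory=dict)
    thresholds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    slice_mode: str = "mean"
    single_slice_index: int = 0

    @field_validator("height")
    @classmethod
    def _height_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("height must be positive")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
    }

    try:
        # --- simulate: phantom stack ---
        pspec = PhantomSpec(**{"seed": config.seed, **config.phantom})
        slices, gt_masks = generate_phantom(pspec)
        ct_path = write_ct_nifti(slices, out / "phantom_ct.nii.gz")
        gt_path = write_labels(gt_masks, out / "phantom_gt.nii.gz")
        manifest["stages"]["simulate_phantom"] = {
            "outputs": {str(ct_path): _sha256(ct_path), str(gt_path): _sha256(gt_path)}
        }

        # --- segment ---
        thresholds = ThresholdSet(**config.thresholds) if config.thresholds else ThresholdSet()
        seg_masks = [
            segment(s, derive_compartments(s, thresholds), thresholds) for s in slices
        ]
        seg_path = write_labels(seg_masks, out / "phantom_labels.nii.gz")
        manifest["stages"]["segment"] = {"outputs": {str(seg_path): _sha256(seg_path)}}

        # --- metrics ---
        per_slice = [
            compute_metrics(s, m, config.height) for s, m in zip(slices, seg_masks)
        ]
        agg = aggregate_slices(
            per_slice,
            mode=config.slice_mode,
            index=config.single_slice_index if config.slice_mode == "single" else None,
        )
        mdf = pd.DataFrame([m.as_row() for m in per_slice] + [agg.as_row()])
        metrics_path = out / "metrics.csv"
        mdf.to_csv(metrics_path, index=False)
        manifest["stages"]["metrics"] = {"outputs": {str(metrics_path): _sha256(metrics_path)}}

        # --- simulate: cohort; estimate; agree ---
        cspec = CohortSpec(**{"seed": config.seed, **config.cohort})
        subjects, ct_table = generate_cohort(cspec)
        subj_path = write_cohort(subjects, out / "cohort.csv")
        ctt_path = write_cohort(ct_table, out / "cohort_ct.csv")
        estimates = predict_cohort(subjects, ct_table)
        est_path = out / "estimates.csv"
        estimates.to_csv(est_path, index=False)
        table2 = summarize_table2(subjects, {"1 slice": estimates})
        t2_path = out / "table2.csv"
        table2.to_csv(t2_path, index=False)
        manifest["stages"]["estimate_agree"] = {
            "outputs": {
                str(p): _sha256(p) for p in (subj_path, ctt_path, est_path, t2_path)
            }
        }
    except Exception as exc:
        manifest["error"] = {"stage": _current_stage(manifest), "cause": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _current_stage(manifest: dict) -> str:
    done = list(manifest["stages"])
    order = ["simulate_phantom", "segment", "metrics", "estimate_agree"]
    for stage in order:
        if stage not in done:
            return stage
    return "finalize"
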