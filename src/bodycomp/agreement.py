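"""Method-agreement statistics against a DXA reference.

Implements the validation suite used to compare CT-based mass estimates
with DXA: Pearson correlation with a Fisher-z confidence interval,
Bland-Altman bias and 95% limits of agreement, a simplified error grid
binning per-subject relative errors, a QQ normality check, and a summary
grid with one row per model × mass type × slice mode.

Sign convention throughout: differences are estimate − reference
(model − DXA), so a negative bias means the model underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _models

__all__ = [
    "PairedSeries",
    "AgreementSummary",
    "pearson_with_ci",
    "bland_altman",
    "BlandAltman",
    "error_grid",
    "DEFAULT_ERROR_BANDS",
    "qq_normality",
    "QQResult",
    "predict_cohort",
    "summarize_table2",
]


@dataclass
class PairedSeries:
    """Paired estimates and reference values (kg) for one comparison."""

    estimate: np.ndarray
    reference: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.estimate.shape != self.reference.shape or self.estimate.ndim != 1:
            raise ValueError("estimate and reference must be 1-D of equal length")
        if self.estimate.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(self.estimate)) and np.all(np.isfinite(self.reference))):
            raise ValueError("non-finite values in paired series")

    def __len__(self) -> int:
        return int(self.estimate.size)


class AgreementSummary(NamedTuple):
    """One cell group of the agreement table."""

    pearson_r: float | None
    r_ci_low: float | None
    r_ci_high: float | None
    bias: float
    loa_low: float
    loa_high: float
    band_fractions: dict[str, float]
    n: int


def pearson_with_ci(pairs: PairedSeries, level: float = 0.95):
    """Sample Pearson r with a Fisher z-transform confidence interval.

    Requires n ≥ 4 (the Fisher interval needs n − 3 > 0) and non-zero
    variance in both series.
    """
    x, y = pairs.estimate, pairs.reference
    if len(pairs) < 4:
        raise ValueError("need at least 4 pairs for a confidence interval")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=level)
    return float(res.statistic), (float(ci.low), float(ci.high))


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # (estimate + reference) / 2, the plot abscissa
    diffs: np.ndarray  # estimate - reference


def bland_altman(pairs: PairedSeries) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement (bias ± 1.96 SD).

    The SD of the differences uses the n−1 denominator.
    """
    d = pairs.estimate - pairs.reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(pairs.estimate + pairs.reference) / 2.0,
        diffs=d,
    )


#: Relative-error band edges: <10%, 10-25%, >=25% (contiguous).
DEFAULT_ERROR_BANDS = (0.10, 0.25)


def error_grid(
    pairs: PairedSeries,
    bands: tuple[float, float] = DEFAULT_ERROR_BANDS,
) -> dict[str, float]:
    """Simplified error grid: fractions of subjects per relative-error band.

    Relative error is |estimate − reference| / reference; the reference
    must be strictly positive.  Returns fractions summing to 1 with keys
    like ``"<10%"``, ``"10-25%"``, ``">=25%"``.
    """
    lo, hi = bands
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < low < high")
    if np.any(pairs.reference <= 0):
        raise ValueError("reference values must be strictly positive")
    rel = np.abs(pairs.estimate - pairs.reference) / pairs.reference
    n = rel.size
    keys = (f"<{lo:.0%}", f"{lo:.0%}-{hi:.0%}".replace("%-", "-"), f">={hi:.0%}")
    return {
        keys[0]: float((rel < lo).sum()) / n,
        keys[1]: float(((rel >= lo) & (rel < hi)).sum()) / n,
        keys[2]: float((rel >= hi).sum()) / n,
    }


class QQResult(NamedTuple):
    theoretical: np.ndarray
    sample: np.ndarray
    slope: float
    intercept: float
    degenerate: bool


def qq_normality(values: Sequence[float]) -> QQResult:
    """Normal QQ plot data with the fitted QQ line.

    Ordered sample quantiles are paired with standard-normal quantiles at
    plotting positions (i − 0.5)/n; the line is the OLS fit of sample on
    theoretical quantiles.  A constant input is flagged degenerate.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 3:
        raise ValueError("need at least 3 values")
    n = v.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    if np.ptp(v) == 0:
        return QQResult(theo, v, 0.0, float(v[0]), True)
    slope, intercept = np.polyfit(theo, v, 1)
    return QQResult(theo, v, float(slope), float(intercept), False)


# ---------------------------------------------------------------------------
# Model application and the summary grid


def predict_cohort(subjects: pd.DataFrame, ct: pd.DataFrame) -> pd.DataFrame:
    """Apply all three mass models to a cohort.

    ``subjects`` needs id and weight; ``ct`` needs id, fat_area_cm2,
    muscle_area_cm2, fat_pct, roi_mean_hu, fat_mean_hu.  Returns one row
    per subject with fm/ffm estimates per model.
    """
    df = subjects.merge(ct, on="id", validate="one_to_one")
    fm3 = np.array(
        [
            _models.model3_fm(w, r, f, fh).fm_kg
            for w, r, f, fh in zip(
                df["weight"], df["roi_mean_hu"], df["fat_pct"], df["fat_mean_hu"]
            )
        ]
    )
    out = pd.DataFrame({"id": df["id"]})
    out["fm_model1"] = _models.model1_fm(df["fat_area_cm2"].to_numpy())
    out["ffm_model1"] = _models.model1_ffm(df["muscle_area_cm2"].to_numpy())
    out["fm_model2"] = _models.model2_fm(df["fat_area_cm2"].to_numpy())
    out["ffm_model2"] = _models.model2_ffm(df["muscle_area_cm2"].to_numpy())
    out["fm_focusedon"] = fm3
    out["ffm_focusedon"] = _models.model3_ffm(df["weight"].to_numpy(), fm3)
    return out


_MODEL_COLS = {
    "model1": ("fm_model1", "ffm_model1"),
    "model2": ("fm_model2", "ffm_model2"),
    "focusedon": ("fm_focusedon", "ffm_focusedon"),
}


def summarize_table2(
    subjects: pd.DataFrame,
    estimates_by_mode: dict[str, pd.DataFrame],
    models: Sequence[str] = ("model1", "model2", "focusedon"),
    include_derived_ffm_pearson: bool = False,
) -> pd.DataFrame:
    """Agreement grid: model × {FM, FFM} × slice mode vs the DXA reference.

    ``estimates_by_mode`` maps a slice-mode label (e.g. "1 slice",
    "16 slices") to a :func:`predict_cohort` output.  Pearson r is omitted
    for the density-weighted model's FFM by default, because that FFM is
    derived as weight − FM rather than estimated directly.
    """
    for col in ("id", "dxa_fm", "dxa_ffm"):
        if col not in subjects.columns:
            raise ValueError(f"subjects table is missing DXA column {col!r}")
    rows = []
    for mode, est in estimates_by_mode.items():
        df = subjects.merge(est, on="id", validate="one_to_one")
        for model in models:
            fm_col, ffm_col = _MODEL_COLS[model]
            for mass, est_col, ref_col in (
                ("FM", fm_col, "dxa_fm"),
                ("FFM", ffm_col, "dxa_ffm"),
            ):
                pairs = PairedSeries(df[est_col].to_numpy(), df[ref_col].to_numpy())
                ba = bland_altman(pairs)
                derived_ffm = model == "focusedon" and mass == "FFM"
                if derived_ffm and not include_derived_ffm_pearson:
                    r = ci = None
                else:
                    r, ci = pearson_with_ci(pairs)
                rows.append(
                    {
                        "slice_mode": mode,
                        "model": model,
                        "mass": mass,
                        "pearson": r,
                        "r_ci_low": None if ci is None else ci[0],
                        "r_ci_high": None if ci is None else ci[1],
                        "loa_low": ba.loa_low,
                        "bias": ba.bias,
                        "loa_high": ba.loa_high,
                        "n": len(pairs),
                    }
                )
    return pd.DataFrame(rows)
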