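"""Intraclass-correlation repeatability statistics.

The ICC estimates the proportion of total variation attributable to
between-subject variation.  Two estimators are provided:

* one-way random effects, ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW),
  for repeat acquisitions of the same eye where the "rater" (scan
  occasion) carries no identity across subjects;
* two-way mixed effects for fixed conditions such as contrast levels,
  reported as the single-rater consistency form
  ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE), which discounts a
  systematic shift common to all subjects (a pure column effect).  The
  absolute-agreement form ICC(2,1) is available as an option.

Negative ICC estimates are retained as computed — they are an artifact
of the moment estimators and should simply be read as low repeatability.
An ICC above 0.80 is classified "high", below 0.50 "low", anything else
"moderate"; the boundaries themselves fall in the moderate band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeasurementGrid",
    "AnovaDecomposition",
    "ICCResult",
    "icc_oneway",
    "icc_twoway_mixed",
    "contrast_repeatability",
    "classify_icc",
    "delta_icc",
    "delta_icc_bin",
    "DELTA_ICC_BINS",
]

HIGH_CUTOFF = 0.80
LOW_CUTOFF = 0.50


@dataclass
class MeasurementGrid:
    """n_subjects x k matrix of one metric (k = repeats or conditions)."""

    values: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 measurements")
        if not np.isfinite(v).all():
            raise ValueError("missing cells: apply listwise deletion first")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares and degrees of freedom behind an ICC estimate."""

    ms_between_subjects: float
    df_between_subjects: int
    ms_within_subjects: float | None = None
    df_within_subjects: int | None = None
    ms_columns: float | None = None
    df_columns: int | None = None
    ms_error: float | None = None
    df_error: int | None = None


@dataclass(frozen=True)
class ICCResult:
    """ICC estimate, the model used, its ANOVA decomposition, and a label."""

    icc: float
    model: str
    anova: AnovaDecomposition
    classification: str | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.icc)


def classify_icc(icc: float) -> str:
    """'high' above 0.80, 'low' below 0.50 (negatives included), else 'moderate'."""
    if not np.isfinite(icc):
        raise ValueError("ICC is undefined")
    if icc > HIGH_CUTOFF:
        return "high"
    if icc < LOW_CUTOFF:
        return "low"
    return "moderate"


def _result(icc: float, model: str, anova: AnovaDecomposition) -> ICCResult:
    label = classify_icc(icc) if np.isfinite(icc) else None
    return ICCResult(icc=icc, model=model, anova=anova, classification=label)


def icc_oneway(grid: MeasurementGrid) -> ICCResult:
    """One-way random effects ICC(1) from the one-way ANOVA decomposition."""
    x = grid.values
    n, k = grid.n, grid.k
    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssw = float(((x - row_means[:, None]) ** 2).sum())
    dfb, dfw = n - 1, n * (k - 1)
    msb, msw = ssb / dfb, ssw / dfw
    anova = AnovaDecomposition(
        ms_between_subjects=msb, df_between_subjects=dfb,
        ms_within_subjects=msw, df_within_subjects=dfw,
    )
    denom = msb + (k - 1) * msw
    if denom == 0.0:
        warnings.warn("zero total variance: one-way ICC undefined")
        return _result(np.nan, "oneway_random", anova)
    return _result((msb - msw) / denom, "oneway_random", anova)


def icc_twoway_mixed(grid: MeasurementGrid, form: str = "consistency") -> ICCResult:
    """Two-way mixed effects ICC with fixed column (condition) effects.

    ``form="consistency"`` gives ICC(3,1); ``form="agreement"`` gives
    ICC(2,1), which additionally penalizes the column variance.
    """
    if form not in ("consistency", "agreement"):
        raise ValueError("form must be 'consistency' or 'agreement'")
    x = grid.values
    n, k = grid.n, grid.k
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    dfr, dfc, dfe = n - 1, k - 1, (n - 1) * (k - 1)
    msr, msc, mse = ssr / dfr, ssc / dfc, sse / dfe
    anova = AnovaDecomposition(
        ms_between_subjects=msr, df_between_subjects=dfr,
        ms_columns=msc, df_columns=dfc, ms_error=mse, df_error=dfe,
    )
    model = f"twoway_mixed_{form}"
    if form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        warnings.warn("zero total variance: two-way ICC undefined")
        return _result(np.nan, model, anova)
    return _result((msr - mse) / denom, model, anova)


def contrast_repeatability(
    per_image_grids: list[MeasurementGrid], form: str = "consistency"
) -> tuple[float, list[ICCResult]]:
    """Averaged two-way mixed ICC across contrast conditions.

    One grid per repeat image (subjects x contrast levels); the ICC is
    computed per grid and arithmetically averaged.  Undefined per-grid
    ICCs are excluded from the average with a warning.
    """
    results = [icc_twoway_mixed(g, form=form) for g in per_image_grids]
    defined = [r.icc for r in results if r.defined]
    if len(defined) < len(results):
        warnings.warn(
            f"{len(results) - len(defined)} undefined per-image ICC(s) excluded"
        )
    mean = float(np.mean(defined)) if defined else np.nan
    return mean, results


def delta_icc(icc_processed: float, icc_unprocessed: float) -> float:
    """ICC on processed image minus ICC on unprocessed image."""
    if not (np.isfinite(icc_processed) and np.isfinite(icc_unprocessed)):
        raise ValueError("both ICCs must be defined")
    return float(icc_processed) - float(icc_unprocessed)


DELTA_ICC_BINS = (
    "no_change_or_worse",
    "improved_0.0_0.1",
    "improved_0.1_0.2",
    "improved_0.2_0.3",
    "improved_0.3_0.4",
    "improved_0.4_0.5",
    "improved_gt_0.5",
)


def delta_icc_bin(delta: float) -> str:
    """Reporting bin for an ICC difference: worsening, improvement deciles, >0.5."""
    if delta <= 0:
        return DELTA_ICC_BINS[0]
    if delta > 0.5:
        return DELTA_ICC_BINS[6]
    decile = int(np.ceil(delta * 10)) - 1  # (0, 0.1] -> 0, ..., (0.4, 0.5] -> 4
    return DELTA_ICC_BINS[1 + min(4, max(0, decile))]
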