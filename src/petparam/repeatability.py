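"""Agreement, bias, test-retest repeatability and ICC statistics.

These are the validation-layer statistics applied to regional or voxel
estimates:

* ``agreement``: ordinary least squares of parametric estimates on gold
  standard values; reports r^2 (squared Pearson correlation), slope and
  intercept.
* ``trt``: paired percent difference normalised to the pair mean,
  TRT = (retest - test)/(retest + test) * 200, and its absolute-value form.
* ``bias``: (parametric - conventional)/conventional * 100.
* ``icc_2way``: two-way mixed-effects, absolute-agreement,
  average-measures intraclass correlation, ICC(A,k), with the standard
  F-based 95% confidence interval.
* ``trt_map``: voxel-wise absolute-TRT images averaged across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "TRTResult",
    "ICCResult",
    "agreement",
    "trt",
    "bias",
    "icc_2way",
    "trt_map",
]


# ---------------------------------------------------------------------------
# agreement (r^2 / slope)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    r_squared: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r^2 must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("agreement needs at least 3 points")


def agreement(x, y, *, through_origin: bool = False) -> AgreementResult:
    """OLS regression of parametric values ``y`` on gold-standard ``x``.

    r^2 is the squared Pearson correlation; with ``through_origin`` the
    slope is the zero-intercept least-squares slope (r^2 unchanged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("agreement needs at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("agreement inputs must be finite")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in x")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
    else:
        sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
        slope = sxy / sxx
        intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0:
        r2 = 0.0
    else:
        sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
        r2 = sxy**2 / (sxx * syy)
    return AgreementResult(r_squared=min(r2, 1.0), slope=slope,
                           intercept=intercept, n=int(x.size))


# ---------------------------------------------------------------------------
# TRT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRTResult:
    trt: np.ndarray
    abs_trt: np.ndarray
    mean: float
    sd: float
    abs_mean: float
    abs_sd: float
    n_excluded: int = 0


def trt(test, retest) -> TRTResult:
    """Paired test-retest repeatability, TRT = (R - T)/(R + T) * 200.

    Pairs with non-positive sum are excluded (with a warning and a count);
    for positive inputs |TRT| < 200 by construction.
    """
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape:
        raise ValueError("test and retest must be paired")
    s = t + r
    ok = np.isfinite(s) & (s > 0)
    n_excluded = int(t.size - ok.sum())
    if n_excluded:
        warnings.warn(f"TRT: excluded {n_excluded} pair(s) with non-positive sum",
                      stacklevel=2)
    values = (r[ok] - t[ok]) / s[ok] * 200.0
    abs_values = np.abs(values)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    abs_sd = float(np.std(abs_values, ddof=1)) if values.size > 1 else float("nan")
    return TRTResult(
        trt=values,
        abs_trt=abs_values,
        mean=float(np.mean(values)) if values.size else float("nan"),
        sd=sd,
        abs_mean=float(np.mean(abs_values)) if values.size else float("nan"),
        abs_sd=abs_sd,
        n_excluded=n_excluded,
    )


def bias(parametric, conventional) -> float | np.ndarray:
    """Signed percent difference of a parametric estimate from the
    conventional (gold standard) value."""
    p = np.asarray(parametric, dtype=float)
    c = np.asarray(conventional, dtype=float)
    if np.any(c == 0):
        raise ValueError("conventional value must be non-zero")
    out = (p - c) / c * 100.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    ms_subjects: float
    ms_sessions: float
    ms_error: float

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if not (self.ci_lower <= self.icc + 1e-9 and self.icc <= self.ci_upper + 1e-9):
            raise ValueError("CI must bracket the ICC")


def icc_2way(data, alpha: float = 0.05) -> ICCResult:
    """ICC(A,k): two-way, absolute-agreement, average-measures.

    ``data`` is an (n_subjects, k_sessions) table with no missing cells
    (k = 2 in the test-retest design, but any k >= 2 is accepted).  The
    two-way ANOVA decomposition gives

        ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)

    with MS_R/MS_C/MS_E the subject/session/error mean squares.  The 95%
    confidence interval follows the standard F-based construction for
    absolute-agreement ICCs (single-measures bounds stepped up with the
    Spearman-Brown relation).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("data must be subjects x sessions with >= 2 sessions")
    n, k = X.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not allowed")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    icc_k = (msr - mse) / denom if denom != 0 else float("nan")

    # F-based CI: bounds for single-measures ICC(A,1), then Spearman-Brown
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc_1 / (n * (1.0 - icc_1)) if icc_1 != 1.0 else np.inf
    b = 1.0 + k * icc_1 * (n - 1) / (n * (1.0 - icc_1)) if icc_1 != 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        up1 = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
        lo = lo1 * k / (1.0 + lo1 * (k - 1))
        up = up1 * k / (1.0 + up1 * (k - 1))
    else:
        lo, up = icc_k, icc_k  # degenerate: no residual variance
    lo = min(lo, icc_k)
    up = max(up, icc_k)
    return ICCResult(icc=float(icc_k), ci_lower=float(lo), ci_upper=float(up),
                     ms_subjects=msr, ms_sessions=msc, ms_error=mse)


# ---------------------------------------------------------------------------
# voxel-wise TRT maps
# ---------------------------------------------------------------------------

def trt_map(test_maps, retest_maps) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject mean and SD maps of voxel-wise absolute TRT.

    ``test_maps``/``retest_maps`` are per-subject sequences of aligned 3D
    arrays.  Voxels with non-positive pair sums become NaN.  With a single
    subject the SD map is all-NaN (with a warning).
    """
    tests = [np.asarray(m, dtype=float) for m in test_maps]
    retests = [np.asarray(m, dtype=float) for m in retest_maps]
    if len(tests) != len(retests) or not tests:
        raise ValueError("need equal, non-empty lists of test and retest maps")
    shape = tests[0].shape
    if any(m.shape != shape for m in tests + retests):
        raise ValueError("all maps must share one grid")
    per_subject = []
    for t, r in zip(tests, retests):
        s = t + r
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(s > 0, np.abs(r - t) / s * 200.0, np.nan)
        per_subject.append(a)
    stack = np.stack(per_subject)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        mean_map = np.nanmean(stack, axis=0)
    if len(tests) == 1:
        warnings.warn("single subject: SD map undefined (all-NaN)", stacklevel=2)
        sd_map = np.full(shape, np.nan)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd_map = np.nanstd(stack, axis=0, ddof=1)
    return mean_map, sd_map
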