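"""Agreement and error analysis between predicted and observed motor scores.

Implements the full evaluation protocol: MAPE/MAE/MSE with 95% t-intervals
on the per-case mean, Pearson correlation, ordinary least squares of
predicted on observed with 95% confidence and prediction bands,
Bland-Altman agreement (bias = mean of observed - predicted, limits of
agreement = bias +/- 1.96 s with their own t-based confidence intervals
using the variance approximation 3 s^2 / n), a one-sample t-test of the
bias, Shapiro-Wilk normality of the differences, failure-case flagging
(per-case MAPE more than two SDs above the mean), and paired comparison of
two models by the difference of squared errors with a paired two-tailed
t-test.

Degenerate inputs (zero variance, zero observed scores) are flagged
explicitly rather than silently producing NaN.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PredictionSet",
    "MetricWithCI",
    "RegressionFit",
    "BlandAltmanReport",
    "EvaluationReport",
    "DegenerateInputError",
    "t_mean_ci",
    "error_metrics",
    "pearson",
    "ols_with_bands",
    "bland_altman",
    "bias_test",
    "shapiro_wilk",
    "failure_cases",
    "diff_squared_errors",
    "evaluate_predictions",
    "plot_scatter_with_bands",
    "plot_bland_altman",
]


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass
class PredictionSet:
    """Parallel observed/predicted Year-4 scores with patient identifiers."""

    observed: np.ndarray
    predicted: np.ndarray
    patient_ids: list[str] | None = None

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=np.float64)
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        if self.observed.shape != self.predicted.shape or self.observed.ndim != 1:
            raise ValueError("observed and predicted must be parallel 1D vectors")
        if len(self.observed) < 1:
            raise ValueError("need at least 1 case")
        if not (np.all(np.isfinite(self.observed)) and np.all(np.isfinite(self.predicted))):
            raise ValueError("scores must be finite")
        if self.patient_ids is None:
            self.patient_ids = [f"case{i}" for i in range(len(self.observed))]
        elif len(self.patient_ids) != len(self.observed):
            raise ValueError("patient_ids length mismatch")

    def __len__(self) -> int:
        return len(self.observed)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictionSet":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["observed"].to_numpy(), df["predicted"].to_numpy(),
                   list(df["patient_id"].astype(str)))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"patient_id": self.patient_ids, "observed": self.observed,
             "predicted": self.predicted}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self):
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def t_mean_ci(x: np.ndarray, level: float = 0.95) -> MetricWithCI:
    """Two-sided t confidence interval for the mean of a sample."""
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise DegenerateInputError("need at least 2 values for a t interval")
    m = float(x.mean())
    se = float(x.std(ddof=1) / math.sqrt(n))
    half = float(stats.t.ppf(0.5 + level / 2, n - 1)) * se
    return MetricWithCI(m, m - half, m + half, level)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


@dataclass
class ErrorMetrics:
    mae: MetricWithCI
    mse: MetricWithCI
    mape: MetricWithCI | None  # None when an observed score is not > 0
    mape_undefined_reason: str | None = None


def per_case_mape(p: PredictionSet) -> np.ndarray:
    """Per-case absolute percentage errors 100*|y - yhat| / y."""
    if np.any(p.observed <= 0):
        raise DegenerateInputError("MAPE undefined: observed scores must be > 0")
    return 100.0 * np.abs(p.observed - p.predicted) / p.observed


def error_metrics(p: PredictionSet) -> ErrorMetrics:
    """MAPE, MAE and MSE with 95% t-intervals on the per-case mean.

    If any observed score is not positive, MAPE is reported as None (with a
    reason) while MAE and MSE are still returned.
    """
    err = p.observed - p.predicted

    def _ci(x: np.ndarray) -> MetricWithCI:
        if len(x) < 2:  # a single case carries no interval information
            return MetricWithCI(float(x[0]), float(x[0]), float(x[0]))
        return t_mean_ci(x)

    mae = _ci(np.abs(err))
    mse = _ci(err**2)
    try:
        mape = _ci(per_case_mape(p))
        reason = None
    except DegenerateInputError as exc:
        mape, reason = None, str(exc)
    return ErrorMetrics(mae=mae, mse=mse, mape=mape, mape_undefined_reason=reason)


def pearson(p: PredictionSet) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-based p-value."""
    if len(p) < 3:
        raise ValueError("correlation needs at least 3 cases")
    if p.observed.std() == 0 or p.predicted.std() == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    r = stats.pearsonr(p.observed, p.predicted)
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# regression with bands
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    grid: np.ndarray
    confidence_low: np.ndarray
    confidence_high: np.ndarray
    prediction_low: np.ndarray
    prediction_high: np.ndarray


def ols_with_bands(p: PredictionSet, grid: np.ndarray | None = None) -> RegressionFit:
    """OLS of predicted (ordinate) on observed (abscissa) with pointwise 95%
    confidence (mean response) and prediction bands on the grid."""
    if len(p) < 3:
        raise ValueError("regression needs at least 3 cases")
    if p.observed.std() == 0:
        raise DegenerateInputError("regression undefined for constant observed scores")
    if grid is None:
        grid = np.linspace(p.observed.min(), p.observed.max(), 100)
    grid = np.asarray(grid, dtype=np.float64)
    X = sm.add_constant(p.observed)
    fit = sm.OLS(p.predicted, X).fit()
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        grid=grid,
        confidence_low=pred["mean_ci_lower"].to_numpy(),
        confidence_high=pred["mean_ci_upper"].to_numpy(),
        prediction_low=pred["obs_ci_lower"].to_numpy(),
        prediction_high=pred["obs_ci_upper"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass
class BlandAltmanReport:
    mean_difference: MetricWithCI
    sd_differences: float
    loa_lower: MetricWithCI
    loa_upper: MetricWithCI
    bias_p: float
    shapiro_p: float
    degenerate: bool = False


def bland_altman(p: PredictionSet) -> BlandAltmanReport:
    """Bland-Altman agreement of observed vs predicted scores.

    Differences are observed - predicted; limits of agreement are
    mean +/- 1.96 s, each with a 95% t interval using standard error
    s * sqrt(3/n).  Constant differences (s = 0) collapse the limits to the
    mean and flag the report as degenerate.
    """
    d = p.observed - p.predicted
    n = len(d)
    if n < 3:
        raise ValueError("Bland-Altman analysis needs at least 3 cases")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        m = MetricWithCI(mean, mean, mean)
        return BlandAltmanReport(
            mean_difference=m, sd_differences=0.0, loa_lower=m, loa_upper=m,
            bias_p=float("nan"), shapiro_p=float("nan"), degenerate=True,
        )
    tq = float(stats.t.ppf(0.975, n - 1))
    mean_ci = t_mean_ci(d)
    se_loa = sd * math.sqrt(3.0 / n)
    lo = mean - 1.96 * sd
    hi = mean + 1.96 * sd
    return BlandAltmanReport(
        mean_difference=mean_ci,
        sd_differences=sd,
        loa_lower=MetricWithCI(lo, lo - tq * se_loa, lo + tq * se_loa),
        loa_upper=MetricWithCI(hi, hi - tq * se_loa, hi + tq * se_loa),
        bias_p=bias_test(d),
        shapiro_p=shapiro_wilk(d)[1],
    )


def bias_test(differences: np.ndarray) -> float:
    """Two-sided one-sample t-test p-value for mean(differences) == 0."""
    d = np.asarray(differences, dtype=np.float64)
    if len(d) < 3:
        raise DegenerateInputError("bias test needs at least 3 differences")
    if d.std(ddof=1) == 0:
        raise DegenerateInputError("bias test degenerate: constant differences")
    return float(stats.ttest_1samp(d, 0.0).pvalue)


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality statistic W and p-value."""
    x = np.asarray(x, dtype=np.float64)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if x.std() == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for constant input")
    w, pv = stats.shapiro(x)
    return float(w), float(pv)


# ---------------------------------------------------------------------------
# failure analysis and model comparison
# ---------------------------------------------------------------------------


@dataclass
class FailureAnalysis:
    threshold: float  # flag cases with per-case MAPE above this
    cases: list[tuple[str, float]]


def failure_cases(p: PredictionSet, n_sd: float = 2.0) -> FailureAnalysis:
    """Flag cases whose per-case MAPE exceeds the mean by more than n_sd
    sample standard deviations."""
    if len(p) < 3:
        raise ValueError("failure analysis needs at least 3 cases")
    m = per_case_mape(p)
    sd = float(m.std(ddof=1))
    threshold = float(m.mean()) + n_sd * sd
    flagged = [
        (pid, float(v)) for pid, v in zip(p.patient_ids, m) if sd > 0 and v > threshold
    ]
    return FailureAnalysis(threshold=threshold, cases=flagged)


@dataclass
class DiffSquaredErrors:
    """Paired comparison of models a and b on shared observations.

    delta_i = (a_i - y_i)^2 - (b_i - y_i)^2, so a positive mean means model
    a has larger squared error (is worse) than model b.
    """

    delta: np.ndarray
    mean: MetricWithCI
    p_value: float
    degenerate: bool = False


def diff_squared_errors(
    pred_a: np.ndarray, pred_b: np.ndarray, observed: np.ndarray
) -> DiffSquaredErrors:
    a = np.asarray(pred_a, dtype=np.float64)
    b = np.asarray(pred_b, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if not (a.shape == b.shape == y.shape) or a.ndim != 1 or len(a) < 3:
        raise ValueError("pred_a, pred_b, observed must be parallel vectors of length >= 3")
    sq_a = (a - y) ** 2
    sq_b = (b - y) ** 2
    delta = sq_a - sq_b
    if delta.std(ddof=1) == 0:
        m = float(delta.mean())
        return DiffSquaredErrors(
            delta=delta, mean=MetricWithCI(m, m, m), p_value=float("nan"), degenerate=True
        )
    return DiffSquaredErrors(
        delta=delta,
        mean=t_mean_ci(delta),
        p_value=float(stats.ttest_rel(sq_a, sq_b).pvalue),
    )


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    n: int
    mape: MetricWithCI | None
    mae: MetricWithCI
    mse: MetricWithCI
    pearson_r: float
    pearson_p: float
    regression: RegressionFit
    bland_altman: BlandAltmanReport
    failures: FailureAnalysis
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, float) and math.isnan(o):
                return None
            return o

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(p: PredictionSet) -> EvaluationReport:
    """Compute the complete evaluation protocol for one prediction set."""
    em = error_metrics(p)
    r, pv = pearson(p)
    reg = ols_with_bands(p)
    ba = bland_altman(p)
    notes = {"metric_definitions": "textbook MAPE/MAE/MSE; per-case 95% t-intervals"}
    if em.mape_undefined_reason:
        notes["mape"] = em.mape_undefined_reason
        failures = FailureAnalysis(threshold=float("nan"), cases=[])
    else:
        failures = failure_cases(p)
    return EvaluationReport(
        n=len(p),
        mape=em.mape,
        mae=em.mae,
        mse=em.mse,
        pearson_r=r,
        pearson_p=pv,
        regression=reg,
        bland_altman=ba,
        failures=failures,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_scatter_with_bands(p: PredictionSet, fit: RegressionFit, path: str | Path) -> None:
    """Scatter of predicted vs observed with the OLS line and 95% bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    g = fit.grid
    ax.fill_between(g, fit.prediction_low, fit.prediction_high, color="0.85",
                    label="95% prediction interval")
    ax.fill_between(g, fit.confidence_low, fit.confidence_high, color="0.6",
                    label="95% confidence interval")
    ax.plot(g, fit.intercept + fit.slope * g, "k-", lw=1.5)
    ax.scatter(p.observed, p.predicted, s=18, color="tab:blue", zorder=3)
    ax.set_xlabel("Observed MDS-UPDRS-III (Year 4)")
    ax.set_ylabel("Predicted MDS-UPDRS-III (Year 4)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(p: PredictionSet, report: BlandAltmanReport, path: str | Path) -> None:
    """Differences vs means with the bias line and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = p.observed - p.predicted
    m = (p.observed + p.predicted) / 2.0
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(m, d, s=18, color="tab:blue")
    ax.axhline(report.mean_difference.estimate, color="k", lw=1.5)
    for loa in (report.loa_lower, report.loa_upper):
        ax.axhline(loa.estimate, color="k", ls="--", lw=1)
        ax.axhspan(loa.ci_low, loa.ci_high, color="0.9", zorder=0)
    ax.set_xlabel("Mean of observed and predicted score")
    ax.set_ylabel("Observed - predicted")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
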