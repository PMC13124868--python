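"""Prediction-error metrics and statistical comparisons.

The screen judges every calibration model by the absolute error (AE) of its
validation predictions, summarised as the mean absolute error (MAE) and the
standard deviation of the absolute errors (SD_AE).  Relative error (RE, %)
supports cross-parameter comparison, with a paired one-tailed t-test for
model-vs-model contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "absolute_errors",
    "mae",
    "sd_ae",
    "relative_errors",
    "paired_t_test_one_tailed",
    "re_mean_ci",
    "MetricRecord",
    "write_metrics",
    "read_metrics",
    "TTestResult",
]


def absolute_errors(y_obs, y_pred) -> np.ndarray:
    """AE_i = |y_obs,i - y_pred,i|."""
    return np.abs(np.asarray(y_obs, dtype=float) - np.asarray(y_pred, dtype=float))


def mae(ae) -> float:
    """Mean absolute error: sum(AE_i) / n."""
    return float(np.mean(np.asarray(ae, dtype=float)))


def sd_ae(ae, ddof: int = 1) -> float:
    """Standard deviation of the absolute errors.

    Sample standard deviation (``ddof=1``) by default; set ``ddof=0`` for
    the population variant.
    """
    ae = np.asarray(ae, dtype=float)
    if ae.size <= ddof:
        return 0.0
    return float(np.std(ae, ddof=ddof))


def relative_errors(y_obs, y_pred) -> np.ndarray:
    """RE_i (%) = |y_obs,i - y_pred,i| / y_obs,i * 100.

    Samples with ``y_obs == 0`` are excluded with a warning (RE undefined).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    nz = y_obs != 0
    if not nz.all():
        warnings.warn(
            f"{int((~nz).sum())} sample(s) with y_obs = 0 excluded from RE"
        )
    return np.abs(y_obs[nz] - y_pred[nz]) / np.abs(y_obs[nz]) * 100.0


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    reject: bool


def paired_t_test_one_tailed(ae_a, ae_b, alpha: float = 0.05) -> TTestResult:
    """Paired one-tailed Student's t-test of H1: mean(ae_a - ae_b) > 0.

    Rejecting means the first model's errors are significantly larger.
    """
    ae_a = np.asarray(ae_a, dtype=float)
    ae_b = np.asarray(ae_b, dtype=float)
    if ae_a.shape != ae_b.shape:
        raise ValueError("paired samples must have equal length")
    res = stats.ttest_rel(ae_a, ae_b, alternative="greater")
    df = ae_a.size - 1
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # zero-variance differences
        d = float(np.mean(ae_a - ae_b))
        t, p = 0.0, 0.5
        if d != 0:
            t = np.inf if d > 0 else -np.inf
            p = 0.0 if d > 0 else 1.0
    return TTestResult(t, df, p, p <= alpha)


def re_mean_ci(re, level: float = 0.95):
    """Mean relative error with its t-distribution confidence interval.

    With a single value the interval is undefined and returned as NaN.
    """
    re = np.asarray(re, dtype=float)
    m = float(np.mean(re))
    if re.size < 2:
        return m, float("nan"), float("nan")
    half = stats.t.ppf(0.5 + level / 2.0, re.size - 1) * stats.sem(re)
    return m, m - float(half), m + float(half)


@dataclass
class MetricRecord:
    """Per (parameter, technique, combination, repetition) screen outcome."""

    parameter: str
    technique: str
    combination: str  # combination label
    repetition: int
    mae: float = float("nan")
    sd_ae: float = float("nan")
    n_val: int = 0
    failed: bool = False
    failure_reason: str = ""
    ae: np.ndarray | None = None
    re: np.ndarray | None = None
    model_size: int = 0  # latent variables (PLS) or hidden neurons (ANN)

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "technique": self.technique,
            "combination": self.combination,
            "repetition": self.repetition,
            "MAE": self.mae,
            "SD_AE": self.sd_ae,
            "n_val": self.n_val,
            "failed": self.failed,
            "failure_reason": self.failure_reason,
            "model_size": self.model_size,
        }


def write_metrics(records: list[MetricRecord], path) -> None:
    """Write screen records to CSV (one row per record); round-trips through
    :func:`read_metrics` losslessly at float precision."""
    df = pd.DataFrame([r.as_row() for r in records],
                      columns=["parameter", "technique", "combination",
                               "repetition", "MAE", "SD_AE", "n_val",
                               "failed", "failure_reason", "model_size"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_metrics(path) -> list[MetricRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""])
    out = []
    for _, row in df.iterrows():
        out.append(MetricRecord(
            parameter=str(row["parameter"]),
            technique=str(row["technique"]),
            combination=str(row["combination"]),
            repetition=int(row["repetition"]),
            mae=float(row["MAE"]) if row["MAE"] == row["MAE"] else float("nan"),
            sd_ae=float(row["SD_AE"]) if row["SD_AE"] == row["SD_AE"] else float("nan"),
            n_val=int(row["n_val"]),
            failed=bool(row["failed"]) if not isinstance(row["failed"], str)
            else row["failed"] == "True",
            failure_reason=str(row["failure_reason"]),
            model_size=int(row["model_size"]),
        ))
    return out
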