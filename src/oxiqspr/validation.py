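"""External-validation metric battery for regression QSPR models.

Implements the standard predictivity criteria used to judge a model against
an external test set: Pearson R^2; the through-origin determination
coefficients R^2_0 (observed regressed on predicted) and R'^2_0 (the swapped
fit); the rm^2 pair and their mean/absolute difference; Lin's concordance
correlation coefficient (CCC); the external Q^2_F1 (training-mean reference)
and Q^2_F2 (test-mean reference); and the error metrics RMSE, MAE and SD,
where SD is the standard deviation of the absolute residuals so that
MAE + 3 SD is internally coherent.

Quality classification compares MAE and MAE + 3 SD against fractions of the
training activity range (10% / 20% / 25%) together with rm^2 and the
R-family closeness rules; everything between the "high" and "low" rule sets
is "moderate".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class MetricReport:
    n_used: int
    R2: float
    R2_0: float
    R2p_0: float
    rm2: float
    rm2_prime: float
    rm2_avg: float
    rm2_delta: float
    CCC: float
    Q2_F1: Optional[float]
    Q2_F2: float
    RMSE: float
    MAE: float
    SD: float
    MAE_plus_3SD: float
    quality: Optional[str] = None
    systematic_error: Optional[bool] = None
    rm2_negative_difference: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _through_origin_r2(y: np.ndarray, x: np.ndarray) -> float:
    """R^2 of the through-origin regression of y on x, about mean(y)."""
    k = float(np.dot(y, x) / np.dot(x, x))
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:  # constant response (e.g. constant predictions): undefined, report 0
        return 0.0
    return 1.0 - ss_res / ss_tot


def metric_battery(
    obs: Sequence[float],
    pred: Sequence[float],
    train_mean: Optional[float] = None,
    activity_range: Optional[float] = None,
    high_mae3sd_fraction: float = 0.10,
) -> MetricReport:
    """Compute the full battery for one (observed, predicted) pairing.

    ``train_mean`` enables Q^2_F1; ``activity_range`` (the training
    delta-logk7) enables the high/moderate/low classification.
    """
    y = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("obs and pred must be 1-d vectors of equal length")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.var(y) == 0:
        raise ValueError("zero variance in observed values")

    r = float(np.corrcoef(y, p)[0, 1]) if np.var(p) > 0 else 0.0
    r2 = r * r
    r2_0 = _through_origin_r2(y, p)
    r2p_0 = _through_origin_r2(p, y)

    flag = False

    def _rm2(r2_origin: float) -> float:
        nonlocal flag
        diff = r2 - r2_origin
        if diff < 0:
            flag = True
        return r2 * (1.0 - np.sqrt(abs(diff)))

    rm2 = _rm2(r2_0)
    rm2p = _rm2(r2p_0)

    cov = float(np.mean((y - y.mean()) * (p - p.mean())))
    ccc = 2.0 * cov / (float(np.var(y)) + float(np.var(p)) + (y.mean() - p.mean()) ** 2)

    press = float(np.sum((y - p) ** 2))
    q2_f1 = None
    if train_mean is not None:
        q2_f1 = 1.0 - press / float(np.sum((y - train_mean) ** 2))
    q2_f2 = 1.0 - press / float(np.sum((y - y.mean()) ** 2))

    res = y - p
    rmse = float(np.sqrt(np.mean(res**2)))
    mae = float(np.mean(np.abs(res)))
    sd = float(np.std(np.abs(res), ddof=1))

    report = MetricReport(
        n_used=n,
        R2=r2,
        R2_0=r2_0,
        R2p_0=r2p_0,
        rm2=rm2,
        rm2_prime=rm2p,
        rm2_avg=(rm2 + rm2p) / 2.0,
        rm2_delta=abs(rm2 - rm2p),
        CCC=ccc,
        Q2_F1=q2_f1,
        Q2_F2=q2_f2,
        RMSE=rmse,
        MAE=mae,
        SD=sd,
        MAE_plus_3SD=mae + 3.0 * sd,
        rm2_negative_difference=flag,
    )
    if n >= 5:
        report.systematic_error = systematic_error_check(y, p)
    if activity_range is not None:
        report.quality = classify_quality(
            report, activity_range, high_mae3sd_fraction=high_mae3sd_fraction
        )
    return report


def trim_high_residuals(
    obs: Sequence[float],
    pred: Sequence[float],
    fraction: float = 0.05,
    ids: Optional[Sequence] = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Drop the ceil(fraction * n) records with the largest absolute residuals.

    At least one record is removed whenever fraction > 0.  Ties are broken
    by position/id order.  Returns (obs', pred', removed ids).
    """
    if not 0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    y = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    n = y.size
    labels = list(ids) if ids is not None else list(range(n))
    if fraction == 0:
        return y, p, []
    k = int(np.ceil(fraction * n))
    residuals = np.abs(y - p)
    # stable sort: among equal residuals the earlier id is removed first
    order = np.argsort(-residuals, kind="stable")
    removed = sorted(order[:k].tolist())
    keep = np.setdiff1d(np.arange(n), removed)
    return y[keep], p[keep], [labels[i] for i in removed]


def classify_quality(
    report: MetricReport,
    activity_range: float,
    high_mae3sd_fraction: float = 0.10,
) -> str:
    """Classify descriptive/predictive power as high, moderate or low.

    High requires MAE <= 10% of the activity range, MAE+3SD below
    ``high_mae3sd_fraction`` of the range (10% by default; some conventions
    use 20%), rm2_avg > 0.85 with a small rm2 split, and a mutually
    consistent, high R-family (R^2, R^2_0, R'^2_0, CCC).  Low is triggered
    by MAE > 20% of the range, MAE+3SD > 25%, a weak rm2 pair, or a
    uniformly poor R-family.  Everything else is moderate.
    """
    if activity_range <= 0:
        raise ValueError("activity_range must be positive")
    r_family = (report.R2, report.R2_0, report.R2p_0, report.CCC)
    close = max(r_family) - min(r_family) <= 0.1

    high = (
        report.MAE <= 0.10 * activity_range
        and report.MAE_plus_3SD <= high_mae3sd_fraction * activity_range
        and report.rm2_avg > 0.85
        and report.rm2_delta < 0.15
        and close
        and min(r_family) >= 0.85
    )
    if high:
        return "high"
    low = (
        report.MAE > 0.20 * activity_range
        or report.MAE_plus_3SD > 0.25 * activity_range
        or (report.rm2_avg <= 0.5 and report.rm2_delta <= 0.2)
        or all(v <= 0.6 for v in r_family)
    )
    return "low" if low else "moderate"


def systematic_error_check(obs: Sequence[float], pred: Sequence[float]) -> bool:
    """True when residuals show a systematic bias.

    Flags a shifted mean (|mean residual| > 0.5 MAE) or a one-sided residual
    distribution (> 80% of the residuals sharing one sign).
    """
    y = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if y.size < 5:
        raise ValueError("systematic-error check needs at least 5 points")
    res = y - p
    mae = float(np.mean(np.abs(res)))
    if mae == 0:
        return False
    if abs(float(np.mean(res))) > 0.5 * mae:
        return True
    nonzero = res[res != 0]
    if nonzero.size == 0:
        return False
    pos = float(np.mean(nonzero > 0))
    return max(pos, 1.0 - pos) > 0.8
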