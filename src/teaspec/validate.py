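"""Calibration figures of merit: recovery, RMSE, paired t-test and EJCR.

The elliptical joint confidence region (EJCR) test regresses the actual
responses on the predicted ones and asks whether the joint 1-alpha
confidence ellipse of (intercept, slope),

    {beta : (beta_hat - beta)^T X^T X (beta_hat - beta) <= 2 s^2 F_alpha(2, n-2)},

contains the ideal point (0, 1).  A smaller ellipse at fixed alpha means a
more precise accuracy claim, so ellipse areas are also used to rank models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-squared error sqrt(mean((actual - predicted)^2))."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size == 0:
        raise ValueError("empty input")
    if actual.size != predicted.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def recovery(actual: np.ndarray, predicted: np.ndarray):
    """Per-sample recovery 100 * predicted / actual, with mean and sd.

    Returns ``(per_sample, mean, sd)``; sd uses n-1 degrees of freedom.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size:
        raise ValueError("length mismatch")
    if np.any(actual == 0):
        raise ValueError("recovery undefined for zero actual values")
    per_sample = 100.0 * predicted / actual
    sd = float(per_sample.std(ddof=1)) if per_sample.size > 1 else 0.0
    return per_sample, float(per_sample.mean()), sd


def paired_t_test(actual: np.ndarray, predicted: np.ndarray, alpha: float = 0.05):
    """Two-sided paired t-test of actual vs predicted.

    With d = actual - predicted, t = mean(d) / (sd(d)/sqrt(n)), df = n-1.
    Returns ``(t, t_critical, significant)``; `significant` is True when
    |t| >= t_critical, i.e. the means differ at level alpha.  Zero-variance
    differences give t = 0 (identical vectors) or +/-inf.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    n = actual.size
    if n < 2 or predicted.size != n:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = actual - predicted
    sd = d.std(ddof=1)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    if sd == 0:
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
    return t, t_crit, bool(abs(t) >= t_crit)


@dataclass
class EJCRResult:
    """EJCR of the actual-on-predicted regression line.

    ``xtx`` is the design cross-product defining the ellipse metric,
    ``s2`` the residual variance, and ``area`` the exact ellipse area
    pi * (2 s^2 F) / sqrt(det(X^T X)).
    """

    intercept: float
    slope: float
    xtx: np.ndarray
    s2: float
    f_critical: float
    contains_ideal: bool
    area: float
    n: int
    alpha: float

    def contains(self, intercept: float, slope: float) -> bool:
        """Whether an arbitrary (intercept, slope) lies inside the region."""
        delta = np.array([self.intercept - intercept, self.slope - slope])
        return bool(delta @ self.xtx @ delta <= 2.0 * self.s2 * self.f_critical)

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """(n_points, 2) array of (intercept, slope) on the ellipse boundary."""
        c = 2.0 * self.s2 * self.f_critical
        L = np.linalg.cholesky(np.linalg.inv(self.xtx) * c)
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        return (np.array([self.intercept, self.slope])[:, None] + L @ circle).T


def ejcr(actual: np.ndarray, predicted: np.ndarray, alpha: float = 0.05) -> EJCRResult:
    """Elliptical joint confidence region test for (intercept, slope) = (0, 1)."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    n = actual.size
    if n < 3 or predicted.size != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(predicted) == 0:
        raise ValueError("constant predictor: regression undefined")
    X = np.column_stack([np.ones(n), predicted])
    beta, _, _, _ = np.linalg.lstsq(X, actual, rcond=None)
    resid = actual - X @ beta
    s2 = float(resid @ resid / (n - 2))
    xtx = X.T @ X
    f_crit = float(stats.f.ppf(1.0 - alpha, 2, n - 2))
    c = 2.0 * s2 * f_crit
    delta = beta - np.array([0.0, 1.0])
    det = float(np.linalg.det(xtx))
    area = float(np.pi * c / np.sqrt(det)) if s2 > 0 else 0.0
    return EJCRResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        xtx=xtx,
        s2=s2,
        f_critical=f_crit,
        contains_ideal=bool(delta @ xtx @ delta <= c),
        area=area,
        n=n,
        alpha=alpha,
    )


@dataclass
class CalibrationReport:
    """All figures of merit for one (block, target) calibration."""

    block: str
    target: str
    actual: np.ndarray
    predicted: np.ndarray
    recoveries: np.ndarray
    mean_recovery: float
    sd_recovery: float
    rmsec: float
    rmsep: float
    correlation: float
    slope: float
    intercept: float
    t_statistic: float
    t_critical: float
    significant: bool
    ejcr: EJCRResult


def calibration_report(
    block: str,
    target: str,
    actual: np.ndarray,
    predicted: np.ndarray,
    rmsec: float,
    alpha: float = 0.05,
) -> CalibrationReport:
    """Assemble the prediction-set report for one calibrated model."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    per_sample, mean_rec, sd_rec = recovery(actual, predicted)
    t, t_crit, significant = paired_t_test(actual, predicted, alpha)
    region = ejcr(actual, predicted, alpha)
    corr = float(np.corrcoef(actual, predicted)[0, 1])
    return CalibrationReport(
        block=block,
        target=target,
        actual=actual,
        predicted=predicted,
        recoveries=per_sample,
        mean_recovery=mean_rec,
        sd_recovery=sd_rec,
        rmsec=float(rmsec),
        rmsep=rmse(actual, predicted),
        correlation=corr,
        slope=region.slope,
        intercept=region.intercept,
        t_statistic=t,
        t_critical=t_crit,
        significant=significant,
        ejcr=region,
    )


@dataclass
class ModelRanking:
    """Blocks ordered best-first by RMSEP (EJCR area breaks ties)."""

    order: list[str]
    rmsep: dict[str, float]
    ejcr_area: dict[str, float]
    fused_wins: bool


def compare_models(reports: Mapping[str, CalibrationReport]) -> ModelRanking:
    """Rank calibrated blocks by RMSEP, ties broken by EJCR area.

    ``fused_wins`` flags the block named ``"fused"`` when it has both the
    smallest RMSEP and the smallest ellipse area.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rmseps = {name: r.rmsep for name, r in reports.items()}
    areas = {name: r.ejcr.area for name, r in reports.items()}
    order = sorted(reports, key=lambda name: (rmseps[name], areas[name]))
    fused_wins = (
        "fused" in reports
        and rmseps["fused"] == min(rmseps.values())
        and areas["fused"] == min(areas.values())
    )
    return ModelRanking(order=order, rmsep=rmseps, ejcr_area=areas, fused_wins=fused_wins)
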