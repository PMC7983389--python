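"""Four-parameter log-logistic decay of diagnostic diversity with travel time.

The regional DDI is modelled as a decreasing sigmoid of the travel time
t (minutes) from the region of residence to the nearest tertiary
hospital:

    DDI(t) = DDI_low + (DDI_up - DDI_low) / (1 + exp(tau * (t - T_half)))

with lower/upper asymptotes DDI_low < DDI_up (nats), steepness tau > 0
(per minute) and T_half the travel time of half decrease. The curve's
inflection point sits at t = T_half; the tangent there has slope
-(DDI_up - DDI_low) * tau / 4 and crosses the upper asymptote at

    t* = T_half - 2 / tau,

the travel-time threshold beyond which the loss of diversity
substantiates. Parameters are estimated by (optionally weighted)
nonlinear least squares with an analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

# amplitude below which the sigmoid is unidentifiable
DEGENERATE_AMPLITUDE = 1e-8

_TAU_BOUNDS = (1e-4, 100.0)
_MULTISTART_TAU = (0.02, 0.05, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class LogLogisticParams:
    """Parameters of the 4-parameter log-logistic decay curve."""

    ddi_low: float   # lower asymptote, nats
    ddi_up: float    # upper asymptote, nats
    tau: float       # steepness, per minute
    t_half: float    # time of half decrease, minutes

    def validate(self) -> None:
        """Valid member of the sigmoid family.

        The curve decreases iff tau > 0, the decay regime this model is
        for; tau < 0 (an increasing curve, via the family's
        asymptote-swap identity) is admitted so reflected data remain
        representable, but tau = 0 and collapsed asymptotes are not.
        """
        if not np.isfinite([self.ddi_low, self.ddi_up, self.tau, self.t_half]).all():
            raise InvalidParameterError("non-finite log-logistic parameter")
        if self.tau == 0:
            raise InvalidParameterError("tau must be nonzero")
        if self.ddi_up <= self.ddi_low:
            raise InvalidParameterError("ddi_up must exceed ddi_low")

    def as_array(self) -> np.ndarray:
        return np.array([self.ddi_low, self.ddi_up, self.tau, self.t_half])


@dataclass
class LogLogisticFit:
    """Result of a log-logistic fit, with the derived tangent threshold."""

    params: LogLogisticParams
    standard_errors: np.ndarray
    residual_sum_of_squares: float
    n_points: int
    tangent_threshold: float
    converged: bool
    iterations: int
    degenerate: bool = False
    assumptions: dict = field(default_factory=dict)

    def predict(self, t) -> np.ndarray:
        return loglogistic_value(t, self.params)

    def to_dict(self) -> dict:
        p = self.params
        se = self.standard_errors
        return {
            "ddi_low": float(p.ddi_low),
            "ddi_up": float(p.ddi_up),
            "tau": float(p.tau),
            "t_half": float(p.t_half),
            "se_ddi_low": float(se[0]),
            "se_ddi_up": float(se[1]),
            "se_tau": float(se[2]),
            "se_t_half": float(se[3]),
            "tangent_threshold": float(self.tangent_threshold),
            "residual_sum_of_squares": float(self.residual_sum_of_squares),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "degenerate": bool(self.degenerate),
            "assumptions": self.assumptions,
        }


def loglogistic_value(t, params: LogLogisticParams) -> np.ndarray:
    """Evaluate DDI(t); overflow-free for any |tau*(t - T_half)|.

    expit saturates smoothly to 0/1, so extreme arguments return the
    asymptotes exactly instead of overflowing.
    """
    params.validate()
    t = np.asarray(t, dtype=float)
    s = expit(-params.tau * (t - params.t_half))
    return params.ddi_low + (params.ddi_up - params.ddi_low) * s


def tangent_threshold(params: LogLogisticParams) -> float:
    """Travel time where the inflection tangent meets the upper asymptote.

    Closed form T_half - 2/tau: at the inflection (t = T_half) the curve
    value is the midpoint of the asymptotes and the slope is
    -(DDI_up - DDI_low) tau / 4, so the tangent climbs the remaining
    half-amplitude in 2/tau minutes. Always strictly less than T_half.
    """
    if params.tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {params.tau}")
    return params.t_half - 2.0 / params.tau


def default_init(points: np.ndarray) -> LogLogisticParams:
    """Data-driven starting values.

    Asymptotes from the 5th/95th percentiles of H, T_half from the point
    nearest the mid-amplitude, tau from 4 / IQR(t) clipped to a sane
    range. Constant H degenerates to equal asymptotes; the fit flags it.
    """
    t, h = points[:, 0], points[:, 1]
    if len(t) < 5:
        raise InsufficientDataError("need at least 5 points")
    up = float(np.percentile(h, 95))
    low = float(np.percentile(h, 5))
    mid = 0.5 * (up + low)
    t_half = float(t[np.argmin(np.abs(h - mid))])
    iqr_t = float(np.percentile(t, 75) - np.percentile(t, 25))
    tau = 4.0 / iqr_t if iqr_t > 0 else 0.1
    tau = float(np.clip(tau, 1e-3, 10.0))
    return LogLogisticParams(low, up if up > low else low + 1e-9, tau, t_half)


def _residuals_and_jac(theta, t, h, sqrt_w):
    low, up, tau, t_half = theta
    x = tau * (t - t_half)
    s = expit(-x)            # 1 / (1 + e^x)
    f = low + (up - low) * s
    r = (f - h) * sqrt_w
    sp = s * (1.0 - s)       # stable product
    jac = np.empty((t.size, 4))
    jac[:, 0] = (1.0 - s) * sqrt_w
    jac[:, 1] = s * sqrt_w
    jac[:, 2] = -(up - low) * (t - t_half) * sp * sqrt_w
    jac[:, 3] = (up - low) * tau * sp * sqrt_w
    return r, jac


def fit_loglogistic(
    points,
    init: Optional[LogLogisticParams] = None,
    weights: Optional[Sequence[float]] = None,
) -> LogLogisticFit:
    """Weighted nonlinear least-squares fit of the 4-parameter sigmoid.

    Uses a trust-region Levenberg-Marquardt-type iteration with the
    analytic Jacobian, box constraints DDI_low >= 0 and
    tau in [1e-4, 100], and a multi-start fallback over a steepness grid
    when the first start does not converge. Standard errors come from
    the Gauss-Newton covariance (J'J)^-1 scaled by the residual
    variance.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Columns (travel time in minutes, DDI in nats). n >= 5 required.
    init : optional explicit starting parameters.
    weights : optional per-point weights (e.g. region case counts).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): columns (t, H)")
    if pts.shape[0] < 5:
        raise InsufficientDataError(f"need >= 5 points, got {pts.shape[0]}")
    t, h = pts[:, 0], pts[:, 1]
    if np.ptp(t) == 0:
        raise InsufficientDataError("travel times are all identical")
    if weights is None:
        sqrt_w = np.ones_like(t)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != t.shape or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per point")
        sqrt_w = np.sqrt(w)

    start = init if init is not None else default_init(pts)
    lo_b = np.array([0.0, -np.inf, _TAU_BOUNDS[0], -np.inf])
    hi_b = np.array([np.inf, np.inf, _TAU_BOUNDS[1], np.inf])

    def run(p0: LogLogisticParams):
        x0 = np.clip(p0.as_array(), lo_b, hi_b)
        x0[1] = max(x0[1], x0[0])  # keep up >= low at start
        return least_squares(
            lambda th: _residuals_and_jac(th, t, h, sqrt_w)[0],
            x0,
            jac=lambda th: _residuals_and_jac(th, t, h, sqrt_w)[1],
            bounds=(lo_b, hi_b),
            method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=500 * 4,
        )

    attempts = [start]
    mid_t = float(np.median(t))
    for tau0 in _MULTISTART_TAU:
        attempts.append(LogLogisticParams(start.ddi_low, start.ddi_up, tau0, mid_t))

    best = None
    for k, p0 in enumerate(attempts):
        try:
            res = run(p0)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if k == 0 and res.success and res.cost <= 1e-24:
            break  # exact first-start fit; no need for the grid
    if best is None:
        raise FitFailureError("all starts failed", best=None)

    low, up, tau, t_half = best.x
    swapped = up < low
    if swapped:
        # the optimizer fit an increasing curve; canonical form swaps the
        # asymptotes and negates tau (an exact identity of the family)
        low, up, tau = up, low, -tau
    rss = float(2.0 * best.cost)
    n = t.size
    dof = max(n - 4, 1)
    # Gauss-Newton covariance; singular for degenerate fits
    _, J = _residuals_and_jac(best.x, t, h, sqrt_w)
    amp_se = np.nan
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        amp_var = cov[1, 1] + cov[0, 0] - 2.0 * cov[0, 1]
        amp_se = float(np.sqrt(amp_var)) if amp_var > 0 else np.nan
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    if swapped:
        se[[0, 1]] = se[[1, 0]]

    # degenerate when the amplitude is numerically nil or statistically
    # indistinguishable from noise (flat data fit by a spurious sigmoid)
    amp = up - low
    degenerate = amp < DEGENERATE_AMPLITUDE or (
        np.isfinite(amp_se) and amp < 2.0 * amp_se
    )
    params = LogLogisticParams(low, up if up > low else low + DEGENERATE_AMPLITUDE, tau, t_half)
    thr = (
        tangent_threshold(params)
        if (not degenerate and params.tau > 0)
        else float("nan")
    )
    fit = LogLogisticFit(
        params=params,
        standard_errors=se,
        residual_sum_of_squares=rss,
        n_points=int(n),
        tangent_threshold=thr,
        converged=bool(best.success),
        iterations=int(best.nfev),
        degenerate=degenerate,
        assumptions={
            "weighting": "per-region case counts" if weights is not None else "unweighted regions",
            "residuals": "homoscedastic Gaussian on untransformed H",
            "years": "pooled across the input window",
        },
    )
    if not best.success:
        raise FitFailureError("no start converged", best=fit)
    return fit
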