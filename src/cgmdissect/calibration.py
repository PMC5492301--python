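"""Joint estimation of BG-IG kinetics and sensor calibration polynomials.

For one session with n parallel CGM traces and a smooth BG profile, the
model of each trace is

    CGM_i(t) = a_i(t) * (h_tau * BG)(t) + b_i(t) + v_i(t)

with a single time constant tau shared by all sensors and sensor-specific
gain and offset polynomials a_i, b_i of degrees m and l.  All parameters
are estimated at once by trust-region nonlinear least squares on the pooled
deviations.  Estimation precision is summarized by the coefficient of
variation CV_j = 100 * SE_j / |estimate_j| derived from the local
linearization at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import AlignedPairs, align_to_cgm
from .series import GlucoseSeries
from .synthetic import SessionData, bg_to_ig


class FitError(ValueError):
    """Invalid fitting specification or session/fit mismatch."""


@dataclass(frozen=True)
class FitSpec:
    """Model orders, bounds and optimizer settings for one calibration fit."""

    m: int = 1  # gain polynomial degree
    l: int = 1  # offset polynomial degree
    tau_bounds: tuple[float, float] = (0.1, 60.0)
    tau_init: float = 10.0
    tolerance: float = 1e-10
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.m <= 3 and 0 <= self.l <= 3):
            raise FitError("polynomial degrees must lie in 0..3")
        if self.tau_bounds[0] <= 0 or self.tau_bounds[0] >= self.tau_bounds[1]:
            raise FitError("tau bounds must satisfy 0 < lo < hi")

    @property
    def p_per_sensor(self) -> int:
        # shared tau + (m+1) gain + (l+1) offset coefficients
        return self.m + self.l + 3


@dataclass(frozen=True)
class CalibrationFit:
    session_id: str
    m: int
    l: int
    tau_hat: float
    gain_hat: list[np.ndarray]  # per sensor, ascending powers
    offset_hat: list[np.ndarray]
    covariance: np.ndarray | None = field(repr=False, default=None)
    se: np.ndarray | None = field(repr=False, default=None)
    cv: np.ndarray | None = field(repr=False, default=None)  # percent, NaN where undefined
    param_names: list[str] = field(default_factory=list, repr=False)
    converged: bool = True
    tau_at_bound: bool = False
    n_obs: list[int] = field(default_factory=list)
    cost: float = np.nan  # sum of squared deviations at the optimum

    @property
    def n_sensors(self) -> int:
        return len(self.gain_hat)

    @property
    def d_total(self) -> int:
        return int(sum(self.n_obs))


@dataclass(frozen=True)
class ResidualSet:
    """Per-sensor residual series res_i(t) on the aligned CGM grid."""

    session_id: str
    times: np.ndarray = field(repr=False)
    res: list[np.ndarray] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.res)


def _polyval(coeffs: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(t, coeffs)


def _model_values(
    bg: GlucoseSeries, tau: float, gain: np.ndarray, offset: np.ndarray, times: np.ndarray
) -> np.ndarray:
    ig = bg_to_ig(bg, max(tau, 0.0)).value_at(times)
    return _polyval(gain, times) * ig + _polyval(offset, times)


def _aligned(session: SessionData, bg: GlucoseSeries) -> list[AlignedPairs]:
    return [align_to_cgm(bg, trace) for trace in session.cgm]


def _unpack(theta: np.ndarray, n_sensors: int, m: int, l: int):
    tau = theta[0]
    gains, offsets = [], []
    k = 1
    for _ in range(n_sensors):
        gains.append(theta[k : k + m + 1])
        k += m + 1
        offsets.append(theta[k : k + l + 1])
        k += l + 1
    return tau, gains, offsets


def fit_session(session: SessionData, bg: GlucoseSeries, spec: FitSpec) -> CalibrationFit:
    """Pooled nonlinear least squares over all sensors of one session.

    One shared tau, sensor-specific polynomial coefficients.  Missing CGM
    samples and samples outside the BG span are excluded.  Non-convergence
    and a tau estimate pinned at a bound are flagged, not raised.
    """
    pairs = _aligned(session, bg)
    masks = [~np.isnan(p.cgm) for p in pairs]
    if not any(mk.any() for mk in masks):
        raise FitError("no usable CGM samples in session")
    n_sensors = session.n_sensors
    m, l = spec.m, spec.l

    def residual_vec(theta: np.ndarray) -> np.ndarray:
        tau, gains, offsets = _unpack(theta, n_sensors, m, l)
        parts = []
        for p, mk, g, b in zip(pairs, masks, gains, offsets):
            pred = _model_values(bg, tau, g, b, p.times[mk])
            parts.append(p.cgm[mk] - pred)
        return np.concatenate(parts)

    theta0 = np.zeros(1 + n_sensors * (m + l + 2))
    theta0[0] = spec.tau_init
    _, g0, _ = _unpack(theta0, n_sensors, m, l)
    for g in g0:
        g[0] = 1.0  # physiologically neutral start: unit gain, zero offset
    lo = np.full_like(theta0, -np.inf)
    hi = np.full_like(theta0, np.inf)
    lo[0], hi[0] = spec.tau_bounds

    sol = least_squares(
        residual_vec,
        theta0,
        bounds=(lo, hi),
        method="trf",
        ftol=spec.tolerance,
        xtol=spec.tolerance,
        gtol=spec.tolerance,
        max_nfev=spec.max_iter * theta0.size,
    )
    tau_hat, gains, offsets = _unpack(sol.x, n_sensors, m, l)
    names = ["tau"]
    for i in range(1, n_sensors + 1):
        names += [f"a{k}_s{i}" for k in range(m + 1)]
        names += [f"b{k}_s{i}" for k in range(l + 1)]

    n_obs = [int(mk.sum()) for mk in masks]
    dof = sum(n_obs) - sol.x.size
    cov = se = cv = None
    if dof > 0:
        J = sol.jac
        JtJ = J.T @ J
        try:
            sigma2 = 2.0 * sol.cost / dof
            cov = sigma2 * np.linalg.inv(JtJ)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = 100.0 * se / np.abs(sol.x)
            cv = np.where(np.abs(sol.x) < 1e-12, np.nan, cv)
        except np.linalg.LinAlgError:
            cov = se = cv = None

    at_bound = bool(
        tau_hat <= spec.tau_bounds[0] + 1e-9 or tau_hat >= spec.tau_bounds[1] - 1e-9
    )
    return CalibrationFit(
        session_id=session.session_id,
        m=m,
        l=l,
        tau_hat=float(tau_hat),
        gain_hat=[np.array(g) for g in gains],
        offset_hat=[np.array(b) for b in offsets],
        covariance=cov,
        se=se,
        cv=cv,
        param_names=names,
        converged=bool(sol.success),
        tau_at_bound=at_bound,
        n_obs=n_obs,
        cost=float(2.0 * sol.cost),
    )


def compute_residuals(session: SessionData, bg: GlucoseSeries, fit: CalibrationFit) -> ResidualSet:
    """res_i(t) = CGM_i(t) - [a_i(t) (h_tau * BG)(t) + b_i(t)] on the aligned grid.

    Missing CGM samples propagate as NaN residuals.
    """
    if len(fit.gain_hat) != session.n_sensors:
        raise FitError("fit and session disagree on the number of sensors")
    pairs = _aligned(session, bg)
    times = pairs[0].times
    res = []
    for p, g, b in zip(pairs, fit.gain_hat, fit.offset_hat):
        pred = _model_values(bg, fit.tau_hat, g, b, p.times)
        res.append(p.cgm - pred)
    return ResidualSet(session.session_id, times, res)


def precision_summary(
    fits: list[CalibrationFit], thresholds: tuple[float, ...] = (10.0, 20.0, 30.0)
) -> pd.DataFrame:
    """Parameter-wise estimate statistics and CV threshold percentages.

    Per-sensor coefficients are pooled across sensors and sessions under
    their generic names (a0, a1, ..., b0, ...); tau contributes one value
    per session.  CVs reported as NaN (near-zero estimates) are excluded
    from the threshold percentages.
    """
    if not fits:
        raise FitError("no fits to summarize")
    est: dict[str, list[float]] = {}
    cvs: dict[str, list[float]] = {}
    for f in fits:
        values = [f.tau_hat]
        for g, b in zip(f.gain_hat, f.offset_hat):
            values.extend(g)
            values.extend(b)
        cv = f.cv if f.cv is not None else np.full(len(values), np.nan)
        for name, v, c in zip(f.param_names, values, cv):
            generic = name.split("_")[0]
            est.setdefault(generic, []).append(float(v))
            cvs.setdefault(generic, []).append(float(c))
    rows = []
    for name, vals in est.items():
        arr = np.asarray(vals)
        cv_arr = np.asarray(cvs[name])
        ok = ~np.isnan(cv_arr)
        row = {
            "parameter": name,
            "mean": arr.mean(),
            "sd": arr.std(ddof=1) if arr.size > 1 else 0.0,
            "p50": np.percentile(arr, 50),
            "p5": np.percentile(arr, 5),
            "p95": np.percentile(arr, 95),
        }
        for thr in thresholds:
            pct = 100.0 * np.mean(cv_arr[ok] < thr) if ok.any() else np.nan
            row[f"cv_lt_{int(thr)}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
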