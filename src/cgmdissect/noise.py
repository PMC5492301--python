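"""Autoregressive measurement-noise modelling and decomposition.

The residual noise left after removing kinetics and calibration from a CGM
trace is split, per session, into a *common component* cc(t) shared by all
sensors worn in parallel and a *sensor-specific component* ssc_i(t) unique
to each sensor:

    cc(t)    = mean over sensors of res_i(t)
    ssc_i(t) = res_i(t) - cc(t)

Both components are modelled as stationary AR processes driven by Gaussian
white innovations.  AR coefficients are estimated by conditional least
squares (one-step prediction-error loss), orders are chosen by a BIC over
candidate orders, and the fitted innovations are checked for normality with
the Anderson-Darling test.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class ARError(ValueError):
    """Invalid AR model or series for AR estimation."""


class NonStationaryError(ARError):
    """AR coefficients with a characteristic root on or outside the unit circle."""


@dataclass(frozen=True)
class ARModel:
    """An autoregressive process x(t) = sum_k coeffs[k-1] x(t-k) + w(t).

    ``innovation_var`` is the variance of the white innovation w(t) in
    mg^2/dL^2; ``fitted_on`` records the number of regression rows used
    when the model was estimated from data (0 for a specified model).
    """

    coeffs: np.ndarray = field(repr=False)
    innovation_var: float
    fitted_on: int = 0

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        object.__setattr__(self, "coeffs", c)
        if c.ndim != 1 or c.size < 1:
            raise ARError("need at least one AR coefficient (use 0.0 for white noise)")
        if not np.isfinite(self.innovation_var) or self.innovation_var <= 0:
            raise ARError("innovation variance must be positive")

    @property
    def order(self) -> int:
        return int(self.coeffs.size)

    def is_stationary(self) -> bool:
        # roots of z^p - c1 z^(p-1) - ... - cp
        poly = np.concatenate(([1.0], -self.coeffs))
        roots = np.roots(poly)
        return bool(np.all(np.abs(roots) < 1.0 - 1e-12))

    def require_stationary(self) -> None:
        if not self.is_stationary():
            raise NonStationaryError(
                f"AR coefficients {self.coeffs.tolist()} are not stationary"
            )


def stationary_variance(model: ARModel) -> float:
    """Long-run variance of the AR process via the Yule-Walker equations."""
    model.require_stationary()
    c, p = model.coeffs, model.order
    # solve for autocorrelations rho_1..rho_p: rho_k = sum_j c_j rho_|k-j|
    A = np.eye(p)
    b = np.zeros(p)
    for k in range(1, p + 1):
        for j in range(1, p + 1):
            m = abs(k - j)
            if m == 0:
                b[k - 1] += c[j - 1]
            else:
                A[k - 1, m - 1] -= c[j - 1]
    rho = np.linalg.solve(A, b)
    return float(model.innovation_var / (1.0 - float(c @ rho)))


def simulate_ar(
    model: ARModel,
    length: int,
    seed: int | np.random.Generator,
    burn_in: int = 500,
) -> np.ndarray:
    """Draw a zero-mean realization of a stationary AR process.

    The first ``burn_in`` samples are discarded so the returned window is
    (approximately) a draw from the stationary distribution.  Identical
    (model, length, seed, burn_in) yield identical output.
    """
    model.require_stationary()
    if length < 1:
        raise ARError("length must be >= 1")
    if burn_in < 0:
        raise ARError("burn_in must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = model.order
    n = length + burn_in
    w = rng.normal(0.0, np.sqrt(model.innovation_var), n)
    x = np.zeros(n)
    c = model.coeffs
    for t in range(n):
        k = min(p, t)
        x[t] = (c[:k] @ x[t - k : t][::-1] if k else 0.0) + w[t]
    return x[burn_in:]


def _lagged_rows(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of lagged values and target vector for one series."""
    n = x.size
    X = np.column_stack([x[order - k : n - k] for k in range(1, order + 1)])
    y = x[order:]
    return X, y


def fit_ar(series: np.ndarray, order: int) -> ARModel:
    """Estimate AR coefficients by conditional least squares.

    The loss is the mean squared one-step prediction error, whose minimized
    value is returned as the innovation variance.
    """
    x = np.asarray(series, dtype=float)
    if order < 1:
        raise ARError("order must be >= 1")
    if x.size <= 10 * order:
        raise ARError(f"series of length {x.size} too short for AR({order}) fit")
    if np.ptp(x) == 0:
        raise ARError("constant series cannot be fitted as an AR process")
    X, y = _lagged_rows(x, order)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < order:
        raise ARError("rank-deficient lag regression")
    resid = y - X @ coef
    model = ARModel(coef, float(np.mean(resid**2)), fitted_on=int(y.size))
    if not model.is_stationary():
        warnings.warn("fitted AR coefficients are non-stationary", stacklevel=2)
    return model


def prediction_errors(model: ARModel, series: np.ndarray) -> np.ndarray:
    """One-step prediction errors e(t) of ``model`` applied to ``series``."""
    x = np.asarray(series, dtype=float)
    p = model.order
    if x.size <= p:
        raise ARError("series shorter than the AR order")
    X, y = _lagged_rows(x, p)
    return y - X @ model.coeffs


def bic_ar(series: np.ndarray, order: int) -> float:
    """BIC for one candidate AR order: N ln(lss) + k ln(N).

    ``lss`` is the conditional-least-squares loss (mean squared one-step
    prediction error) and N the series length.
    """
    x = np.asarray(series, dtype=float)
    lss = fit_ar(x, order).innovation_var
    if lss <= 0:
        raise ARError("zero prediction-error loss; BIC undefined")
    n = x.size
    return float(n * np.log(lss) + order * np.log(n))


@dataclass(frozen=True)
class ARSelection:
    per_series_order: list[int]
    modal_order: int
    bic_curves: list[np.ndarray] = field(repr=False)


def select_ar_order(series_list: list[np.ndarray], k_max: int = 15) -> ARSelection:
    """Per-series argmin-BIC order in 1..k_max, then the mode across series.

    ``k_max`` is reduced automatically where a series is too short to
    support the conditional-least-squares fit at high orders.  Ties in the
    mode are broken toward the smaller order.
    """
    if not series_list:
        raise ARError("empty series list")
    orders: list[int] = []
    curves: list[np.ndarray] = []
    for x in series_list:
        x = np.asarray(x, dtype=float)
        k_hi = min(k_max, (x.size - 1) // 10)
        if k_hi < 1:
            raise ARError(f"series of length {x.size} too short for order selection")
        curve = np.array([bic_ar(x, k) for k in range(1, k_hi + 1)])
        orders.append(int(np.argmin(curve)) + 1)
        curves.append(curve)
    counts = Counter(orders)
    top = max(counts.values())
    modal = min(k for k, v in counts.items() if v == top)
    return ARSelection(orders, modal, curves)


@dataclass(frozen=True)
class ValidationResult:
    statistic: float
    critical_5pct: float
    passed: bool


def validate_ar(model: ARModel, series: np.ndarray) -> ValidationResult:
    """Anderson-Darling composite-normality check on prediction errors.

    Passing at the 5% level supports the Gaussian-innovation AR description
    of the series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < model.order + 8:
        raise ARError("series too short to validate")
    e = prediction_errors(model, x)
    with warnings.catch_warnings():
        # scipy >= 1.17 deprecation chatter about p-value methods; the
        # critical-value comparison below is version-stable
        warnings.simplefilter("ignore", FutureWarning)
        res = sps.anderson(e, dist="norm")
    idx = list(res.significance_level).index(5.0)
    crit = float(res.critical_values[idx])
    return ValidationResult(float(res.statistic), crit, bool(res.statistic < crit))


def fit_population_ar(series_list: list[np.ndarray], order: int) -> ARModel:
    """Pool the lag-regression rows of several series into one AR fit.

    Rows whose lag window would cross a series boundary are excluded, so no
    spurious cross-series correlation enters the estimate.
    """
    if not series_list:
        raise ARError("empty series list")
    Xs, ys = [], []
    for x in series_list:
        x = np.asarray(x, dtype=float)
        if x.size <= order:
            continue
        X, y = _lagged_rows(x, order)
        Xs.append(X)
        ys.append(y)
    if not Xs:
        raise ARError(f"no series long enough for AR({order}) pooling")
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    if y.size <= 10 * order:
        raise ARError("too few pooled rows for a stable fit")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < order:
        raise ARError("rank-deficient pooled lag regression")
    resid = y - X @ coef
    model = ARModel(coef, float(np.mean(resid**2)), fitted_on=int(y.size))
    if not model.is_stationary():
        warnings.warn("pooled AR coefficients are non-stationary", stacklevel=2)
    return model


# ---------------------------------------------------------------------------
# residual decomposition


@dataclass(frozen=True)
class NoiseDecomposition:
    """Common / sensor-specific split of a session's residual profiles."""

    cc: np.ndarray = field(repr=False)
    ssc: list[np.ndarray] = field(repr=False)
    session_id: str = ""


def decompose_noise(residuals: list[np.ndarray], session_id: str = "") -> NoiseDecomposition:
    """Split n >= 2 aligned residual series into cc and ssc_i.

    cc(t) is the per-instant mean across sensors; ssc_i(t) = res_i(t) - cc(t).
    Reconstruction cc + ssc_i == res_i is exact by construction, and the
    ssc_i sum to zero at every instant.
    """
    if len(residuals) < 2:
        raise ARError("noise decomposition needs at least 2 parallel sensors")
    arrs = [np.asarray(r, dtype=float) for r in residuals]
    n0 = arrs[0].size
    if any(a.size != n0 for a in arrs):
        raise ARError("residual series must share one aligned grid")
    cc = np.mean(np.vstack(arrs), axis=0)
    ssc = [a - cc for a in arrs]
    return NoiseDecomposition(cc, ssc, session_id)


def variance_summary(decomps: list[NoiseDecomposition]) -> pd.DataFrame:
    """Per-session cc/ssc variances with cross-session medians.

    Returns a tidy frame (session_id, component, variance).  The median row
    block mirrors the published per-sensor-generation summary; a rank-sum
    test compares the cc and ssc variance samples.
    """
    if not decomps:
        raise ARError("no decompositions to summarize")
    rows = []
    for d in decomps:
        rows.append({"session_id": d.session_id, "component": "cc",
                     "variance": float(np.var(d.cc))})
        for i, s in enumerate(d.ssc, start=1):
            rows.append({"session_id": d.session_id, "component": f"ssc_{i}",
                         "variance": float(np.var(s))})
    df = pd.DataFrame(rows)
    cc_vars = df.loc[df.component == "cc", "variance"].to_numpy()
    ssc_vars = df.loc[df.component.str.startswith("ssc"), "variance"].to_numpy()
    if cc_vars.size and ssc_vars.size and (np.ptp(cc_vars) or np.ptp(ssc_vars)):
        stat, pval = sps.ranksums(cc_vars, ssc_vars)
    else:
        stat, pval = np.nan, np.nan
    df.attrs["median_cc_variance"] = float(np.median(cc_vars))
    df.attrs["median_ssc_variance"] = float(np.median(ssc_vars))
    df.attrs["ranksum_statistic"] = float(stat)
    df.attrs["ranksum_p"] = float(pval)
    return df


# Published population processes for the Enlite sensor (used as generative
# defaults by the synthetic module and as recovery targets in validation).
POPULATION_CC_AR = ARModel(np.array([1.584, -0.8842, 0.1798]), 3.98)
POPULATION_SSC_AR = ARModel(np.array([1.367, -0.4816]), 2.54)
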