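"""Polynomial-order selection by BIC on whitened residuals.

The calibration residuals are serially correlated, so before computing a
BIC the residual series of each sensor is whitened: an AR model (order
chosen by the AR-BIC criterion, capped at 15) is fitted to it and the
one-step prediction errors eta are taken as the uncorrelated version of
the measurement noise.  The model-order BIC is then

    BIC = d ln(RSS) + p ln(d),    RSS = mean(eta^2),  p = m + l + 3

per sensor and session.  Candidate orders are compared pairwise through
Delta BIC = BIC_LO - BIC_EHO (LO = lower-order, EHO = equal-or-higher-order
by parameter count); each pair is tested for a location difference with a
t-test when both BIC samples pass a Shapiro-Wilk normality check and a
Wilcoxon rank-sum test otherwise.  Significant pairs are scored by
(percentage of positive Delta BIC) x (mean Delta BIC) and the EHO of the
top-scoring pair is selected.  If no pair is significant the most
parsimonious candidate wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import ResidualSet
from .noise import bic_ar, fit_ar, prediction_errors


class SelectionError(ValueError):
    """Invalid input to whitening or ranking."""


@dataclass(frozen=True)
class WhitenedResiduals:
    session_id: str
    eta: list[np.ndarray] = field(repr=False)  # per sensor prediction errors
    orders: list[int] = field(default_factory=list)


def whiten_residuals(
    res: ResidualSet, k_max: int = 15, filter_source: ResidualSet | None = None
) -> WhitenedResiduals:
    """Replace each residual series by AR one-step prediction errors.

    By default the whitening AR model is fitted on the series itself.  When
    comparing candidate mean models, however, a filter fitted on a misfit
    model's residuals absorbs the smooth misfit along with the serial
    correlation; passing ``filter_source`` (the residuals of the richest
    candidate, whose residuals are essentially pure noise) fits the filter
    there and applies it to ``res``, so every candidate is whitened by the
    same noise-only filter and deterministic misfit survives into the BIC.
    """
    src = filter_source if filter_source is not None else res
    if len(src.res) != len(res.res):
        raise SelectionError("filter source must have the same number of sensors")
    etas, orders = [], []
    for series, ref_series in zip(res.res, src.res):
        x = np.asarray(series, dtype=float)
        x = x[~np.isnan(x)]
        xr = np.asarray(ref_series, dtype=float)
        xr = xr[~np.isnan(xr)]
        if x.size < 20 or xr.size < 20:
            raise SelectionError("residual series too short to whiten (need >= 20)")
        if np.ptp(xr) == 0:
            raise SelectionError("degenerate constant residual series")
        k_hi = min(k_max, (xr.size - 1) // 10)
        bics = [bic_ar(xr, k) for k in range(1, k_hi + 1)]
        order = int(np.argmin(bics)) + 1
        model = fit_ar(xr, order)
        etas.append(prediction_errors(model, x))
        orders.append(order)
    return WhitenedResiduals(res.session_id, etas, orders)


def compute_bic(eta: np.ndarray, d: int, p: int) -> float:
    """BIC = d ln(RSS) + p ln(d) with RSS the mean squared whitened residual."""
    eta = np.asarray(eta, dtype=float)
    if eta.size == 0:
        raise SelectionError("empty whitened residual series")
    if d <= p:
        raise SelectionError("observation count must exceed parameter count")
    rss = float(np.mean(eta**2))
    if rss <= 0:
        raise SelectionError("zero residual sum of squares; BIC diverges")
    return float(d * np.log(rss) + p * np.log(d))


@dataclass(frozen=True)
class BICRecord:
    session_id: str
    sensor_index: int
    m: int
    l: int
    d: int
    bic: float

    @property
    def p(self) -> int:
        return self.m + self.l + 3


def bic_records_frame(records: list[BICRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "session_id": r.session_id,
                "sensor_index": r.sensor_index,
                "m": r.m,
                "l": r.l,
                "p": r.p,
                "d": r.d,
                "bic": r.bic,
            }
            for r in records
        ]
    )


def rank_models(
    records: pd.DataFrame | list[BICRecord],
    alpha: float = 0.05,
    paired_tests: bool = True,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Rank (LO, EHO) order pairs by positivity x mean Delta BIC.

    ``records`` must hold a BIC value for every (m, l) candidate on the
    same set of session x sensor units.  BIC values are paired by unit
    (each session x sensor contributes one BIC per candidate), so the
    default location tests are the paired ones on the Delta BIC sample:
    paired t when the differences pass a Shapiro-Wilk normality check,
    Wilcoxon signed-rank otherwise.  ``paired_tests=False`` switches to
    unpaired two-sample tests on the raw BIC samples, whose power is
    limited because between-session BIC variation dwarfs the order signal.
    """
    df = records if isinstance(records, pd.DataFrame) else bic_records_frame(records)
    required = {"session_id", "sensor_index", "m", "l", "p", "bic"}
    if not required.issubset(df.columns):
        raise SelectionError(f"records need columns {sorted(required)}")
    units = df.groupby(["m", "l"]).apply(
        lambda g: frozenset(zip(g.session_id, g.sensor_index)), include_groups=False
    )
    if units.nunique() != 1:
        raise SelectionError("every (m, l) must cover the same session x sensor units")
    orders = sorted(units.index)
    wide = df.pivot_table(
        index=["session_id", "sensor_index"], columns=["m", "l"], values="bic"
    )
    if len(wide) < 5:
        raise SelectionError("need at least 5 records per model pair")

    p_of = {(m, l): m + l + 3 for (m, l) in orders}
    rows = []
    for lo in orders:
        for eho in orders:
            if lo == eho or p_of[lo] > p_of[eho]:
                continue
            b_lo = wide[lo].to_numpy()
            b_eho = wide[eho].to_numpy()
            delta = b_lo - b_eho
            if paired_tests:
                if np.ptp(delta) == 0:
                    test, pval = "degenerate", 1.0
                elif sps.shapiro(delta).pvalue > alpha:
                    test, pval = "paired_t", sps.ttest_rel(b_lo, b_eho).pvalue
                else:
                    test, pval = "signed_rank", sps.wilcoxon(b_lo, b_eho).pvalue
            else:
                normal = (
                    sps.shapiro(b_lo).pvalue > alpha
                    and sps.shapiro(b_eho).pvalue > alpha
                )
                if normal:
                    test, pval = "t", sps.ttest_ind(b_lo, b_eho).pvalue
                else:
                    test, pval = "ranksum", sps.ranksums(b_lo, b_eho).pvalue
            positivity = 100.0 * float(np.mean(delta > 0))
            mean_delta = float(np.mean(delta))
            rows.append(
                {
                    "lo_m": lo[0],
                    "lo_l": lo[1],
                    "eho_m": eho[0],
                    "eho_l": eho[1],
                    "test_used": test,
                    "p_value": float(pval),
                    "significant": bool(pval < alpha),
                    "positivity": positivity,
                    "mean_delta": mean_delta,
                    "score": positivity * mean_delta,
                }
            )
    ranking = pd.DataFrame(rows).sort_values(
        ["score", "p_value"], ascending=[False, True], ignore_index=True
    )
    contenders = ranking[ranking.significant & (ranking.score > 0)]
    if len(contenders):
        best_score = contenders.score.max()
        top = contenders[contenders.score >= best_score].copy()
        # ties broken toward the more parsimonious higher-order candidate
        top["p_eho"] = top.eho_m + top.eho_l + 3
        top = top.sort_values(["p_eho", "p_value"]).iloc[0]
        selected = (int(top.eho_m), int(top.eho_l))
    else:
        selected = min(orders, key=lambda o: (p_of[o], o[0] + o[1]))
    return ranking, selected
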