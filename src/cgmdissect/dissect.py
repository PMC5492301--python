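"""MARD-based dissection of CGM error and accuracy stratification.

The global error and its three components are quantified by the mean
absolute relative difference between the signal pairs that bracket each
stage of the error chain: BG vs CGM (global), BG vs IG (kinetics),
IG vs IGS (calibration) and IGS vs CGM (noise).  IG and IGS are model
reconstructions from the fitted time constant and polynomials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import CalibrationFit, _model_values
from .preprocess import align_to_cgm
from .series import GlucoseSeries
from .synthetic import SessionData, bg_to_ig


class DissectionError(ValueError):
    """Invalid input to an accuracy computation."""


def mard(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean absolute relative difference, percent: 100 mean |test-ref|/ref."""
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.size == 0:
        raise DissectionError("series must be aligned, same length >= 1")
    if np.any(ref <= 0):
        raise DissectionError("reference values must be positive")
    return float(100.0 * np.mean(np.abs(tst - ref) / ref))


def dissect_error(
    session: SessionData,
    bg: GlucoseSeries,
    fit: CalibrationFit,
    decomposition=None,
) -> pd.DataFrame:
    """Per-sensor MARD of the global error and its three components.

    Signals are evaluated at the aligned CGM instants with non-missing CGM.
    ``decomposition`` is accepted for pipeline symmetry; the noise
    component is measured directly as mard(IGS_i, CGM_i).
    """
    if len(fit.gain_hat) != session.n_sensors:
        raise DissectionError("fit does not match the session's sensor count")
    ig_series = bg_to_ig(bg, fit.tau_hat)
    rows = []
    for i, trace in enumerate(session.cgm):
        pairs = align_to_cgm(bg, trace)
        ok = ~np.isnan(pairs.cgm)
        t = pairs.times[ok]
        bg_v = pairs.bg[ok]
        cgm_v = pairs.cgm[ok]
        ig_v = ig_series.value_at(t)
        igs_v = _model_values(bg, fit.tau_hat, fit.gain_hat[i], fit.offset_hat[i], t)
        # denominators must be positive: strong offset drift can push the
        # reconstructed IGS through zero at glucose lows; such instants are
        # excluded from the ratios rather than poisoning the whole session
        pos = (bg_v > 0) & (ig_v > 0) & (igs_v > 0)
        if not pos.all():
            t, bg_v, cgm_v, ig_v, igs_v = (
                x[pos] for x in (t, bg_v, cgm_v, ig_v, igs_v)
            )
        rows.append(
            {
                "session_id": session.session_id,
                "sensor": i + 1,
                "global_mard": mard(bg_v, cgm_v),
                "bgig_mard": mard(bg_v, ig_v),
                "calibration_mard": mard(ig_v, igs_v),
                "noise_mard": mard(igs_v, cgm_v),
            }
        )
    return pd.DataFrame(rows)


DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.0, 70.0), (70.0, 180.0), (180.0, np.inf))


def _band_label(lo: float, hi: float) -> str:
    if lo <= 0:
        return f"<{hi:g}"
    if np.isinf(hi):
        return f">{lo:g}"
    return f"{lo:g}-{hi:g}"


def stratify_by_range(
    reference: np.ndarray,
    cgm: np.ndarray,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Accuracy per glycemic band, pairs assigned by their reference value.

    Bands are [lo, hi) except the last which is closed above only by
    infinity; adjacent bands must tile (0, inf) without overlap.  Returns
    per-band sample count, time percentage and the mean/SD of the
    per-sample absolute relative differences, plus an overall row.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(cgm, dtype=float)
    if ref.size == 0 or ref.shape != tst.shape:
        raise DissectionError("need aligned, nonempty reference/CGM pairs")
    if np.any(ref <= 0):
        raise DissectionError("reference values must be positive")
    edges = sorted(bands)
    for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
        if hi1 != lo2:
            raise DissectionError("bands must tile (0, inf) without overlap or gap")
    if edges[0][0] != 0 or not np.isinf(edges[-1][1]):
        raise DissectionError("bands must start at 0 and end at infinity")

    ard = 100.0 * np.abs(tst - ref) / ref
    total = ref.size
    rows = []
    for lo, hi in bands:
        mask = (ref >= lo) & (ref < hi)
        n = int(mask.sum())
        rows.append(
            {
                "band": _band_label(lo, hi),
                "n": n,
                "time_pct": 100.0 * n / total,
                "mard_mean": float(ard[mask].mean()) if n else np.nan,
                "mard_sd": float(ard[mask].std(ddof=1)) if n > 1 else np.nan,
            }
        )
    rows.append(
        {
            "band": "overall",
            "n": total,
            "time_pct": 100.0,
            "mard_mean": float(ard.mean()),
            "mard_sd": float(ard.std(ddof=1)) if total > 1 else np.nan,
        }
    )
    return pd.DataFrame(rows)


def rate_of_change_stats(bg: GlucoseSeries, bin_edges: np.ndarray) -> pd.DataFrame:
    """Histogram of the 1-step glucose rate of change, mg/dL/min.

    Fractions sum to 1; rates outside the outer edges are collected into
    the first/last bins so no sample is silently dropped.
    """
    if bg.values.size < 2:
        raise DissectionError("need at least 2 samples for a rate profile")
    rate = np.diff(bg.values) / bg.dt
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise DissectionError("bin edges must be increasing with >= 2 values")
    clipped = np.clip(rate, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "fraction": counts / rate.size,
        }
    )
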