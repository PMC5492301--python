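"""Reference smoothing, CGM alignment, and session quality control.

Sparse reference draws (every 15 +/- 5 min) are turned into a smooth 1-min
blood-glucose profile by a discrete second-order Tikhonov smoother: the
profile x on the output grid minimizes

    || A x - y ||^2  +  lam * || D2 x ||^2

where A interpolates the grid at the sample instants and D2 is the second
difference operator.  The penalty null space is affine, so constant and
linear data are reproduced exactly.  With ``roughness_penalty="auto"`` the
weight is chosen by the discrepancy criterion: lam is increased until the
residual sum of squares at the sample instants matches the assumed
measurement variance of the reference instrument.  When that assumed
variance is zero (gold-standard reference) the smoother reduces to
minimum-roughness interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .series import GlucoseSeries, ReferenceSamples

_LAM_FLOOR = 1e-8


class PreprocessError(ValueError):
    """Invalid smoother input or configuration."""


@dataclass(frozen=True)
class SmootherConfig:
    grid_dt: float = 1.0
    roughness_penalty: float | str = "auto"
    max_gap: float = 45.0
    ref_sd_frac: float = 0.02  # assumed proportional SD of the reference instrument

    def __post_init__(self) -> None:
        if self.grid_dt <= 0:
            raise PreprocessError("grid_dt must be positive")
        if self.max_gap <= self.grid_dt:
            raise PreprocessError("max_gap must exceed grid_dt")
        if isinstance(self.roughness_penalty, str):
            if self.roughness_penalty != "auto":
                raise PreprocessError("roughness_penalty must be a number or 'auto'")
        elif self.roughness_penalty < 0:
            raise PreprocessError("roughness_penalty must be non-negative")
        if self.ref_sd_frac < 0:
            raise PreprocessError("ref_sd_frac must be non-negative")


def _interp_matrix(grid: np.ndarray, times: np.ndarray) -> sparse.csr_matrix:
    """Rows of linear-interpolation weights mapping grid values to instants."""
    dt = grid[1] - grid[0]
    pos = (times - grid[0]) / dt
    i0 = np.clip(np.floor(pos).astype(int), 0, grid.size - 2)
    w = pos - i0
    rows = np.repeat(np.arange(times.size), 2)
    cols = np.column_stack([i0, i0 + 1]).ravel()
    data = np.column_stack([1.0 - w, w]).ravel()
    return sparse.csr_matrix((data, (rows, cols)), shape=(times.size, grid.size))


def _solve(AtA, AtY, D2tD2, lam: float) -> np.ndarray:
    return spsolve((AtA + lam * D2tD2).tocsc(), AtY)


def smooth_reference(ref: ReferenceSamples, cfg: SmootherConfig | None = None) -> GlucoseSeries:
    """Second-order-difference penalized estimate of the BG profile.

    Returns a series on the ``cfg.grid_dt`` grid spanning the reference
    instants.  Requires at least 4 samples and no gap above ``cfg.max_gap``.
    """
    cfg = cfg or SmootherConfig()
    if len(ref) < 4:
        raise PreprocessError("need at least 4 reference samples to smooth")
    gaps = np.diff(ref.times)
    if np.any(gaps > cfg.max_gap):
        raise PreprocessError(f"reference gap {gaps.max():.1f} min exceeds max_gap")
    t0, t1 = ref.span
    grid = t0 + cfg.grid_dt * np.arange(int(round((t1 - t0) / cfg.grid_dt)) + 1)
    A = _interp_matrix(grid, ref.times)
    n = grid.size
    D2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    AtA = (A.T @ A).tocsc()
    AtY = A.T @ ref.values
    D2tD2 = (D2.T @ D2).tocsc()

    if cfg.roughness_penalty != "auto":
        lam = max(float(cfg.roughness_penalty), _LAM_FLOOR)
        return GlucoseSeries(grid[0], cfg.grid_dt, _solve(AtA, AtY, D2tD2, lam))

    target = float(np.sum((cfg.ref_sd_frac * ref.values) ** 2))
    x = _solve(AtA, AtY, D2tD2, _LAM_FLOOR)
    if target <= 0 or np.sum((A @ x - ref.values) ** 2) >= target:
        # gold-standard reference, or data already rougher than the noise
        # level at the floor: minimum-roughness interpolation
        return GlucoseSeries(grid[0], cfg.grid_dt, x)
    lo, hi = np.log10(_LAM_FLOOR), 8.0
    for _ in range(60):  # RSS(lam) is monotone increasing
        mid = 0.5 * (lo + hi)
        x = _solve(AtA, AtY, D2tD2, 10.0**mid)
        if np.sum((A @ x - ref.values) ** 2) < target:
            lo = mid
        else:
            hi = mid
    return GlucoseSeries(grid[0], cfg.grid_dt, _solve(AtA, AtY, D2tD2, 10.0**lo))


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignedPairs:
    """BG/CGM values paired at CGM sample instants inside the BG span."""

    times: np.ndarray = field(repr=False)
    bg: np.ndarray = field(repr=False)
    cgm: np.ndarray = field(repr=False)
    n_dropped: int = 0  # CGM instants outside the BG span


def align_to_cgm(bg: GlucoseSeries, cgm: GlucoseSeries) -> AlignedPairs:
    """Pair the smooth BG profile with a CGM trace on the CGM grid.

    CGM samples outside the BG span are dropped and counted; no sample is
    ever fabricated.  Missing CGM samples (NaN) stay NaN in the output.
    """
    t = cgm.times
    inside = (t >= bg.t0 - 1e-9) & (t <= bg.t_end + 1e-9)
    if not inside.any():
        raise PreprocessError("no overlap between BG profile and CGM trace")
    t_in = t[inside]
    return AlignedPairs(t_in, bg.value_at(t_in), cgm.values[inside], int((~inside).sum()))


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QCConfig:
    max_cgm_gap: float = 30.0  # minutes of consecutive missing CGM tolerated
    min_coverage: float = 0.9
    require_same_day_insertion: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise PreprocessError("min_coverage must be in (0, 1]")


@dataclass(frozen=True)
class QCReport:
    table: pd.DataFrame  # session_id, kept, reason

    @property
    def n_kept(self) -> int:
        return int(self.table.kept.sum())


def _max_nan_run(values: np.ndarray) -> int:
    run = best = 0
    for v in values:
        run = run + 1 if np.isnan(v) else 0
        best = max(best, run)
    return best


def _qc_reason(session, cfg: QCConfig) -> str | None:
    traces = session.cgm
    t0, dt, n = traces[0].t0, traces[0].dt, traces[0].values.size
    for s in traces[1:]:
        if s.t0 != t0 or s.dt != dt or s.values.size != n:
            return "structural_inconsistency"
    if len(traces) < 2:
        return "fewer_than_two_sensors"
    if cfg.require_same_day_insertion and not getattr(session, "same_day_insertion", True):
        return "insertion_day_mismatch"
    for i, s in enumerate(traces, start=1):
        if _max_nan_run(s.values) * dt > cfg.max_cgm_gap:
            return f"signal_loss_sensor_{i}"
        coverage = 1.0 - np.isnan(s.values).mean()
        if coverage < cfg.min_coverage:
            return f"low_coverage_sensor_{i}"
    return None


def qc_sessions(dataset: list, cfg: QCConfig | None = None) -> tuple[list, QCReport]:
    """Exclude sessions failing any QC rule; report every exclusion."""
    if not dataset:
        raise PreprocessError("empty dataset")
    cfg = cfg or QCConfig()
    kept, rows = [], []
    for sess in dataset:
        reason = _qc_reason(sess, cfg)
        if reason is None:
            kept.append(sess)
        rows.append({"session_id": sess.session_id, "kept": reason is None,
                     "reason": reason or ""})
    return kept, QCReport(pd.DataFrame(rows))
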