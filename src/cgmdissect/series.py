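"""Core time-series containers for glucose signals.

All signals in this package live on uniform time grids measured in minutes
from the session origin (t = 0 at the first CGM sample).  Glucose is in
mg/dL throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SeriesError(ValueError):
    """Invalid glucose series or reference sample set."""


@dataclass(frozen=True)
class GlucoseSeries:
    """A uniformly sampled glucose signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, minutes.
    dt : float
        Sampling interval, minutes (> 0).
    values : ndarray
        Glucose concentrations, mg/dL.  NaN marks an explicitly missing
        sample (sensor signal loss); all present values must be finite and
        non-negative.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise SeriesError(f"dt must be positive and finite, got {self.dt}")
        if vals.ndim != 1 or vals.size < 2:
            raise SeriesError("a glucose series needs at least 2 samples")
        present = vals[~np.isnan(vals)]
        if np.any(~np.isfinite(present)):
            raise SeriesError("glucose values must be finite (or NaN for missing)")
        if np.any(present < 0):
            raise SeriesError("glucose values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary instants inside the span."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0 - 1e-9) or np.any(t > self.t_end + 1e-9):
            raise SeriesError("requested instants fall outside the series span")
        return np.interp(t, self.times, self.values)

    def with_values(self, values: np.ndarray) -> "GlucoseSeries":
        return GlucoseSeries(self.t0, self.dt, np.asarray(values, dtype=float))


@dataclass(frozen=True)
class ReferenceSamples:
    """Sparse reference blood-glucose samples (e.g. YSI draws).

    ``times`` must be strictly increasing; gaps are validated against the
    configured window only where a generator or QC step requires it.
    """

    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size != v.size:
            raise SeriesError("times and values must be 1-D and the same length")
        if t.size and np.any(np.diff(t) <= 0):
            raise SeriesError("reference times must be strictly increasing")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise SeriesError("reference samples must be finite")
        if np.any(v <= 0):
            raise SeriesError("reference glucose must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])
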