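"""Session CSV dialect and structured sidecars.

One CSV per session with columns ``time_min, ref_bg, cgm_1, ..., cgm_n``;
a row exists for every instant at which any signal has a sample, and cells
are empty where a signal has no sample (a missing CGM sample at a grid
instant is an empty cell on an existing row).  UTF-8, '.' decimal
separator.  Generative truth of synthetic sessions travels in a JSON
sidecar next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .noise import ARModel
from .series import GlucoseSeries, ReferenceSamples
from .synthetic import SensorTruth, SessionData, SessionTruth


class SessionIOError(ValueError):
    """Malformed session file."""


def write_session_csv(session: SessionData, path: str | Path) -> None:
    path = Path(path)
    cgm_times = session.cgm[0].times
    all_times = np.unique(np.concatenate([cgm_times, session.reference.times]))
    cols: dict[str, list] = {"time_min": [], "ref_bg": []}
    for i in range(session.n_sensors):
        cols[f"cgm_{i + 1}"] = []
    ref_lookup = dict(zip(session.reference.times, session.reference.values))
    cgm_lookup = [dict(zip(cgm_times, s.values)) for s in session.cgm]
    for t in all_times:
        cols["time_min"].append(t)
        cols["ref_bg"].append(ref_lookup.get(t, np.nan))
        for i, lk in enumerate(cgm_lookup):
            cols[f"cgm_{i + 1}"].append(lk.get(t, np.nan))
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_session_csv(path: str | Path) -> SessionData:
    """Parse a session CSV, enforcing the container invariants.

    The CGM grid is reconstructed from the instants that carry CGM rows;
    grid instants whose cells are all empty on a row are kept as missing
    samples.  Malformed numeric cells are reported with their line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SessionIOError(f"{path}: unreadable CSV ({exc})") from exc
    if "time_min" not in df.columns or "ref_bg" not in df.columns:
        raise SessionIOError(f"{path}: missing required columns time_min/ref_bg")
    cgm_cols = sorted(
        (c for c in df.columns if c.startswith("cgm_")), key=lambda c: int(c.split("_")[1])
    )
    if not cgm_cols:
        raise SessionIOError(f"{path}: no cgm_* columns")
    for col in ["time_min", "ref_bg", *cgm_cols]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SessionIOError(f"{path}: non-numeric value in column {col} at line {line}")
        df[col] = coerced
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.isnan(t)) or np.any(np.diff(t) <= 0):
        raise SessionIOError(f"{path}: time_min must be present and strictly increasing")

    has_cgm = df[cgm_cols].notna().any(axis=1).to_numpy()
    cgm_t = t[has_cgm]
    if cgm_t.size < 2:
        raise SessionIOError(f"{path}: fewer than 2 CGM rows")
    diffs = np.diff(cgm_t)
    dt = float(np.min(diffs))
    if np.any(np.abs(diffs / dt - np.round(diffs / dt)) > 1e-6):
        raise SessionIOError(f"{path}: CGM rows are not on a uniform grid (mixed dt)")
    n_grid = int(round((cgm_t[-1] - cgm_t[0]) / dt)) + 1
    grid = cgm_t[0] + dt * np.arange(n_grid)
    traces = []
    for col in cgm_cols:
        vals = np.full(n_grid, np.nan)
        col_v = df[col].to_numpy(dtype=float)[has_cgm]
        idx = np.round((cgm_t - cgm_t[0]) / dt).astype(int)
        vals[idx] = col_v
        traces.append(GlucoseSeries(float(grid[0]), dt, vals))

    has_ref = df["ref_bg"].notna().to_numpy()
    reference = ReferenceSamples(t[has_ref], df["ref_bg"].to_numpy(dtype=float)[has_ref])
    sid = path.stem
    return SessionData(traces, reference, session_id=sid)


# ---------------------------------------------------------------------------
# truth sidecar


def _ar_to_dict(model: ARModel) -> dict:
    return {
        "coeffs": model.coeffs.tolist(),
        "innovation_var": model.innovation_var,
        "fitted_on": model.fitted_on,
    }


def _ar_from_dict(d: dict) -> ARModel:
    return ARModel(np.asarray(d["coeffs"]), d["innovation_var"], d.get("fitted_on", 0))


def write_truth_json(truth: SessionTruth, path: str | Path) -> None:
    payload = {
        "tau": truth.tau,
        "cc_ar": _ar_to_dict(truth.cc_ar),
        "sensors": [
            {
                "gain_coeffs": s.gain_coeffs.tolist(),
                "offset_coeffs": s.offset_coeffs.tolist(),
                "ssc_ar": _ar_to_dict(s.ssc_ar),
            }
            for s in truth.sensors
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> SessionTruth:
    d = json.loads(Path(path).read_text())
    sensors = [
        SensorTruth(
            np.asarray(s["gain_coeffs"]), np.asarray(s["offset_coeffs"]), _ar_from_dict(s["ssc_ar"])
        )
        for s in d["sensors"]
    ]
    return SessionTruth(d["tau"], sensors, _ar_from_dict(d["cc_ar"]))


def write_dataset(sessions: list[SessionData], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sess in sessions:
        sid = sess.session_id or f"s{len(paths) + 1:03d}"
        p = out / f"{sid}.csv"
        write_session_csv(sess, p)
        if sess.truth is not None:
            write_truth_json(sess.truth, out / f"{sid}.truth.json")
        paths.append(p)
    return paths


def read_dataset(in_dir: str | Path) -> list[SessionData]:
    in_dir = Path(in_dir)
    paths = sorted(
        p
        for p in in_dir.glob("*.csv")
        if not p.name.endswith((".truth.csv", ".bg.csv", ".res.csv"))
    )
    if not paths:
        raise SessionIOError(f"no session CSV files in {in_dir}")
    sessions = []
    for p in paths:
        sess = read_session_csv(p)
        truth_path = p.with_name(p.stem + ".truth.json")
        if truth_path.exists():
            sess = replace(sess, truth=read_truth_json(truth_path))
        sessions.append(sess)
    return sessions
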