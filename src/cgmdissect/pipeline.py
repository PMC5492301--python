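"""End-to-end orchestration of the sensor-error modelling pipeline.

Stages, in order: session QC -> reference smoothing -> calibration fits over
the (m, l) order grid -> residual whitening and BIC -> Delta-BIC ranking and
order selection -> noise decomposition -> AR order selection and validation
-> population AR fits -> MARD dissection -> report tables.  Every random
draw flows from the single run seed through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .calibration import FitSpec, compute_residuals, fit_session, precision_summary
from .dissect import DEFAULT_BANDS, dissect_error, rate_of_change_stats, stratify_by_range
from .noise import decompose_noise, fit_population_ar, select_ar_order, validate_ar, variance_summary
from .preprocess import QCConfig, SmootherConfig, qc_sessions, smooth_reference
from .selection import BICRecord, bic_records_frame, compute_bic, rank_models, whiten_residuals
from .synthetic import PopulationConfig, SessionConfig, generate_dataset


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and session."""


def substream_seed(master_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage substream seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}/{stage}/{item}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulate: bool = True
    n_sessions: int = 40
    input_dir: str | None = None
    out_dir: str = "cgmdissect_run"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    smoother: SmootherConfig | None = None  # None: derive ref SD from the generator
    orders: tuple[tuple[int, int], ...] = tuple(product(range(4), range(4)))
    k_max: int = 15
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def resolved_smoother(self) -> SmootherConfig:
        if self.smoother is not None:
            return self.smoother
        if self.simulate:
            # assume the generative reference error (gold standard when 0)
            return SmootherConfig(ref_sd_frac=self.session.ref_noise_sd_frac)
        return SmootherConfig()


@dataclass
class RunResult:
    config: RunConfig
    qc_report: pd.DataFrame
    fits: dict[tuple[int, int], list]
    bic_records: pd.DataFrame
    ranking: pd.DataFrame
    selected_order: tuple[int, int]
    precision: pd.DataFrame
    variance: pd.DataFrame
    cc_order: int
    ssc_order: int
    population_cc: object
    population_ssc: object
    ad_pass_cc: float
    ad_pass_ssc: float
    dissection: pd.DataFrame
    stratified: pd.DataFrame
    rates: pd.DataFrame
    manifest: dict


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> RunResult:
    t_start = time.time()
    # ---- inputs
    if config.simulate:
        sessions = generate_dataset(
            config.population,
            config.n_sessions,
            substream_seed(config.seed, "simulate"),
            config.session,
        )
    else:
        if not config.input_dir:
            raise PipelineError("stage=input: no input directory and simulate=False")
        sessions = sio.read_dataset(config.input_dir)
    if not sessions:
        raise PipelineError("stage=input: no sessions")

    # ---- QC
    kept, report = qc_sessions(sessions, config.qc)
    if not kept:
        raise PipelineError("stage=qc: no sessions survived quality control")

    # ---- smoothing
    smoother = config.resolved_smoother()
    bg_profiles = {}
    for sess in kept:
        try:
            bg_profiles[sess.session_id] = smooth_reference(sess.reference, smoother)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=smooth session={sess.session_id}: {exc}") from exc

    # ---- calibration fit grid
    fits: dict[tuple[int, int], list] = {}
    for (m, l) in config.orders:
        spec = FitSpec(m=m, l=l)
        fits[(m, l)] = []
        for sess in kept:
            try:
                fits[(m, l)].append(fit_session(sess, bg_profiles[sess.session_id], spec))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(
                    f"stage=fit order=({m},{l}) session={sess.session_id}: {exc}"
                ) from exc

    # ---- whitened BIC records (one noise-only whitening filter per sensor,
    # fitted on the richest candidate's residuals)
    richest = max(config.orders, key=lambda o: o[0] + o[1])
    filter_res = {
        sess.session_id: compute_residuals(
            sess, bg_profiles[sess.session_id], fit
        )
        for sess, fit in zip(kept, fits[richest])
    }
    records: list[BICRecord] = []
    for (m, l), fit_list in fits.items():
        for sess, fit in zip(kept, fit_list):
            res = compute_residuals(sess, bg_profiles[sess.session_id], fit)
            white = whiten_residuals(
                res, config.k_max, filter_source=filter_res[sess.session_id]
            )
            for i, eta in enumerate(white.eta):
                d = fit.n_obs[i]
                p = m + l + 3
                records.append(
                    BICRecord(sess.session_id, i, m, l, d, compute_bic(eta, d, p))
                )
    bic_df = bic_records_frame(records)

    # ---- ranking / selection
    ranking, selected = rank_models(bic_df)
    sel_fits = fits[selected]

    # ---- decomposition and AR modelling at the selected order
    decomps = []
    for sess, fit in zip(kept, sel_fits):
        res = compute_residuals(sess, bg_profiles[sess.session_id], fit)
        clean = [r[~np.isnan(r)] for r in res.res]
        decomps.append(decompose_noise(clean, sess.session_id))
    cc_list = [d.cc for d in decomps]
    ssc_list = [s for d in decomps for s in d.ssc]
    cc_sel = select_ar_order(cc_list, config.k_max)
    ssc_sel = select_ar_order(ssc_list, config.k_max)
    pop_cc = fit_population_ar(cc_list, cc_sel.modal_order)
    pop_ssc = fit_population_ar(ssc_list, ssc_sel.modal_order)
    from .noise import fit_ar  # per-series validation models

    def _ad_pass_rate(series_list, order):
        passed = 0
        for x in series_list:
            model = fit_ar(x, order)
            passed += validate_ar(model, x).passed
        return 100.0 * passed / len(series_list)

    ad_cc = _ad_pass_rate(cc_list, cc_sel.modal_order)
    ad_ssc = _ad_pass_rate(ssc_list, ssc_sel.modal_order)

    # ---- summaries
    precision = precision_summary(sel_fits)
    variance = variance_summary(decomps)
    dissection = pd.concat(
        [
            dissect_error(sess, bg_profiles[sess.session_id], fit)
            for sess, fit in zip(kept, sel_fits)
        ],
        ignore_index=True,
    )
    ref_pool, cgm_pool = [], []
    for sess in kept:
        bg = bg_profiles[sess.session_id]
        for trace in sess.cgm:
            from .preprocess import align_to_cgm

            pairs = align_to_cgm(bg, trace)
            ok = ~np.isnan(pairs.cgm)
            ref_pool.append(pairs.bg[ok])
            cgm_pool.append(pairs.cgm[ok])
    stratified = stratify_by_range(
        np.concatenate(ref_pool), np.concatenate(cgm_pool), config.bands
    )
    rate_edges = np.arange(-4.0, 4.0 + 0.5, 0.5)
    rate_tables = [
        rate_of_change_stats(bg_profiles[s.session_id], rate_edges) for s in kept
    ]
    rates = rate_tables[0][["bin_lo", "bin_hi"]].copy()
    counts = np.sum([t["count"].to_numpy() for t in rate_tables], axis=0)
    rates["count"] = counts
    rates["fraction"] = counts / counts.sum()

    manifest = {
        "seed": config.seed,
        "n_sessions_in": len(sessions),
        "n_sessions_kept": len(kept),
        "selected_order": list(selected),
        "cc_order": cc_sel.modal_order,
        "ssc_order": ssc_sel.modal_order,
        "elapsed_s": round(time.time() - t_start, 2),
    }

    result = RunResult(
        config=config,
        qc_report=report.table,
        fits=fits,
        bic_records=bic_df,
        ranking=ranking,
        selected_order=selected,
        precision=precision,
        variance=variance,
        cc_order=cc_sel.modal_order,
        ssc_order=ssc_sel.modal_order,
        population_cc=pop_cc,
        population_ssc=pop_ssc,
        ad_pass_cc=ad_cc,
        ad_pass_ssc=ad_ssc,
        dissection=dissection,
        stratified=stratified,
        rates=rates,
        manifest=manifest,
    )
    if write_outputs:
        _write_outputs(result)
    return result


def _write_outputs(result: RunResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_csv(out / "qc_report.csv", index=False)
    result.bic_records.to_csv(out / "bic_records.csv", index=False)
    result.ranking.to_csv(out / "ranking.csv", index=False)
    result.precision.to_csv(out / "precision_table.csv", index=False)
    result.variance.to_csv(out / "variance_table.csv", index=False)
    result.dissection.to_csv(out / "dissection_table.csv", index=False)
    result.stratified.to_csv(out / "stratified_table.csv", index=False)
    result.rates.to_csv(out / "rate_histogram.csv", index=False)
    rows = []
    for (m, l), fit_list in result.fits.items():
        for f in fit_list:
            row = {"session_id": f.session_id, "m": m, "l": l, "tau_hat": f.tau_hat,
                   "converged": f.converged, "tau_at_bound": f.tau_at_bound, "cost": f.cost}
            for i, (g, b) in enumerate(zip(f.gain_hat, f.offset_hat), start=1):
                for k, v in enumerate(g):
                    row[f"a{k}_s{i}"] = v
                for k, v in enumerate(b):
                    row[f"b{k}_s{i}"] = v
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)
    manifest = dict(result.manifest)
    manifest["population_cc"] = {
        "coeffs": list(np.asarray(result.population_cc.coeffs)),
        "innovation_var": result.population_cc.innovation_var,
    }
    manifest["population_ssc"] = {
        "coeffs": list(np.asarray(result.population_ssc.coeffs)),
        "innovation_var": result.population_ssc.innovation_var,
    }
    manifest["ad_pass_cc_pct"] = result.ad_pass_cc
    manifest["ad_pass_ssc_pct"] = result.ad_pass_ssc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
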