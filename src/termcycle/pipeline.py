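"""Cohort-level orchestration of the trace and genomic analyses.

These helpers string the per-module operations into the runs the
analysis scripts and CLI execute: calibrate every trace in a cohort,
classify post-termination behavior, collect departure records and
lifetimes, and run the terminator/antisense battery on simulated end
tracks.  Everything is deterministic given the seeds carried in the
configs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, kinetics, motion
from .calibration import (
    CalibrationFit,
    IntensityTrace,
    TerminationEvent,
    compute_elongation_rate,
    fit_elongation_decay,
    intensity_to_position,
)
from .rendseq import (
    control_replicates,
    distance_profile,
    filter_terminators,
    terminator_peak_table,
)
from .simulate import (
    GroundTruth,
    RendSimConfig,
    TraceSimConfig,
    simulate_cohort,
    simulate_rendseq,
)

__all__ = [
    "detect_probe_interval",
    "termination_event",
    "analyze_trace",
    "analyze_cohort",
    "departure_records",
    "spot_lifetimes",
    "rendseq_analysis",
    "run_pipeline",
]


def detect_probe_interval(trace: IntensityTrace) -> tuple[float, float]:
    """Probe appearance and departure times (change-point heuristic).

    Uses the probe-present flags when the trace carries them, otherwise
    thresholds the probe channel halfway between its 10th and 90th
    percentiles.  Returns (t_appear, t_depart).
    """
    if trace.probe_present is not None:
        on = trace.probe_present
    else:
        lo, hi = np.percentile(trace.I_probe, [10, 90])
        on = trace.I_probe > (lo + hi) / 2.0
    idx = np.nonzero(on)[0]
    if idx.size == 0:
        raise ValueError("no probe signal detected")
    return float(trace.time[idx[0]]), float(trace.time[idx[-1]])


def termination_event(
    trace: IntensityTrace, fit: CalibrationFit, t_T: float
) -> TerminationEvent:
    """Build the termination record, with I_T from the fitted curve.

    Evaluating the calibration at t_T rather than reading the single
    noisy frame keeps the downstream algebra (z(t_T) = z_T) exact.
    RNAP departure is the first frame after t_T where the spot is gone;
    censored (None) when the spot survives to the end of the record.
    """
    I_T = float(fit.intensity_at(t_T - fit.window[0]))
    departure: float | None = None
    if trace.rnap_present is not None:
        gone = np.nonzero((trace.time > t_T) & ~trace.rnap_present)[0]
        if gone.size:
            departure = float(trace.time[gone[0]])
    return TerminationEvent(t_T=t_T, I_T=I_T, rnap_departure_time=departure)


def analyze_trace(
    trace: IntensityTrace,
    z_P: float,
    z_T: float,
    template_length: float,
    truth: GroundTruth | None = None,
    orientation: str = "up",
    window_s: float = 50.0,
) -> dict:
    """Full single-trace analysis: calibration, diffusion, behavior.

    When ``truth`` is given its elongation window (t_start, t_T) is
    used; otherwise the probe-interval heuristic supplies it.  Returns
    a flat dict of per-molecule results (NaN where a stage could not
    run, e.g. no post-termination frames).
    """
    if truth is not None:
        window = (truth.t_start, truth.t_T)
        t_T = truth.t_T
    else:
        t0, t1 = detect_probe_interval(trace)
        window, t_T = (t0, t1), t1
    try:
        fit = fit_elongation_decay(trace, window, orientation=orientation)
    except ValueError:
        # molecule lost (bleach/dissociation) before elongation finished
        return {
            "trace_id": trace.trace_id,
            "lambda_hat": math.nan,
            "I_P_hat": math.nan,
            "I_mn_hat": math.nan,
            "resid_sd": math.nan,
            "converged": False,
            "t_T": t_T,
            "retained": False,
            "r_hat": math.nan,
            "max_D": math.nan,
            "n_windows": 0,
            "slid": False,
            "antisense": False,
            "sense_reinit": False,
            "secondary_rate": math.nan,
        }
    term = termination_event(trace, fit, t_T)
    row: dict = {
        "trace_id": trace.trace_id,
        "lambda_hat": fit.lam,
        "I_P_hat": fit.I_P,
        "I_mn_hat": fit.I_mn,
        "resid_sd": fit.resid_sd,
        "converged": fit.converged,
        "t_T": t_T,
        "retained": term.rnap_departure_time is None
        or term.rnap_departure_time - t_T > kinetics.SIMULTANEITY_THRESHOLD,
        "r_hat": math.nan,
        "max_D": math.nan,
        "n_windows": 0,
        "slid": False,
        "antisense": False,
        "sense_reinit": False,
        "secondary_rate": math.nan,
    }
    if not fit.converged:
        return row
    r_hat = compute_elongation_rate(fit, term, z_P, z_T)
    row["r_hat"] = r_hat
    if not math.isfinite(r_hat):
        return row

    post = trace.time > t_T
    if trace.rnap_present is not None:
        post &= trace.rnap_present
    if term.rnap_departure_time is not None:
        post &= trace.time < term.rnap_departure_time
    if np.count_nonzero(post) >= 2:
        pos = intensity_to_position(
            fit,
            r_hat,
            trace.time[post],
            trace.I_rnap[post],
            z_P,
            z_T=z_T,
            template_length=template_length,
        )
        z = np.where(pos.valid, pos.z, np.nan)
        windows = motion.window_diffusion(pos.time, z, window=window_s)
        if windows:
            row["n_windows"] = len(windows)
            row["max_D"] = max(w.D for w in windows)
            row["slid"] = motion.classify_sliding(windows)
        call = motion.classify_secondary_initiation(
            trace, fit, term, orientation=orientation
        )
        row["antisense"] = call.antisense
        row["sense_reinit"] = call.sense_reinit
        row["secondary_rate"] = call.rate
    return row


def analyze_cohort(
    traces: list[IntensityTrace],
    truths: list[GroundTruth] | None,
    config: TraceSimConfig,
) -> pd.DataFrame:
    """Per-molecule analysis table over a cohort."""
    rows = []
    for i, trace in enumerate(traces):
        truth = truths[i] if truths is not None else None
        rows.append(
            analyze_trace(
                trace,
                z_P=config.z_P,
                z_T=config.z_T,
                template_length=config.template_length,
                truth=truth,
                orientation=config.tether_orientation,
            )
        )
    return pd.DataFrame(rows)


def departure_records(
    traces: list[IntensityTrace], truths: list[GroundTruth] | None = None
) -> list[kinetics.DepartureRecord]:
    """Probe vs RNAP departure times for every terminating molecule."""
    records = []
    for i, trace in enumerate(traces):
        try:
            _, probe_dep = detect_probe_interval(trace)
        except ValueError:
            continue
        departure: float | None = None
        if trace.rnap_present is not None:
            gone = np.nonzero(~trace.rnap_present)[0]
            if gone.size:
                departure = float(trace.time[gone[0]])
        records.append(
            kinetics.DepartureRecord(
                probe_departure=probe_dep, rnap_departure=departure
            )
        )
    return records


def spot_lifetimes(
    traces: list[IntensityTrace],
) -> tuple[np.ndarray, np.ndarray]:
    """Post-termination RNAP spot lifetimes with acquisition censoring.

    The observed lifetime runs from probe departure (termination) to
    RNAP spot disappearance; spots still present at the final frame
    are right-censored at the record end.  Molecules that departed
    with (or before) the probe contribute nothing.
    """
    durations, censored = [], []
    for trace in traces:
        try:
            _, probe_dep = detect_probe_interval(trace)
        except ValueError:
            continue
        if trace.rnap_present is None:
            continue
        gone = np.nonzero((trace.time > probe_dep) & ~trace.rnap_present)[0]
        if gone.size:
            dur = float(trace.time[gone[0]]) - probe_dep
            if dur > kinetics.SIMULTANEITY_THRESHOLD:
                durations.append(dur)
                censored.append(False)
        else:
            dur = float(trace.time[-1]) - probe_dep
            if dur > 0:
                durations.append(dur)
                censored.append(True)
    return np.asarray(durations), np.asarray(censored)


def rendseq_analysis(
    config: RendSimConfig,
    genes: pd.DataFrame,
    n_control_replicates: int = 100,
    bin_width: int = 200,
    max_distance: int = 2000,
    seed: int = 0,
) -> dict:
    """Simulate end tracks and run the full terminator/antisense battery.

    Returns a dict with the tracks, truth table, filtered terminator
    set, per-terminator peak table, distance profile, control-replicate
    fractions and the empirical p-value for terminator-proximal
    antisense enrichment.
    """
    tracks, truth = simulate_rendseq(config)
    term_df = pd.DataFrame(config.terminators, columns=["position", "strand"])
    term_set = filter_terminators(term_df, genes)
    peaks = terminator_peak_table(tracks, term_set)
    profile = distance_profile(
        tracks, term_set, bin_width=bin_width, max_distance=max_distance
    )
    center = profile.loc[profile["distance"] == 0]
    observed = float(center["fraction"].iloc[0]) if len(center) else math.nan
    n_eligible = int(term_set["eligible"].sum())
    controls = control_replicates(
        tracks,
        genes,
        term_df,
        n_locations=n_eligible,
        n_replicates=n_control_replicates,
        bin_width=bin_width,
        seed=seed,
    )
    n_ge = int(np.count_nonzero(controls["fraction"] >= observed))
    p_emp = n_ge / len(controls)
    return {
        "tracks": tracks,
        "truth": truth,
        "terminators": term_set,
        "peak_table": peaks,
        "distance_profile": profile,
        "controls": controls,
        "terminator_fraction": observed,
        "empirical_p": p_emp,
    }


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_molecules: int = 50,
    trace_config: TraceSimConfig | None = None,
    rend_config: RendSimConfig | None = None,
    genes: pd.DataFrame | None = None,
    n_control_replicates: int = 20,
) -> dict:
    """End-to-end demo run on synthetic data; writes tables + manifest.

    Stages: simulate a trace cohort, calibrate and classify it, fit the
    censored lifetime, simulate end tracks and run the terminator
    battery.  Deterministic given ``seed``; a manifest records
    versions, seeds and parameters.  Any stage failure propagates with
    the stage name prepended.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if trace_config is None:
        trace_config = TraceSimConfig(seed=seed)
    else:
        trace_config = dataclasses.replace(trace_config, seed=seed)
    if rend_config is None or genes is None:
        from .simulate import synthetic_genome_annotation

        genes, term_df, G = synthetic_genome_annotation(n_blocks=40, seed=seed)
        rend_config = RendSimConfig(
            genome_length=G,
            genes=list(genes[["start", "end", "strand"]].itertuples(index=False)),
            terminators=list(term_df[["position", "strand"]].itertuples(index=False)),
            seed=seed,
        )

    params = {
        "seed": seed,
        "n_molecules": n_molecules,
        "trace_config": dataclasses.asdict(trace_config),
        "rend_config": {
            k: v
            for k, v in dataclasses.asdict(rend_config).items()
            if k not in ("genes", "terminators")
        },
    }
    chash = io.config_hash(params)
    meta = {"config_hash": chash, "seed": seed}
    report: dict = {"config_hash": chash, "seed": seed}

    stage = "simulate-traces"
    try:
        traces, truths = simulate_cohort(trace_config, n_molecules, seed=seed)
        io.write_traces(traces, outdir / "traces.tsv", meta)
        io.write_ground_truth(truths, outdir / "traces_truth.tsv", meta)

        stage = "calibrate/motion"
        table = analyze_cohort(traces, truths, trace_config)
        io.write_table(table, outdir / "behavior_calls.tsv", meta)
        retained = table[table["retained"]]
        report["n_molecules"] = n_molecules
        report["n_retained"] = int(len(retained))
        report["fraction_slid"] = (
            float(retained["slid"].mean()) if len(retained) else math.nan
        )
        report["fraction_antisense"] = (
            float(retained["antisense"].mean()) if len(retained) else math.nan
        )

        stage = "kinetics"
        durations, censored = spot_lifetimes(traces)
        if durations.size and np.any(~censored):
            est = kinetics.correct_photobleaching(
                durations, censored, k_PB=trace_config.k_PB, seed=seed
            )
            report["lifetime_s"] = est.lifetime
            report["lifetime_se_s"] = est.lifetime_se
        recs = departure_records(traces)
        if recs:
            fracs = kinetics.classify_departures(recs)
            report["departure_fractions"] = {
                k: v[0] for k, v in fracs.items()
            }

        stage = "rendseq"
        rend = rendseq_analysis(
            rend_config,
            genes,
            n_control_replicates=n_control_replicates,
            seed=seed,
        )
        io.write_end_tracks(rend["tracks"], outdir / "tracks")
        io.write_table(rend["peak_table"], outdir / "terminator_peaks.tsv", meta)
        io.write_table(rend["distance_profile"], outdir / "distance_profile.tsv", meta)
        io.write_table(rend["controls"], outdir / "control_replicates.tsv", meta)
        report["terminator_fraction"] = rend["terminator_fraction"]
        report["control_p"] = rend["empirical_p"]
    except Exception as exc:  # noqa: BLE001 - annotate stage, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "termcycle_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "params": params,
        "config_hash": chash,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
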