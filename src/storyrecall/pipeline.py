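"""End-to-end pipeline runner over synthetic (or previously written) inputs.

Stage order mirrors the analysis: simulate -> behavior -> preprocess+gc ->
timecourse -> connectivity.  Each stage writes its artifacts into the output
directory and contributes to a machine-readable JSON summary that also
records package versions, the config, its hash, and every seed.  A stage
failure aborts with the stage name; artifacts written so far are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import (agreement, boundary_peaks_from_agreement, code_response_vector,
                       consensus_learning_test, crosscorr_lag, participant_contrast,
                       run_label_perm_lag, word_learning_contrast)
from .connectivity import boundary_map, cluster_perm_maps, lagged_profile, peak_locked_mi
from .granger import (cross_run_gc, effect_size_patientwise, select_cpr_channels,
                      sign_flip_test)
from .io_formats import (PipelineConfig, read_press_logs, read_recording, read_truth,
                         read_word_table, write_agreement, write_mi_map,
                         write_press_logs, write_recording, write_summary,
                         write_truth, write_word_table)
from .preprocess import band_amplitude, clean_and_align
from .synth import (SimulationTruth, gen_segmentation_logs, gen_two_run_recording,
                    gen_word_table)
from .timecourse import boundary_locked, detect_peaks, recall_timecourse, word_correlation

__all__ = ["run_pipeline", "ALL_STAGES"]

log = logging.getLogger("storyrecall")

ALL_STAGES = ("simulate", "behavior", "gc", "timecourse", "connectivity")

# feasible target-feature bands at the 100 Hz analysis rate
_TARGET_BANDS = [(0.0, 4.0), (4.0, 8.0), (8.0, 15.0), (15.0, 30.0)]


def _target_features(x: np.ndarray, fs: float) -> np.ndarray:
    """Per-channel feature stack for synthetic 100 Hz amplitude data: the raw
    series plus the band amplitudes feasible below the Nyquist rate."""
    rows = [x]
    rows += [band_amplitude(x, fs, band) for band in _TARGET_BANDS]
    return np.vstack(rows)


def _truth_from_config(cfg: PipelineConfig) -> SimulationTruth:
    shifts = np.zeros(cfg.n_channels)
    effect = np.arange(cfg.n_effect_channels)
    shifts[effect] = cfg.anticipation_shift_ms
    dur_ms = cfg.neural_duration_s * 1000.0
    bounds = np.linspace(0.12, 0.92, cfg.n_boundaries) * dur_ms
    margin = 2000.0 + abs(cfg.coupling_lag_ms)
    windows = [(max(b - 1000.0, margin), min(b + 1000.0, dur_ms - margin)) for b in bounds]
    return SimulationTruth(
        anticipation_shift_ms=shifts,
        effect_channels=effect,
        boundary_times_ms=bounds,
        coupling_lag_ms=cfg.coupling_lag_ms,
        coupling_windows=windows,
        word_learning_delta=cfg.word_delta,
        seed=cfg.seed,
    )


def run_pipeline(config: PipelineConfig, out_dir, stages=ALL_STAGES) -> dict:
    """Execute the requested stages and return (and write) the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "version": __version__,
        "seed": config.seed,
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s starting (seed=%d)", stage, config.seed)
        try:
            _STAGE_FNS[stage](config, out, state, summary)
        except Exception as err:
            write_summary(summary, out / "summary.json")
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    write_summary(summary, out / "summary.json")
    return summary


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    truth = _truth_from_config(cfg)
    dur_ms = cfg.story_duration_s * 1000.0
    b_frac = np.linspace(0.12, 0.92, cfg.n_boundaries) * dur_ms
    logs1, logs2 = gen_segmentation_logs(
        cfg.n_participants, b_frac, dur_ms, advance_ms=cfg.behavioral_advance_ms,
        response_jitter_sd=cfg.response_jitter_sd_ms, hit_prob=cfg.hit_prob,
        false_press_rate=cfg.false_press_rate_per_min, seed=cfg.seed,
        response_jitter_sd_run2=cfg.response_jitter_sd_run2_ms,
    )
    # per-word learning varies substantially across words; naive
    # predictability is skewed toward low values
    words, correct = gen_word_table(
        cfg.n_words,
        base_prob_fn=lambda rng, n: rng.beta(2.0, 6.0, n),
        delta_fn=lambda rng, n: rng.normal(cfg.word_delta, 0.15, n),
        seed=cfg.seed + 1,
    )
    run1, run2, env, truth = gen_two_run_recording(
        cfg.n_channels, cfg.n_hippo, cfg.neural_duration_s, truth, snr=cfg.snr,
    )
    write_press_logs(logs1 + logs2, out / "press_logs.csv")
    write_word_table(words, out / "word_table.tsv")
    np.savetxt(out / "correct_naive.csv", correct["naive"], fmt="%d", delimiter=",")
    np.savetxt(out / "correct_exposed.csv", correct["exposed"], fmt="%d", delimiter=",")
    write_recording(run1, run2, env, out / "recording.h5")
    write_truth(truth, out / "truth.json")
    state.update(logs1=logs1, logs2=logs2, words=words, correct=correct,
                 run1=run1, run2=run2, env=env, truth=truth)
    summary["simulate"] = {
        "n_participants": cfg.n_participants,
        "n_words": cfg.n_words,
        "n_channels": cfg.n_channels + cfg.n_hippo,
        "boundaries_ms": truth.boundary_times_ms,
    }


def _load_inputs(cfg: PipelineConfig, out: Path, state: dict) -> None:
    if "logs1" not in state:
        logs = read_press_logs(out / "press_logs.csv")
        state["logs1"] = [lg for lg in logs if lg.run == 1]
        state["logs2"] = [lg for lg in logs if lg.run == 2]
        state["words"] = read_word_table(out / "word_table.tsv")
        state["correct"] = {
            "naive": np.loadtxt(out / "correct_naive.csv", delimiter=",", ndmin=2),
            "exposed": np.loadtxt(out / "correct_exposed.csv", delimiter=",", ndmin=2),
        }
        state["run1"], state["run2"], state["env"] = read_recording(out / "recording.h5")
        state["truth"] = read_truth(out / "truth.json")


def _stage_behavior(cfg: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    _load_inputs(cfg, out, state)
    logs1, logs2 = state["logs1"], state["logs2"]
    tc1 = agreement(np.stack([code_response_vector(lg) for lg in logs1]), run=1)
    tc2 = agreement(np.stack([code_response_vector(lg) for lg in logs2]), run=2)
    write_agreement(tc1, out / "agreement_run1.csv")
    write_agreement(tc2, out / "agreement_run2.csv")
    consensus = consensus_learning_test(logs1, logs2, n_perm=cfg.n_perm, seed=cfg.seed + 2)
    xcorr = crosscorr_lag(tc2, tc1, max_lag_ms=500)
    perm_lag = run_label_perm_lag(logs1, logs2, max_lag_ms=500,
                                  n_perm=cfg.n_perm, seed=cfg.seed + 3)
    boundaries = boundary_peaks_from_agreement(tc2)
    state["boundaries_ms"] = boundaries
    words = state["words"]
    word_stats = word_learning_contrast(words)
    part_stats = participant_contrast(state["correct"]["exposed"].sum(axis=1),
                                      state["correct"]["naive"].sum(axis=1))
    summary["behavior"] = {
        "consensus_mean_run1": float(np.mean(consensus["cos_run1"])),
        "consensus_mean_run2": float(np.mean(consensus["cos_run2"])),
        "consensus_mean_diff": consensus["mean_diff"],
        "consensus_p_perm": consensus["p_perm"],
        "n_improved": consensus["n_improved"],
        "p_binomial": consensus["p_binomial"],
        "crosscorr_lag_ms": xcorr["lag_ms"],
        "crosscorr_r_max": xcorr["r_max"],
        "lag_p_perm": perm_lag["p"],
        "n_boundaries_detected": int(boundaries.size),
        "word_t": word_stats["t"], "word_df": word_stats["df"], "word_d": word_stats["d"],
        "participant_t": part_stats["t"], "participant_df": part_stats["df"],
        "participant_d": part_stats["d"],
    }


def _stage_gc(cfg: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    _load_inputs(cfg, out, state)
    run1, run2, env = clean_and_align(state["run1"], state["run2"], state["env"])
    state["run1c"], state["run2c"], state["envc"] = run1, run2, env
    cortical = [i for i, lab in enumerate(run1.channel_labels) if not lab.startswith("hippo")]
    table, results = cross_run_gc(run1, run2, env, p_max=cfg.p_max,
                                  order=cfg.gc_order, channels=cortical)
    # pseudo-patients: contiguous blocks of 8 channels stand in for subjects
    patients = np.array([f"pt{i // 8}" for i in range(len(cortical))])
    table["patient"] = patients
    flip_ch = sign_flip_test(table["delta_F"].to_numpy(), n_perm=cfg.n_perm,
                             seed=cfg.seed + 4)
    flip_pt = sign_flip_test(table["delta_F"].to_numpy(), groups=patients,
                             n_perm=cfg.n_perm, seed=cfg.seed + 5)
    sel = select_cpr_channels(table["delta_F"].to_numpy(),
                              posterior_ratio=cfg.posterior_ratio, seed=cfg.seed + 6)
    table["selected"] = np.isin(np.arange(len(table)), sel["selected"])
    table.to_csv(out / "gc_results.tsv", sep="\t", index=False)
    state["gc_table"], state["gc_results"] = table, results
    state["cpr_channels"] = sel["selected"]
    state["cortical"] = cortical
    summary["gc"] = {
        "order": int(table["order"].iloc[0]),
        "delta_F_mean": float(table["delta_F"].mean()),
        "p_sign_flip_channels": flip_ch["p"],
        "p_sign_flip_patients": flip_pt["p"],
        "n_cpr_channels": int(len(sel["selected"])),
        "effect_size_d": effect_size_patientwise(table["delta_F"].to_numpy(), patients),
    }


def _stage_timecourse(cfg: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    if "gc_results" not in state:
        _stage_gc(cfg, out, state, summary)
    run1, run2 = state["run1c"], state["run2c"]
    cpr = state["cpr_channels"]
    if cpr.size == 0:  # fall back to the strongest channels
        cpr = np.argsort(state["gc_table"]["delta_F"].to_numpy())[-4:]
    tc = recall_timecourse(run1, run2, state["gc_results"], cpr)
    state["recall_tc"] = tc
    np.savetxt(out / "recall_timecourse.csv",
               np.column_stack([np.arange(tc.values.size) + tc.start_sample,
                                tc.values]),
               delimiter=",", header="sample,value", comments="# ")
    peaks = detect_peaks(tc.values, tc.fs, percentile=cfg.peak_percentile)
    state["recall_peaks"] = peaks
    truth = state["truth"]
    b_samples = np.round(truth.boundary_times_ms * tc.fs / 1000.0).astype(int) - tc.start_sample
    w = int(5 * tc.fs)
    b_valid = b_samples[(b_samples + int(-w) >= 0) & (b_samples + w <= tc.values.size)]
    locked = boundary_locked(tc.values, tc.fs, b_valid, n_perm=cfg.n_perm,
                             seed=cfg.seed + 7, q=cfg.q_fdr)
    wcorr = word_correlation(tc.values, tc.fs, state["words"],
                             n_perm=cfg.n_perm, seed=cfg.seed + 8, q=cfg.q_fdr,
                             tc_offset_ms=tc.start_sample / tc.fs * 1000.0)
    summary["timecourse"] = {
        "n_peaks": int(peaks.times.size),
        "boundary_locked_peak_s": locked["peak_s"],
        "boundary_locked_p_fdr": locked["p_fdr"],
        "boundary_locked_n_sig": int(locked["mask"].sum()),
        "word_corr_peak_lag_s": wcorr.get("peak_lag_s"),
        "word_corr_r_peak": wcorr.get("r_peak"),
        "word_corr_n_sig": int(np.sum(wcorr["mask"])) if not wcorr.get("degenerate") else 0,
    }


def _stage_connectivity(cfg: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    if "recall_tc" not in state:
        _stage_timecourse(cfg, out, state, summary)
    run1, run2 = state["run1c"], state["run2c"]
    fs = run1.fs
    truth = state["truth"]
    cpr = state["cpr_channels"]
    hippo_idx = [i for i, lab in enumerate(run1.channel_labels) if lab.startswith("hippo")]
    other_idx = [i for i in state["cortical"] if i not in set(cpr.tolist())][: max(4, len(hippo_idx))]
    lag_step = int(round(cfg.lag_step_ms * fs / 1000.0))
    lag_max = int(round(cfg.lag_range_ms * fs / 1000.0))
    lag_grid = np.arange(-lag_max, lag_max + 1, lag_step)
    cpr_by_run = {1: run1.data[cpr], 2: run2.data[cpr]}
    feats = {
        (r, i): _target_features(data.data[i], fs)
        for r, data in ((1, run1), (2, run2)) for i in hippo_idx + other_idx
    }
    b_samples = np.round(truth.boundary_times_ms * fs / 1000.0).astype(int)
    dist_step = max(int(round(0.5 * fs)), 1)
    dist_grid = np.arange(int(-3 * fs), int(1 * fs) + 1, dist_step)
    maps = {}
    for run_id, cpr_dat in cpr_by_run.items():
        for group, idxs in (("hippocampus", hippo_idx), ("control", other_idx)):
            maps[(run_id, group)] = np.stack([
                boundary_map(cpr_dat, feats[(run_id, i)], b_samples, fs,
                             dist_grid, lag_grid, roi=group, run=run_id).mi
                for i in idxs
            ])
    plaus = (np.abs(lag_grid)[:, None] <= int(1 * fs)) & \
        ((dist_grid[None, :] >= -2 * fs) & (dist_grid[None, :] <= 0.5 * fs))
    cluster = {}
    for run_id in (1, 2):
        cs = cluster_perm_maps(maps[(run_id, "hippocampus")], maps[(run_id, "control")],
                               n_perm=cfg.n_perm, seed=cfg.seed + 9 + run_id,
                               plausible_mask=plaus)
        cluster[run_id] = cs
        from .connectivity import MIMap
        write_mi_map(MIMap(maps[(run_id, "hippocampus")].mean(axis=0), lag_grid,
                           dist_grid, fs, roi="hippocampus", run=run_id),
                     out / f"mi_map_hippo_run{run_id}.tsv")
    tc = state["recall_tc"]
    peak = peak_locked_mi(
        cpr_by_run,
        {r: [feats[(r, i)] for i in hippo_idx] for r in (1, 2)},
        {r: [feats[(r, i)] for i in other_idx] for r in (1, 2)},
        tc.values, tc.fs, tc.start_sample, lag_grid, fs,
        n_perm=cfg.n_perm_peak, seed=cfg.seed + 12, q=cfg.q_fdr,
    )
    cluster_json = {
        str(r): {"max_sum": cluster[r].max_sum, "p": cluster[r].p_perm,
                 "n_clusters": len(cluster[r].clusters),
                 "t_threshold": cluster[r].t_threshold}
        for r in cluster
    }
    (out / "cluster_stats.json").write_text(json.dumps(cluster_json, indent=2))
    run2_mi = peak["run2"]["mean"]
    summary["connectivity"] = {
        "cluster_p_run1": cluster[1].p_perm,
        "cluster_p_run2": cluster[2].p_perm,
        "peak_mi_lag_ms_run2": float(lag_grid[np.argmax(run2_mi)] / fs * 1000.0),
        "n_sig_lags_run2_vs_shuffled": int(peak["run2"]["mask_vs_shuffled"].sum()),
        "n_recall_peaks": int(peak["peaks"].times.size),
    }


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "gc": _stage_gc,
    "timecourse": _stage_timecourse,
    "connectivity": _stage_connectivity,
}
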