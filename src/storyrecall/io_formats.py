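"""Readers and writers for every pipeline artifact.

Tabular artifacts are plain text (CSV/TSV) with documented headers;
recordings go into a chunked HDF5 container with rate/label/run attributes
and a JSON ground-truth sidecar; summaries are JSON.  Every writer/reader
pair round-trips losslessly and readers validate the schema, naming the
offending field on failure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import AgreementTimecourse, PressLog, make_word_table
from .preprocess import AudioEnvelope, RecordingRun
from .synth import SimulationTruth

__all__ = [
    "PipelineConfig",
    "write_press_logs",
    "read_press_logs",
    "write_word_table",
    "read_word_table",
    "write_agreement",
    "read_agreement",
    "write_recording",
    "read_recording",
    "write_truth",
    "read_truth",
    "write_mi_map",
    "read_mi_map",
    "write_summary",
]

PRESS_COLUMNS = ["participant_id", "run", "press_time_ms", "story_duration_ms"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def write_press_logs(logs: list[PressLog], path) -> None:
    rows = [
        {"participant_id": lg.participant_id, "run": lg.run,
         "press_time_ms": t, "story_duration_ms": lg.story_duration}
        for lg in logs for t in lg.press_times
    ]
    # participants with zero presses still need a row to survive the round trip
    for lg in logs:
        if lg.press_times.size == 0:
            rows.append({"participant_id": lg.participant_id, "run": lg.run,
                         "press_time_ms": np.nan, "story_duration_ms": lg.story_duration})
    pd.DataFrame(rows, columns=PRESS_COLUMNS).to_csv(path, index=False)


def read_press_logs(path) -> list[PressLog]:
    df = pd.read_csv(path)
    _require(df, PRESS_COLUMNS, "press log CSV")
    logs = []
    for (pid, run), grp in df.groupby(["participant_id", "run"], sort=True):
        times = grp["press_time_ms"].dropna().to_numpy(dtype=float)
        logs.append(PressLog(str(pid), int(run), times,
                             int(grp["story_duration_ms"].iloc[0])))
    return logs


def write_word_table(table: pd.DataFrame, path) -> None:
    cols = ["token", "onset_ms", "offset_ms", "p_naive", "p_exposed"]
    table[cols].to_csv(path, sep="\t", index=False)


def read_word_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["token", "onset_ms", "offset_ms", "p_naive", "p_exposed"], "word table TSV")
    return make_word_table(df)


def write_agreement(tc: AgreementTimecourse, path) -> None:
    header = f"# run={tc.run} n_participants={tc.n_participants}\n"
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("agreement\n")
        np.savetxt(fh, tc.values, fmt="%.10g")


def read_agreement(path) -> AgreementTimecourse:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# run="):
            raise ValueError("agreement CSV: missing '# run=' metadata header")
        meta = dict(tok.split("=") for tok in header[2:].split())
        fh.readline()  # column name
        values = np.loadtxt(fh, ndmin=1)
    return AgreementTimecourse(values, int(meta["run"]), int(meta["n_participants"]))


def write_recording(run1: RecordingRun, run2: RecordingRun, envelope: AudioEnvelope,
                    path) -> None:
    with h5py.File(path, "w") as fh:
        for run in (run1, run2):
            ds = fh.create_dataset(f"run{run.run}", data=run.data, chunks=True)
            ds.attrs["fs"] = run.fs
            ds.attrs["run"] = run.run
            ds.attrs["channel_labels"] = [str(s) for s in run.channel_labels]
        env = fh.create_dataset("envelope", data=envelope.values, chunks=True)
        env.attrs["fs"] = envelope.fs
        env.attrs["band"] = list(envelope.band)


def read_recording(path) -> tuple[RecordingRun, RecordingRun, AudioEnvelope]:
    with h5py.File(path, "r") as fh:
        for name in ("run1", "run2", "envelope"):
            if name not in fh:
                raise ValueError(f"recording container: missing dataset '{name}'")
        runs = []
        for name in ("run1", "run2"):
            ds = fh[name]
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in ds.attrs["channel_labels"]]
            runs.append(RecordingRun(ds[...], float(ds.attrs["fs"]), labels,
                                     int(ds.attrs["run"])))
        env = fh["envelope"]
        envelope = AudioEnvelope(env[...], float(env.attrs["fs"]),
                                 tuple(env.attrs["band"]))
    return runs[0], runs[1], envelope


def write_truth(truth: SimulationTruth, path) -> None:
    d = asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    d["coupling_windows"] = [list(w) for w in truth.coupling_windows]
    d["coupling_runs"] = list(truth.coupling_runs)
    Path(path).write_text(json.dumps(d, indent=2))


def read_truth(path) -> SimulationTruth:
    d = json.loads(Path(path).read_text())
    try:
        return SimulationTruth(
            anticipation_shift_ms=np.asarray(d["anticipation_shift_ms"], dtype=float),
            effect_channels=np.asarray(d["effect_channels"], dtype=int),
            boundary_times_ms=np.asarray(d["boundary_times_ms"], dtype=float),
            coupling_lag_ms=float(d["coupling_lag_ms"]),
            coupling_windows=[tuple(w) for w in d["coupling_windows"]],
            word_learning_delta=d.get("word_learning_delta", 0.0),
            seed=int(d["seed"]),
            coupling_runs=tuple(d.get("coupling_runs", (1, 2))),
            coupling_strength=float(d.get("coupling_strength", 1.0)),
        )
    except KeyError as err:
        raise ValueError(f"truth JSON: missing field {err}") from err


def write_mi_map(mimap, path) -> None:
    from .connectivity import MIMap  # local import to avoid a cycle

    assert isinstance(mimap, MIMap)
    with open(path, "w") as fh:
        fh.write(f"# roi={mimap.roi or '-'} run={mimap.run} fs={mimap.fs} "
                 f"conditioning={mimap.conditioning}\n")
        fh.write("# rows: lag_samples; columns: distance_samples\n")
        fh.write("lag\\distance\t" + "\t".join(str(d) for d in mimap.distance_grid) + "\n")
        for i, lag in enumerate(mimap.lag_grid):
            fh.write(str(lag) + "\t" + "\t".join(f"{v:.10g}" for v in mimap.mi[i]) + "\n")


def read_mi_map(path):
    from .connectivity import MIMap

    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("# roi="):
            raise ValueError("MI map TSV: missing '# roi=' metadata header")
        meta = dict(tok.split("=") for tok in meta_line[2:].split())
        fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
        distance = np.array([int(v) for v in header[1:]])
        body = np.loadtxt(fh, ndmin=2)
    lag = body[:, 0].astype(int)
    mi = body[:, 1:]
    roi = meta["roi"] if meta["roi"] != "-" else ""
    return MIMap(mi, lag, distance, float(meta["fs"]), roi=roi, run=int(meta["run"]),
                 conditioning=meta["conditioning"])


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # strict JSON has no NaN/Inf
    return obj


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(summary), indent=2, sort_keys=True))


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end synthetic pipeline.

    Every stochastic stage owns an explicit seed derived from ``seed``; the
    config round-trips losslessly through YAML.
    """

    seed: int = 0
    # behavioral simulation
    n_participants: int = 40
    story_duration_s: float = 120.0
    n_boundaries: int = 10
    behavioral_advance_ms: float = 182.0
    response_jitter_sd_ms: float = 150.0
    response_jitter_sd_run2_ms: float = 110.0  # tighter run-2 responses: consensus learning
    hit_prob: float = 0.9
    false_press_rate_per_min: float = 0.5
    n_words: int = 200
    word_delta: float = 0.2
    # neural simulation
    n_channels: int = 32
    n_effect_channels: int = 8
    n_hippo: int = 4
    neural_duration_s: float = 120.0
    anticipation_shift_ms: float = 200.0
    coupling_lag_ms: float = -700.0
    snr: float = 1.0
    # analysis
    p_max: int = 20
    gc_order: int | None = None
    posterior_ratio: float = 10.0
    peak_percentile: float = 95.0
    q_fdr: float = 0.05
    lag_step_ms: float = 50.0
    lag_range_ms: float = 1500.0
    n_perm: int = 200
    n_perm_peak: int = 50

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown field(s) {sorted(unknown)}")
        return cls(**data)
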