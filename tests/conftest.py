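"""Shared fixtures: one planted two-run recording reused across test modules.

All fixture data is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from storyrecall.granger import cross_run_gc
from storyrecall.preprocess import clean_and_align
from storyrecall.synth import SimulationTruth, gen_two_run_recording


@pytest.fixture(scope="session")
def planted_recording():
    """16 cortical + 2 hippocampal channels, 120 s at 100 Hz.

    Channels 0-3 carry a 200 ms run-2 anticipation of the shared latent;
    the hippocampal channels lead the cortical pattern by 700 ms inside
    1 s windows around twelve designated event times.
    """
    shifts = np.zeros(16)
    shifts[:4] = 200.0
    event_ms = np.arange(10000.0, 106000.0, 8000.0)
    truth = SimulationTruth(
        anticipation_shift_ms=shifts,
        effect_channels=np.arange(4),
        boundary_times_ms=event_ms,
        coupling_lag_ms=-700.0,
        coupling_windows=[(p - 500.0, p + 500.0) for p in event_ms],
        seed=11,
        coupling_strength=1.5,
    )
    run1, run2, env, truth = gen_two_run_recording(16, 2, 120.0, truth, snr=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run1, run2, env = clean_and_align(run1, run2, env)
    return {"run1": run1, "run2": run2, "env": env, "truth": truth,
            "event_ms": event_ms, "n_cortical": 16}


@pytest.fixture(scope="session")
def gc_fit(planted_recording):
    """Cross-run GC over the cortical channels of the planted recording."""
    rec = planted_recording
    table, results = cross_run_gc(
        rec["run1"], rec["run2"], rec["env"], p_max=25,
        channels=list(range(rec["n_cortical"])),
    )
    return {"table": table, "results": results}
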