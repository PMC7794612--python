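"""Shared fixtures.

The expensive end-to-end runs (full signal chain, cohort cross-validation)
are session-scoped so the acceptance tests and the module tests share them.
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pytest

import ventrack as vt


def stationary_params(freq: float, freq_sd: float = 0.0) -> vt.BehaviourParams:
    """A fish pinned in place, ventilating at a fixed (or jittered) rate."""
    return vt.BehaviourParams(
        state="fear", mean_speed=0.0, speed_sd=0.0, speed_tau=1.0,
        freeze_rate=1.0, freeze_duration=1e9,
        dart_rate=0.0, dart_speed=0.0, dart_duration=0.1,
        vent_base_freq=freq, vent_freq_sd=freq_sd, vent_tau=1.0,
        heading_persistence=0.5,
    )


@pytest.fixture(scope="session")
def arena():
    return vt.default_arena()


@pytest.fixture(scope="session")
def cohort_table():
    """The default study-shaped cohort: 2760 standardised index windows."""
    return vt.generate_cohort(vt.default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def tracker_runs():
    """Noiseless end-to-end localisation of 5 normal-state fish, 60 s each.

    Recordings carry 1 s of padding per side; accuracy is evaluated on the
    analysed 60 s interior (zero-phase filter edges are settling there).
    Returns per-fish error series and (estimated, true) speed pairs plus the
    wall-clock processing time.
    """
    errors, speeds_est, speeds_true = [], [], []
    t0 = time.monotonic()
    for i in range(5):
        traj = vt.simulate_trajectory(vt.default_params("normal"), 62.0,
                                      seed=100 + i, fish_id=f"f{i}")
        rec = vt.render_signals(traj, snr=None, seed=200 + i)
        maps = vt.compute_peak_maps(vt.bandpass_extract(rec))
        track = vt.estimate_track(maps, rec.arena)
        vel = vt.differentiate_positions(track)
        sel = (track.t >= 1.0) & (track.t < 61.0)
        tx = np.interp(track.t, traj.t, traj.xy[:, 0])
        ty = np.interp(track.t, traj.t, traj.xy[:, 1])
        errors.append(np.hypot(track.xy[:, 0] - tx, track.xy[:, 1] - ty)[sel])
        speeds_est.append(vel.speed[sel])
        speeds_true.append(np.interp(track.t, traj.t, traj.speed)[sel])
    elapsed = time.monotonic() - t0
    return {"errors": errors, "speed_est": speeds_est,
            "speed_true": speeds_true, "elapsed_s": elapsed}


def frequency_recovery(freq: float, snr: float | None, seed: int) -> float:
    """Worst-tick |AR peak - truth| for a stationary fish on the analysed 20 s."""
    traj = vt.simulate_trajectory(stationary_params(freq), 24.0, seed=seed)
    rec = vt.bandpass_extract(vt.render_signals(traj, snr=snr, seed=seed + 1))
    maps = vt.compute_peak_maps(rec)
    channel = int(np.argmax(rec.samples.var(axis=1)))
    sel = [m for m in maps if 2.0 <= m.t < 22.0]
    return max(abs(float(m.peak_freq[channel]) - freq) for m in sel)


@pytest.fixture(scope="session")
def frequency_runs():
    out = {}
    for freq in (2.0, 3.0, 5.0, 8.0):
        out[(freq, "noiseless")] = frequency_recovery(freq, None, int(10 * freq))
        out[(freq, "snr5")] = frequency_recovery(freq, 5.0, 100 + int(10 * freq))
    return out


@pytest.fixture(scope="session")
def llgmn_reports(cohort_table):
    """LLGMN leave-one-fish-out reports for N = 1..6 plus macro-F pairwise table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reports, pairwise = vt.compare_pc_counts(
            cohort_table, {"kind": "llgmn", "n_components": 2})
    return reports, pairwise


@pytest.fixture(scope="session")
def lda_report_4pc(cohort_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vt.loo_fish_cv(cohort_table, {"kind": "lda"}, n_pcs=4)
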