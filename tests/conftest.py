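"""Shared fixtures: small synthetic sessions with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from evokedio import synthdata as sd


@pytest.fixture(scope="session")
def truth():
    return sd.default_ground_truth()


@pytest.fixture(scope="session")
def ipi_protocol(truth):
    return sd.make_protocol("ipi_variation", n_trials_per_condition=5, seed=0)


@pytest.fixture(scope="session")
def ipi_spikes(ipi_protocol, truth):
    return sd.simulate_spike_responses(ipi_protocol, truth, n_channels=3, seed=11)


def make_detection_session(n_trials=25, spikes_per_trial=8, snr=12.0,
                           artifact_amplitude=None, noise_sd=1.0, seed=0):
    """Raw trace with known spike times, >= 3 ms apart, for scoring detection.

    Returns (ground-truth spike table, protocol, recording).  ``snr`` is the
    template peak amplitude over the noise SD; the optional artifact adds a
    decaying polynomial transient at every pulse onset.
    """
    proto = sd.make_protocol("ipi_variation", ipi_values=[100.0],
                             n_trials_per_condition=n_trials, seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_trials):
        times = 15.0 + 8.0 * np.arange(spikes_per_trial) + rng.uniform(
            0.0, 4.0, spikes_per_trial)
        rows += [(0, t, x) for x in times]
    spikes = pd.DataFrame(rows, columns=["channel", "trial", "time_ms"])
    wave = sd.biphasic_template(amplitude=snr * noise_sd)
    artifact = (None if artifact_amplitude is None
                else sd.ArtifactModel(amplitude=artifact_amplitude))
    rec = sd.synthesize_raw_trace(spikes, proto, waveform=wave,
                                  artifact=artifact, noise_sd=noise_sd,
                                  seed=seed + 1, n_channels=1)
    return spikes, proto, rec


def match_detections(det: pd.DataFrame, truth_spikes: pd.DataFrame,
                     tol_ms: float = 0.5):
    """Greedy per-trial matching of detections to ground truth.

    Returns (recall, precision): matched fraction of true spikes, and of
    detections.
    """
    matched_truth = 0
    matched_det = 0
    for trial, block in truth_spikes.groupby("trial"):
        d = det.loc[det["trial"] == trial, "time_ms"].to_numpy()
        t = block["time_ms"].to_numpy()
        used = np.zeros(d.size, dtype=bool)
        for x in t:
            if d.size == 0:
                continue
            err = np.abs(d - x)
            err[used] = np.inf
            j = int(np.argmin(err))
            if err[j] <= tol_ms:
                used[j] = True
                matched_truth += 1
        matched_det += int(used.sum())
    recall = matched_truth / len(truth_spikes) if len(truth_spikes) else np.nan
    precision = matched_det / len(det) if len(det) else np.nan
    return recall, precision
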