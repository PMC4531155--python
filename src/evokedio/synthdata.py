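"""Synthetic paired-pulse sessions from a known ground-truth circuit.

This module stands in for the wet-lab side of a paired-pulse facilitation
experiment: an input fiber tract is stimulated with pairs of pulses while a
multielectrode array records multiunit output.  A
:class:`CircuitGroundTruth` specifies the circuit's true input-output
behaviour — how the expected first-pulse spike count grows with stimulus
intensity, how the second-pulse response is facilitated as a function of the
inter-pulse interval (IPI), and how first-spike latencies shorten under
facilitation — and the generators here draw stimulation protocols, spike
event tables and raw voltage traces from it.  Because the ground truth is
known, every downstream stage (artifact suppression, spike detection,
feature extraction, information analysis, I/O model fitting) can be scored
against it.

Default calibration: facilitation is absent at 50 ms IPI, peaks at 100 ms,
declines through 200 ms and has vanished by 500 ms, where the two responses
of the pair are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    INTENSITY_VARIATION,
    IPI_VARIATION,
    RawRecording,
    StimulusProtocol,
    empty_spike_table,
)

__all__ = [
    "CircuitGroundTruth",
    "ArtifactModel",
    "hill_base_rate",
    "bump_facilitation",
    "default_ground_truth",
    "biphasic_template",
    "make_protocol",
    "simulate_spike_responses",
    "synthesize_raw_trace",
]

#: The four inter-pulse intervals of the IPI-variation protocol (ms).
DEFAULT_IPIS = (50.0, 100.0, 200.0, 500.0)
#: Relative intensity used throughout IPI-variation sessions.
DEFAULT_IPI_PROTOCOL_INTENSITY = 0.75
#: Trials delivered per condition.
DEFAULT_TRIALS_PER_CONDITION = 20


def hill_base_rate(max_count: float = 6.0, half_intensity: float = 0.4,
                   exponent: float = 2.0) -> Callable[[float], float]:
    """Monotone saturating intensity -> expected first-pulse spike count.

    A Hill curve ``max * i**h / (i**h + k**h)``: zero at zero intensity,
    saturating toward ``max_count`` as the stimulus recruits the whole
    afferent volley.
    """

    def curve(intensity):
        i = np.asarray(intensity, dtype=float)
        out = max_count * i**exponent / (i**exponent + half_intensity**exponent)
        return out if out.ndim else float(out)

    return curve


def bump_facilitation(peak_gain: float = 1.8, peak_ipi: float = 100.0,
                      width_below: float = 0.30, width_above: float = 0.55,
                      ) -> Callable[[float], float]:
    """IPI (ms) -> multiplicative gain on the second-pulse expected count.

    An asymmetric log-Gaussian bump: gain ~1 at 50 ms (facilitation not yet
    engaged), maximal at ``peak_ipi``, decaying through 200 ms and back to 1
    by 500 ms where the two responses are independent.  Widths are in log-IPI
    units on either side of the peak.
    """

    def curve(ipi):
        x = np.log(np.asarray(ipi, dtype=float) / peak_ipi)
        w = np.where(x < 0, width_below, width_above)
        out = 1.0 + (peak_gain - 1.0) * np.exp(-0.5 * (x / w) ** 2)
        return out if out.ndim else float(out)

    return curve


@dataclass
class CircuitGroundTruth:
    """True input-output behaviour of the simulated pathway.

    Parameters
    ----------
    base_rate_curve:
        intensity in [0, 1] -> expected spike count after the first pulse
        (per channel, counted over one IPI window); monotone saturating.
    facilitation_curve:
        IPI (ms) -> multiplicative gain on the second-pulse expected count;
        >= 1 around 100 ms and -> 1 at 500 ms.
    latency1_mean:
        mean first-spike latency after the first pulse at maximal
        intensity (ms).
    latency_shortening:
        ms by which the second-pulse latency shortens per unit facilitation
        gain above 1.
    intensity_latency_slope:
        ms added to the latency mean per unit of *missing* intensity
        (weaker stimuli recruit the pathway more slowly).
    count_dispersion:
        variance-to-mean ratio of the spike-count noise. 1 -> Poisson;
        > 1 -> negative binomial; < 1 -> sub-Poisson (rounded Gaussian with
        the requested variance); 0 -> deterministic counts.
    latency_jitter_sd:
        trial-to-trial SD of the first-spike latency (ms).
    """

    base_rate_curve: Callable[[float], float]
    facilitation_curve: Callable[[float], float]
    latency1_mean: float = 8.0
    latency_shortening: float = 3.0
    intensity_latency_slope: float = 2.0
    count_dispersion: float = 1.0
    latency_jitter_sd: float = 1.0

    def validate(self, ipis: Sequence[float] = DEFAULT_IPIS,
                 tol: float = 0.05) -> None:
        """Check the structural invariants of the ground truth.

        Raises ``ValueError`` if facilitation does not vanish at 500 ms, if
        its argmax over the standard IPIs is not 100 ms, or if the base-rate
        curve decreases anywhere on a dense intensity grid.
        """
        if abs(self.facilitation_curve(500.0) - 1.0) > tol:
            raise ValueError("facilitation gain at 500 ms must be 1 (independence)")
        gains = [self.facilitation_curve(i) for i in ipis]
        if ipis[int(np.argmax(gains))] != 100.0:
            raise ValueError("facilitation must peak at IPI = 100 ms")
        grid = np.linspace(0.0, 1.0, 201)
        rates = np.asarray(self.base_rate_curve(grid), dtype=float)
        if np.any(np.diff(rates) < -1e-12):
            raise ValueError("base_rate_curve must be non-decreasing")

    def latency_mean(self, pulse: int, intensity: float, ipi: float) -> float:
        """Condition-mean first-spike latency (ms) for pulse 1 or 2."""
        m = self.latency1_mean + self.intensity_latency_slope * (1.0 - intensity)
        if pulse == 2:
            gain = float(self.facilitation_curve(ipi))
            m = m - self.latency_shortening * (gain - 1.0)
        return max(m, 0.5)


def default_ground_truth() -> CircuitGroundTruth:
    """Ground truth with the default facilitation and recruitment curves."""
    truth = CircuitGroundTruth(
        base_rate_curve=hill_base_rate(),
        facilitation_curve=bump_facilitation(),
    )
    truth.validate()
    return truth


def make_protocol(kind: str,
                  ipi_values: Sequence[float] = DEFAULT_IPIS,
                  intensity_values: Sequence[float] = (DEFAULT_IPI_PROTOCOL_INTENSITY,),
                  n_trials_per_condition: int = DEFAULT_TRIALS_PER_CONDITION,
                  seed: int = 0,
                  inter_trial_s: float = 5.0) -> StimulusProtocol:
    """Build a paired-pulse stimulation schedule.

    ``ipi_variation`` crosses the given IPIs with a single shared intensity;
    ``intensity_variation`` holds the IPI at 200 ms and ramps over the given
    intensities.  Trials are delivered in one block per condition, with
    first-pulse onsets spaced ``inter_trial_s`` apart (5 s = 0.2 Hz).  The
    schedule itself is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic generators.
    """
    if n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    if kind == IPI_VARIATION:
        if not len(ipi_values):
            raise ValueError("ipi_variation requires at least one IPI")
        if len(intensity_values) != 1:
            raise ValueError("ipi_variation uses a single shared intensity")
        conditions = [(float(ipi), float(intensity_values[0])) for ipi in ipi_values]
    elif kind == INTENSITY_VARIATION:
        if not len(intensity_values):
            raise ValueError("intensity_variation requires at least one intensity")
        conditions = [(200.0, float(i)) for i in intensity_values]
    else:
        raise ValueError(f"unknown protocol kind: {kind!r}")

    rows = []
    trial_id = 0
    onset = inter_trial_s  # leave a silent lead-in before the first pair
    for ipi, intensity in conditions:
        if ipi <= 0:
            raise ValueError("IPIs must be positive")
        for _ in range(n_trials_per_condition):
            rows.append((trial_id, ipi, intensity, onset))
            trial_id += 1
            onset += inter_trial_s
    trials = pd.DataFrame(rows, columns=["trial", "ipi_ms", "intensity", "onset_s"])
    return StimulusProtocol(kind=kind, trials=trials, inter_trial_s=inter_trial_s)


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float,
                 size: int) -> np.ndarray:
    """Spike counts with the requested mean and variance-to-mean ratio."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion == 1.0:
        return rng.poisson(mean, size)
    if dispersion > 1.0:
        # negative binomial with var = dispersion * mean
        r = mean / (dispersion - 1.0)
        p = 1.0 / dispersion
        return rng.negative_binomial(r, p, size)
    if dispersion == 0.0:
        return np.full(size, int(round(mean)))
    draws = rng.normal(mean, np.sqrt(dispersion * mean), size)
    return np.maximum(np.rint(draws), 0).astype(int)


def _draw_latencies(rng: np.random.Generator, mean: float, jitter_sd: float,
                    upper: float, size: int) -> np.ndarray:
    """Lognormal first-spike latencies, truncated to (0, upper).

    Parametrized so the median is ``mean`` and the coefficient of variation
    is approximately ``jitter_sd / mean``; lognormality keeps latencies
    positive and right-skewed, as evoked first-spike delays are.
    """
    sigma = jitter_sd / mean
    lat = np.exp(rng.normal(np.log(mean), sigma, size))
    return np.clip(lat, 0.1, upper - 1e-6)


def simulate_spike_responses(protocol: StimulusProtocol,
                             truth: CircuitGroundTruth,
                             n_channels: int = 16,
                             seed: int = 0) -> pd.DataFrame:
    """Draw a spike-event table for every channel x trial of *protocol*.

    Per channel and trial, the count after pulse 1 is drawn with mean
    ``base_rate_curve(intensity)`` and the count after pulse 2 with that
    mean times ``facilitation_curve(IPI)``.  The first spike of each burst
    falls at a jittered latency after its pulse; any further spikes are
    placed in increasing order within the remainder of the IPI-long window.
    Times are stored in ms relative to the trial's first-pulse onset, so
    pulse-1 events lie in [0, IPI) and pulse-2 events in [IPI, 2 IPI).
    Channels are exchangeable draws from the same ground truth.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    records: list[tuple[int, int, float]] = []
    trials = protocol.trials
    for _, row in trials.iterrows():
        trial = int(row["trial"])
        ipi = float(row["ipi_ms"])
        intensity = float(row["intensity"])
        mean1 = float(truth.base_rate_curve(intensity))
        gain = float(truth.facilitation_curve(ipi))
        mean2 = mean1 * gain
        n1 = _draw_counts(rng, mean1, truth.count_dispersion, n_channels)
        n2 = _draw_counts(rng, mean2, truth.count_dispersion, n_channels)
        for ch in range(n_channels):
            for pulse, n in ((1, int(n1[ch])), (2, int(n2[ch]))):
                if n == 0:
                    continue
                mlat = truth.latency_mean(pulse, intensity, ipi)
                first = float(_draw_latencies(rng, mlat, truth.latency_jitter_sd,
                                              ipi, 1)[0])
                times = [first]
                if n > 1:
                    extra = rng.uniform(first, ipi - 1e-6, n - 1)
                    times.extend(np.sort(extra).tolist())
                offset = 0.0 if pulse == 1 else ipi
                records.extend((ch, trial, offset + t) for t in times)
    if not records:
        return empty_spike_table()
    spikes = pd.DataFrame(records, columns=["channel", "trial", "time_ms"])
    return spikes.sort_values(["channel", "trial", "time_ms"], ignore_index=True)


def biphasic_template(sampling_rate: float = 10_000.0,
                      duration_ms: float = 1.2,
                      amplitude: float = 1.0) -> tuple[np.ndarray, int]:
    """Biphasic extracellular spike waveform and the index of its main peak.

    A dominant negative lobe followed by a smaller positive rebound, total
    duration ``duration_ms`` (default 1.2 ms, comfortably shorter than the
    2 ms peak-lifetime period of the detector so detection is well posed).
    ``amplitude`` is the depth of the negative peak.  Returns
    ``(waveform, peak_index)``; generators align ``peak_index`` with the
    nominal spike time.
    """
    n = max(int(round(duration_ms * 1e-3 * sampling_rate)), 4)
    t = np.arange(n) / sampling_rate * 1e3  # ms
    t_neg, t_pos = 0.3 * duration_ms, 0.7 * duration_ms
    s_neg, s_pos = 0.10 * duration_ms, 0.16 * duration_ms
    wave = (-np.exp(-0.5 * ((t - t_neg) / s_neg) ** 2)
            + 0.5 * np.exp(-0.5 * ((t - t_pos) / s_pos) ** 2))
    wave *= amplitude / np.abs(wave).max()
    return wave, int(np.argmin(wave))


@dataclass
class ArtifactModel:
    """Per-pulse stimulation transient added to every channel.

    A decaying polynomial ``amplitude * (1 - t/duration)**order`` anchored at
    each pulse onset — a stiff, smooth transient that dwarfs spikes and is
    the kind of structure local-polynomial artifact subtraction must remove.
    """

    amplitude: float = 50.0
    duration_ms: float = 10.0
    order: int = 4

    def waveform(self, sampling_rate: float) -> np.ndarray:
        n = int(round(self.duration_ms * 1e-3 * sampling_rate))
        t = np.arange(n) / n
        return self.amplitude * (1.0 - t) ** self.order


def synthesize_raw_trace(spikes: pd.DataFrame,
                         protocol: StimulusProtocol,
                         waveform: tuple[np.ndarray, int] | None = None,
                         artifact: ArtifactModel | None = None,
                         noise_sd: float = 1.0,
                         sampling_rate: float = 10_000.0,
                         seed: int = 0,
                         n_channels: int | None = None) -> RawRecording:
    """Render a spike-event table into a raw multichannel voltage trace.

    The trace is the superposition of Gaussian noise, one spike template per
    event (its main peak aligned with the event time) and, if an
    :class:`ArtifactModel` is given, one stimulation transient at every
    pulse onset.  The input table is the retained ground truth for scoring
    detection.  Raises ``ValueError`` if any spike falls beyond the end of
    the trace implied by the protocol.
    """
    if waveform is None:
        waveform = biphasic_template(sampling_rate)
    wave, peak_idx = waveform
    lookup = protocol.trial_lookup()
    n_ch = n_channels
    if n_ch is None:
        n_ch = int(spikes["channel"].max()) + 1 if len(spikes) else 1

    duration_s = float(protocol.trials["onset_s"].max()) + protocol.inter_trial_s
    n_samples = int(round(duration_s * sampling_rate))
    rng = np.random.default_rng(seed)
    data = (rng.normal(0.0, noise_sd, (n_ch, n_samples)) if noise_sd > 0
            else np.zeros((n_ch, n_samples)))

    for _, ev in spikes.iterrows():
        trial = int(ev["trial"])
        onset_s = float(lookup.loc[trial, "onset_s"])
        t_abs = onset_s + float(ev["time_ms"]) * 1e-3
        start = int(round(t_abs * sampling_rate)) - peak_idx
        stop = start + wave.size
        if stop > n_samples or start < 0:
            raise ValueError(f"spike at {t_abs:.4f} s falls outside the trace")
        data[int(ev["channel"]), start:stop] += wave

    onsets = protocol.pulse_onsets()
    if artifact is not None:
        art = artifact.waveform(sampling_rate)
        for t0 in onsets:
            start = int(round(t0 * sampling_rate))
            stop = min(start + art.size, n_samples)
            data[:, start:stop] += art[: stop - start]

    return RawRecording(samples=data, sampling_rate=sampling_rate,
                        stim_onsets=onsets)
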