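"""Core containers for paired-pulse stimulation experiments.

The analysis revolves around four objects:

* :class:`StimulusProtocol` — the stimulation schedule: for every trial, a
  paired pulse defined by its inter-pulse interval (IPI, ms), a normalized
  stimulus intensity in (0, 1], and the absolute onset time of the first
  pulse.
* :class:`RawRecording` — a multichannel sampled voltage trace with its
  sampling rate and the absolute onset times of every delivered pulse.
* Spike-event tables — plain :class:`pandas.DataFrame` objects with columns
  ``channel, trial, time_ms`` where ``time_ms`` is relative to the owning
  trial's first-pulse onset (may be as early as -10 ms, the left edge of the
  analysis window).
* Response-feature tables — per-trial or per-condition summaries built by
  :mod:`evokedio.features`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column schema of a spike-event table.
SPIKE_COLUMNS = ("channel", "trial", "time_ms")

#: Kinds of stimulation protocol.
IPI_VARIATION = "ipi_variation"
INTENSITY_VARIATION = "intensity_variation"


def empty_spike_table() -> pd.DataFrame:
    """Return an empty spike-event table with the canonical schema."""
    return pd.DataFrame(
        {"channel": pd.Series(dtype=int),
         "trial": pd.Series(dtype=int),
         "time_ms": pd.Series(dtype=float)}
    )


def validate_spike_table(spikes: pd.DataFrame) -> pd.DataFrame:
    """Check that *spikes* has the spike-event schema; return it unchanged."""
    missing = set(SPIKE_COLUMNS) - set(spikes.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    return spikes


@dataclass(frozen=True)
class StimulusProtocol:
    """Paired-pulse stimulation schedule.

    Parameters
    ----------
    kind:
        ``"ipi_variation"`` (single intensity, several IPIs) or
        ``"intensity_variation"`` (fixed 200 ms IPI, several intensities).
    trials:
        DataFrame with columns ``trial`` (int id), ``ipi_ms``, ``intensity``
        (normalized to (0, 1]) and ``onset_s`` (absolute time of the first
        pulse of the pair, seconds).
    inter_trial_s:
        Spacing between consecutive first-pulse onsets; 5 s corresponds to
        the 0.2 Hz delivery rate used throughout.
    """

    kind: str
    trials: pd.DataFrame
    inter_trial_s: float = 5.0

    def __post_init__(self) -> None:
        required = {"trial", "ipi_ms", "intensity", "onset_s"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"protocol trials missing columns: {sorted(missing)}")
        if self.kind not in (IPI_VARIATION, INTENSITY_VARIATION):
            raise ValueError(f"unknown protocol kind: {self.kind!r}")
        ipi = np.asarray(self.trials["ipi_ms"], dtype=float)
        inten = np.asarray(self.trials["intensity"], dtype=float)
        if np.any(ipi <= 0):
            raise ValueError("IPIs must be positive")
        if np.any((inten <= 0) | (inten > 1)):
            raise ValueError("intensities must lie in (0, 1]")
        if self.kind == INTENSITY_VARIATION and not np.allclose(ipi, 200.0):
            raise ValueError("intensity-variation trials must use IPI = 200 ms")
        if self.kind == IPI_VARIATION and np.unique(inten).size != 1:
            raise ValueError("ipi-variation trials must share one intensity")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pulse_onsets(self) -> np.ndarray:
        """Absolute onset times (s) of every pulse, both of each pair, sorted."""
        first = np.asarray(self.trials["onset_s"], dtype=float)
        second = first + np.asarray(self.trials["ipi_ms"], dtype=float) / 1000.0
        return np.sort(np.concatenate([first, second]))

    def trial_lookup(self) -> pd.DataFrame:
        """Trials indexed by trial id."""
        return self.trials.set_index("trial")


@dataclass
class RawRecording:
    """Multichannel sampled extracellular trace.

    ``samples`` has shape (n_channels, n_samples); voltage units are
    arbitrary.  ``stim_onsets`` holds the absolute time (s) of *every*
    delivered pulse and must be strictly increasing.
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    stim_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.stim_onsets.size and np.any(np.diff(self.stim_onsets) <= 0):
            raise ValueError("stim_onsets must be strictly increasing")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids)
            if self.channel_ids.size != self.samples.shape[0]:
                raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "RawRecording":
        """New recording sharing metadata but with different samples."""
        return RawRecording(
            samples=samples,
            sampling_rate=self.sampling_rate,
            stim_onsets=self.stim_onsets.copy(),
            channel_ids=None if self.channel_ids is None else self.channel_ids.copy(),
        )
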