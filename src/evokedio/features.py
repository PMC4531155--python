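"""Evoked-response features from spike-event tables.

The response to one paired pulse is summarized by five features, computed
per channel and trial:

* ``count1`` / ``count2`` — number of evoked spikes in the IPI-long window
  after the first / second pulse (the response *strength*);
* ``count_total`` — their sum, the global response strength;
* ``lat1`` / ``lat2`` — latency (ms) of the first spike after each pulse;
  a trial with no spike in the window has no latency and is excluded from
  latency averages.

All windows are half-open ``[left, right)``: a spike exactly at the second
pulse onset belongs to pulse 2.  The peristimulus time histogram (PSTH)
uses 2 ms bins over ``[-10 ms, 2 IPI)`` relative to the first pulse.

Strengths can be normalized to a reference condition so sessions with
different absolute excitability can be merged: the reference is the
all-electrode mean total strength at the maximal intensity (intensity
protocol) or at the 500 ms IPI (IPI protocol).  Latencies are never
normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import INTENSITY_VARIATION, IPI_VARIATION, StimulusProtocol

__all__ = [
    "PSTH",
    "compute_psth",
    "count_evoked_spikes",
    "first_spike_latency",
    "per_trial_features",
    "condition_features",
    "normalize_strengths",
    "normalize_intensity",
    "facilitation_curve_from_features",
]


@dataclass
class PSTH:
    """Peristimulus time histogram, per channel and pooled over the array.

    ``counts`` has shape (n_channels, n_bins); ``pooled`` is its column sum.
    Bin *b* covers ``[bin_edges[b], bin_edges[b+1])``.
    """

    bin_edges: np.ndarray
    channels: np.ndarray
    counts: np.ndarray
    pooled: np.ndarray
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: bin_left_ms, bin_right_ms, channel, count."""
        rows = []
        for i, ch in enumerate(self.channels):
            for b in range(self.counts.shape[1]):
                rows.append((self.bin_edges[b], self.bin_edges[b + 1],
                             int(ch), int(self.counts[i, b])))
        return pd.DataFrame(rows, columns=["bin_left_ms", "bin_right_ms",
                                           "channel", "count"])


def compute_psth(spikes: pd.DataFrame, ipi: float, bin_ms: float = 2.0,
                 window: tuple[float, float] | None = None,
                 n_trials: int | None = None,
                 channels: Sequence[int] | None = None) -> PSTH:
    """Histogram trial-relative spike times per channel and pooled.

    The default window is ``[-10, 2 IPI)`` ms relative to the first pulse;
    bins are half-open.  ``n_trials`` is carried as metadata (for rate
    conversion); it defaults to the number of distinct trials in the table.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = window if window is not None else (-10.0, 2.0 * ipi)
    n_bins = int(np.ceil((hi - lo) / bin_ms))
    edges = lo + bin_ms * np.arange(n_bins + 1)
    if channels is None:
        channels = np.unique(spikes["channel"]) if len(spikes) else np.empty(0, int)
    channels = np.asarray(channels, dtype=int)
    if n_trials is None:
        n_trials = int(spikes["trial"].nunique()) if len(spikes) else 0
    counts = np.zeros((channels.size, n_bins), dtype=int)
    if len(spikes):
        ch_index = {int(c): i for i, c in enumerate(channels)}
        t = spikes["time_ms"].to_numpy(dtype=float)
        ch = spikes["channel"].to_numpy(dtype=int)
        # half-open bins via floor indexing; hi itself is excluded
        inside = (t >= lo) & (t < lo + n_bins * bin_ms)
        b = np.floor((t[inside] - lo) / bin_ms).astype(int)
        for c, bi in zip(ch[inside], b):
            if c in ch_index:
                counts[ch_index[c], bi] += 1
    return PSTH(bin_edges=edges, channels=channels, counts=counts,
                pooled=counts.sum(axis=0), n_trials=n_trials)


def _pulse_window(pulse: int, ipi: float) -> tuple[float, float]:
    if pulse == 1:
        return 0.0, ipi
    if pulse == 2:
        return ipi, 2.0 * ipi
    raise ValueError("pulse must be 1 or 2")


def _grid(spikes: pd.DataFrame, trials: Iterable[int] | None,
          channels: Iterable[int] | None) -> tuple[np.ndarray, np.ndarray]:
    if trials is None:
        trials = np.unique(spikes["trial"]) if len(spikes) else np.empty(0, int)
    if channels is None:
        channels = np.unique(spikes["channel"]) if len(spikes) else np.empty(0, int)
    return np.asarray(channels, dtype=int), np.asarray(trials, dtype=int)


def count_evoked_spikes(spikes: pd.DataFrame, pulse: int, ipi: float,
                        trials: Iterable[int] | None = None,
                        channels: Iterable[int] | None = None) -> pd.DataFrame:
    """Evoked spike count per channel x trial for one pulse of the pair.

    Pulse 1 counts events in ``[0, IPI)``, pulse 2 in ``[IPI, 2 IPI)``.
    Channel/trial combinations without spikes appear with count 0 (pass
    ``trials``/``channels`` to fix the grid when whole trials are silent).
    """
    lo, hi = _pulse_window(pulse, ipi)
    channels, trials = _grid(spikes, trials, channels)
    out = pd.DataFrame(
        [(c, t) for c in channels for t in trials], columns=["channel", "trial"]
    )
    if len(spikes):
        t = spikes["time_ms"].to_numpy(dtype=float)
        sel = spikes.loc[(t >= lo) & (t < hi)]
        got = sel.groupby(["channel", "trial"]).size()
    else:
        got = pd.Series(dtype=int)
    key = pd.MultiIndex.from_frame(out)
    out["count"] = got.reindex(key, fill_value=0).to_numpy()
    return out


def first_spike_latency(spikes: pd.DataFrame, pulse: int, ipi: float,
                        trials: Iterable[int] | None = None,
                        channels: Iterable[int] | None = None) -> pd.DataFrame:
    """First-spike latency (ms from the pulse onset) per channel x trial.

    Trials with no in-window spike get NaN; condition averages later skip
    them (a latency is undefined when nothing responded).
    """
    lo, hi = _pulse_window(pulse, ipi)
    channels, trials = _grid(spikes, trials, channels)
    out = pd.DataFrame(
        [(c, t) for c in channels for t in trials], columns=["channel", "trial"]
    )
    if len(spikes):
        t = spikes["time_ms"].to_numpy(dtype=float)
        sel = spikes.loc[(t >= lo) & (t < hi)]
        got = sel.groupby(["channel", "trial"])["time_ms"].min() - lo
    else:
        got = pd.Series(dtype=float)
    key = pd.MultiIndex.from_frame(out[["channel", "trial"]])
    out["latency_ms"] = got.reindex(key).to_numpy()
    return out


def per_trial_features(spikes: pd.DataFrame, protocol: StimulusProtocol,
                       n_channels: int | None = None) -> pd.DataFrame:
    """Full per-trial feature table for every channel x trial of *protocol*.

    Columns: channel, trial, ipi_ms, intensity, count1, count2, count_total,
    lat1, lat2.  The trial grid comes from the protocol, so silent trials
    are present with zero counts and missing latencies.
    """
    if n_channels is None:
        n_channels = int(spikes["channel"].max()) + 1 if len(spikes) else 1
    channels = np.arange(n_channels)
    frames = []
    for ipi, block in protocol.trials.groupby("ipi_ms"):
        tids = block["trial"].to_numpy(dtype=int)
        sub = spikes.loc[spikes["trial"].isin(tids)] if len(spikes) else spikes
        c1 = count_evoked_spikes(sub, 1, ipi, trials=tids, channels=channels)
        c2 = count_evoked_spikes(sub, 2, ipi, trials=tids, channels=channels)
        l1 = first_spike_latency(sub, 1, ipi, trials=tids, channels=channels)
        l2 = first_spike_latency(sub, 2, ipi, trials=tids, channels=channels)
        df = c1.rename(columns={"count": "count1"})
        df["count2"] = c2["count"].to_numpy()
        df["count_total"] = df["count1"] + df["count2"]
        df["lat1"] = l1["latency_ms"].to_numpy()
        df["lat2"] = l2["latency_ms"].to_numpy()
        df.insert(2, "ipi_ms", float(ipi))
        lk = block.set_index("trial")["intensity"]
        df.insert(3, "intensity", lk.reindex(df["trial"]).to_numpy())
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["channel", "trial"], ignore_index=True)


def condition_features(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trial features to channel x condition means.

    Counts average over all trials (silent trials contribute 0); latencies
    average over responding trials only.
    """
    g = per_trial.groupby(["channel", "ipi_ms", "intensity"])
    out = g.agg(
        n_trials=("trial", "size"),
        mean_count1=("count1", "mean"),
        mean_count2=("count2", "mean"),
        mean_count_total=("count_total", "mean"),
        mean_lat1=("lat1", "mean"),  # NaNs (non-responding trials) skipped
        mean_lat2=("lat2", "mean"),
    ).reset_index()
    return out


def normalize_strengths(table: pd.DataFrame, protocol_kind: str) -> pd.DataFrame:
    """Divide all strengths by the reference condition's global mean total.

    The reference is the maximal intensity (intensity protocol) or the
    500 ms IPI (IPI protocol); "global" means the across-channel mean of
    the per-channel mean total strength.  Adds ``norm_count1``,
    ``norm_count2`` and ``norm_count_total`` columns; latencies are left
    untouched.
    """
    if protocol_kind == INTENSITY_VARIATION:
        ref_mask = table["intensity"] == table["intensity"].max()
    elif protocol_kind == IPI_VARIATION:
        ref_mask = table["ipi_ms"] == 500.0
        if not ref_mask.any():
            raise ValueError("IPI normalization needs the 500 ms condition")
    else:
        raise ValueError(f"unknown protocol kind: {protocol_kind!r}")
    ref = float(table.loc[ref_mask, "mean_count_total"].mean())
    if ref == 0.0:
        raise ValueError("reference condition has zero mean total strength")
    out = table.copy()
    for col in ("mean_count1", "mean_count2", "mean_count_total"):
        out[col.replace("mean_", "norm_")] = out[col] / ref
    return out


def normalize_intensity(currents: Sequence[float]) -> np.ndarray:
    """Normalize stimulation currents to the session maximum.

    Sessions use different absolute currents; dividing by the per-session
    maximum maps every session onto (0, 1] with the maximum at exactly 1.
    """
    c = np.asarray(currents, dtype=float)
    if c.size == 0:
        raise ValueError("no currents given")
    if np.any(c <= 0):
        raise ValueError("currents must be positive")
    return c / c.max()


def facilitation_curve_from_features(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Empirical facilitation ratio per IPI, with its Monte-Carlo SE.

    Ratio = mean pulse-2 count / mean pulse-1 count, pooled over channels
    and trials within each IPI; the SE is first-order propagated from the
    two sample means.  Recovers the generator's facilitation curve on
    synthetic data as trial count grows.
    """
    rows = []
    for ipi, block in per_trial.groupby("ipi_ms"):
        c1 = block["count1"].to_numpy(dtype=float)
        c2 = block["count2"].to_numpy(dtype=float)
        m1, m2 = c1.mean(), c2.mean()
        n = c1.size
        ratio = m2 / m1 if m1 > 0 else np.nan
        if m1 > 0 and m2 > 0 and n > 1:
            se = ratio * np.sqrt(c1.var(ddof=1) / (n * m1**2)
                                 + c2.var(ddof=1) / (n * m2**2))
        else:
            se = np.nan
        rows.append((float(ipi), n, ratio, se))
    return pd.DataFrame(rows, columns=["ipi_ms", "n", "ratio", "se"])
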