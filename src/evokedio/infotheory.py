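"""Plug-in information measures for stimulus-response pairs.

How much does a response feature (a spike count, a binned latency) tell us
about which stimulus was delivered?  With S the discrete stimulus label
(an IPI or an intensity level) and R the discretized response, the mutual
information is

    MI(R; S) = H(R) - H(R | S)        [bits]

estimated by the plug-in (maximum-likelihood) method from empirical
frequencies.  To compare features whose response entropies differ, the
coding fraction cf(R; S) = MI(R; S) / H(R) rescales MI to [0, 1]: the
fraction of the response variability that is informative about the
stimulus.

The plug-in estimator is biased upward for small samples; a Miller-Madow
correction is available behind a flag but is off by default.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "discretize",
    "entropy",
    "mutual_information",
    "coding_fraction",
    "rank_features",
    "FEATURE_COLUMNS",
]

#: Response features ranked by :func:`rank_features`, in display order.
FEATURE_COLUMNS = ("count1", "count2", "lat1", "lat2", "count_total")

#: Symbol reserved for missing responses (e.g. no spike -> no latency).
MISSING_SYMBOL = -1


def discretize(values: Sequence[float], bin_width: float = 2.0) -> np.ndarray:
    """Fixed-width binning of continuous responses into integer symbols.

    The symbol is ``floor(value / bin_width)``; 2 ms reuses the PSTH
    resolution for latencies.  Missing values (NaN) map to a dedicated
    symbol so that *whether* a response occurred carries information
    instead of being silently dropped.  Integer inputs pass through
    unchanged.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size and np.allclose(v[~np.isnan(v)] % 1, 0):
        out = v.copy()
    else:
        out = np.floor(v / bin_width)
    sym = np.where(np.isnan(out), MISSING_SYMBOL, out)
    return sym.astype(int)


def entropy(symbols: Sequence, miller_madow: bool = False) -> float:
    """Plug-in Shannon entropy in bits of a discrete sample.

    ``miller_madow`` adds the (K-1)/(2 n ln 2) small-sample bias correction,
    K being the number of observed symbols.
    """
    s = np.asarray(symbols)
    if s.size == 0:
        raise ValueError("entropy needs at least one symbol")
    _, counts = np.unique(s, return_counts=True)
    p = counts / s.size
    h = float(-np.sum(p * np.log2(p)))
    if miller_madow:
        h += (counts.size - 1) / (2.0 * s.size * np.log(2))
    return h


def mutual_information(stimuli: Sequence, responses: Sequence,
                       miller_madow: bool = False) -> float:
    """Plug-in MI(R; S) = H(R) - sum_s p(s) H(R | S=s), in bits.

    Non-negative up to floating error and bounded by min(H(R), H(S)).
    A single stimulus label yields 0 with a warning (there is nothing to
    discriminate).
    """
    s = np.asarray(stimuli)
    r = np.asarray(responses)
    if s.size != r.size:
        raise ValueError("stimuli and responses must be paired")
    if s.size == 0:
        raise ValueError("empty sample")
    labels = np.unique(s)
    if labels.size == 1:
        warnings.warn("single stimulus label: MI is 0", stacklevel=2)
        return 0.0
    h_r = entropy(r, miller_madow=miller_madow)
    h_cond = 0.0
    for lab in labels:
        mask = s == lab
        h_cond += mask.mean() * entropy(r[mask], miller_madow=miller_madow)
    mi = h_r - h_cond
    return max(mi, 0.0) if abs(mi) < 1e-12 else mi


def coding_fraction(stimuli: Sequence, responses: Sequence,
                    miller_madow: bool = False) -> float:
    """MI(R; S) / H(R): informative fraction of the response variability.

    Returns NaN when H(R) = 0 (a constant response carries no information
    and the ratio is undefined).
    """
    h_r = entropy(responses, miller_madow=miller_madow)
    if h_r == 0.0:
        return float("nan")
    cf = mutual_information(stimuli, responses, miller_madow=miller_madow) / h_r
    if not -1e-9 <= cf <= 1.0 + 1e-9:
        raise AssertionError(f"coding fraction {cf} outside [0, 1]")
    return float(min(max(cf, 0.0), 1.0))


def rank_features(experiments: Sequence[pd.DataFrame], input_var: str,
                  latency_bin_ms: float = 2.0,
                  miller_madow: bool = False) -> pd.DataFrame:
    """Coding fraction of every response feature, per experiment.

    Each experiment is a per-trial feature table (see
    :func:`evokedio.features.per_trial_features`); ``input_var`` names the
    stimulus column (``"ipi_ms"`` or ``"intensity"``).  Counts are used as
    their own symbols; latencies are binned at ``latency_bin_ms``, with
    non-responding trials as an explicit extra symbol.  Returns a long
    table (experiment, feature, cf) ready for box-plot summaries.
    """
    if input_var not in ("ipi_ms", "intensity"):
        raise ValueError("input_var must be 'ipi_ms' or 'intensity'")
    rows = []
    for k, table in enumerate(experiments):
        s = table[input_var].to_numpy()
        for feat in FEATURE_COLUMNS:
            vals = table[feat].to_numpy(dtype=float)
            if feat.startswith("lat"):
                r = discretize(vals, latency_bin_ms)
            else:
                r = vals.astype(int)
            rows.append((k, feat, coding_fraction(s, r,
                                                  miller_madow=miller_madow)))
    return pd.DataFrame(rows, columns=["experiment", "feature", "cf"])
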