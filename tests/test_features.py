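"""Response-feature arithmetic: PSTH, counts, latencies, normalization."""

import numpy as np
import pandas as pd
import pytest

from evokedio import features as ft
from evokedio import synthdata as sd


def brute_force_psth(spikes, channels, edges):
    counts = np.zeros((len(channels), len(edges) - 1), dtype=int)
    for i, ch in enumerate(channels):
        for _, ev in spikes[spikes["channel"] == ch].iterrows():
            for b in range(len(edges) - 1):
                if edges[b] <= ev["time_ms"] < edges[b + 1]:
                    counts[i, b] += 1
    return counts


class TestPsth:
    def test_delta_response_fills_one_bin(self):
        spikes = pd.DataFrame({"channel": 0, "trial": np.arange(20),
                               "time_ms": 1.0})
        p = ft.compute_psth(spikes, ipi=50.0)
        nz = np.flatnonzero(p.counts[0])
        assert nz.size == 1
        b = int(nz[0])
        assert p.bin_edges[b] == 0.0 and p.counts[0, b] == 20
        assert p.counts.sum() == 20

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(0)
        spikes = pd.DataFrame({
            "channel": rng.integers(0, 3, 400),
            "trial": rng.integers(0, 10, 400),
            "time_ms": rng.uniform(-12, 210, 400),
        })
        p = ft.compute_psth(spikes, ipi=100.0, channels=[0, 1, 2])
        expected = brute_force_psth(spikes, [0, 1, 2], p.bin_edges)
        assert np.array_equal(p.counts, expected)
        assert np.array_equal(p.pooled, expected.sum(axis=0))

    def test_empty_table_all_zero(self):
        p = ft.compute_psth(pd.DataFrame(columns=["channel", "trial", "time_ms"]),
                            ipi=50.0, channels=[0, 1])
        assert p.counts.shape == (2, 55)
        assert p.counts.sum() == 0

    def test_nonpositive_bin_rejected(self):
        with pytest.raises(ValueError):
            ft.compute_psth(pd.DataFrame(columns=["channel", "trial", "time_ms"]),
                            ipi=50.0, bin_ms=0.0)


class TestCountsAndLatencies:
    @pytest.fixture
    def worked_example(self):
        return pd.DataFrame({"channel": [0, 0, 0], "trial": [0, 0, 0],
                             "time_ms": [3.0, 55.0, 58.0]})

    def test_worked_example_counts(self, worked_example):
        c1 = ft.count_evoked_spikes(worked_example, 1, ipi=50.0)
        c2 = ft.count_evoked_spikes(worked_example, 2, ipi=50.0)
        assert c1["count"].iloc[0] == 1
        assert c2["count"].iloc[0] == 2

    def test_worked_example_latencies(self, worked_example):
        l1 = ft.first_spike_latency(worked_example, 1, ipi=50.0)
        l2 = ft.first_spike_latency(worked_example, 2, ipi=50.0)
        assert l1["latency_ms"].iloc[0] == 3.0
        assert l2["latency_ms"].iloc[0] == 5.0

    def test_spike_at_boundary_belongs_to_pulse_two(self):
        spikes = pd.DataFrame({"channel": [0], "trial": [0], "time_ms": [50.0]})
        assert ft.count_evoked_spikes(spikes, 1, 50.0)["count"].iloc[0] == 0
        assert ft.count_evoked_spikes(spikes, 2, 50.0)["count"].iloc[0] == 1

    def test_missing_latency_for_silent_window(self):
        spikes = pd.DataFrame({"channel": [0], "trial": [0], "time_ms": [3.0]})
        l2 = ft.first_spike_latency(spikes, 2, ipi=50.0)
        assert np.isnan(l2["latency_ms"].iloc[0])

    def test_random_table_matches_brute_force(self):
        rng = np.random.default_rng(1)
        spikes = pd.DataFrame({
            "channel": rng.integers(0, 2, 300),
            "trial": rng.integers(0, 8, 300),
            "time_ms": rng.uniform(0, 200, 300),
        })
        ipi = 100.0
        c2 = ft.count_evoked_spikes(spikes, 2, ipi, trials=range(8),
                                    channels=range(2))
        l1 = ft.first_spike_latency(spikes, 1, ipi, trials=range(8),
                                    channels=range(2))
        for ch in range(2):
            for tr in range(8):
                sub = spikes[(spikes["channel"] == ch) & (spikes["trial"] == tr)]
                t = sub["time_ms"].to_numpy()
                expect_c2 = int(np.sum((t >= ipi) & (t < 2 * ipi)))
                got_c2 = int(c2[(c2["channel"] == ch)
                                & (c2["trial"] == tr)]["count"].iloc[0])
                assert got_c2 == expect_c2
                in1 = t[(t >= 0) & (t < ipi)]
                got_l1 = l1[(l1["channel"] == ch)
                            & (l1["trial"] == tr)]["latency_ms"].iloc[0]
                if in1.size:
                    assert got_l1 == in1.min()
                else:
                    assert np.isnan(got_l1)


class TestFeatureTables:
    def test_total_is_sum_of_pulses(self, ipi_spikes, ipi_protocol):
        pt = ft.per_trial_features(ipi_spikes, ipi_protocol, n_channels=3)
        assert (pt["count_total"] == pt["count1"] + pt["count2"]).all()

    def test_pooled_psth_conserves_spikes(self, ipi_spikes, ipi_protocol):
        block = ipi_protocol.trials[ipi_protocol.trials["ipi_ms"] == 100.0]
        sub = ipi_spikes[ipi_spikes["trial"].isin(block["trial"])]
        p = ft.compute_psth(sub, ipi=100.0, channels=[0, 1, 2])
        in_window = ((sub["time_ms"] >= -10) & (sub["time_ms"] < 200)).sum()
        assert p.pooled.sum() == in_window

    def test_silent_trials_present_with_zero_counts(self, truth):
        proto = sd.make_protocol("ipi_variation", ipi_values=[100.0],
                                 n_trials_per_condition=3, seed=0)
        empty = pd.DataFrame(columns=["channel", "trial", "time_ms"])
        pt = ft.per_trial_features(empty, proto, n_channels=2)
        assert len(pt) == 6
        assert (pt["count_total"] == 0).all()
        assert pt["lat1"].isna().all()


class TestNormalization:
    @pytest.fixture
    def two_condition_table(self):
        return pd.DataFrame({
            "channel": [0, 0, 1, 1],
            "ipi_ms": [100.0, 500.0, 100.0, 500.0],
            "intensity": 0.75,
            "n_trials": 5,
            "mean_count1": [2.0, 2.0, 4.0, 4.0],
            "mean_count2": [4.0, 2.0, 6.0, 4.0],
            "mean_count_total": [6.0, 4.0, 10.0, 8.0],
            "mean_lat1": 8.0,
            "mean_lat2": 6.0,
        })

    def test_reference_condition_normalizes_to_one(self, two_condition_table):
        out = ft.normalize_strengths(two_condition_table, "ipi_variation")
        ref = out[out["ipi_ms"] == 500.0]
        assert ref["norm_count_total"].mean() == pytest.approx(1.0)
        # hand-computed: reference global mean total = (4 + 8) / 2 = 6
        assert out["norm_count_total"].tolist() == [1.0, 4 / 6, 10 / 6, 8 / 6]

    def test_scale_invariance(self, two_condition_table):
        doubled = two_condition_table.copy()
        for c in ("mean_count1", "mean_count2", "mean_count_total"):
            doubled[c] *= 2
        a = ft.normalize_strengths(two_condition_table, "ipi_variation")
        b = ft.normalize_strengths(doubled, "ipi_variation")
        for c in ("norm_count1", "norm_count2", "norm_count_total"):
            assert np.allclose(a[c], b[c])

    def test_latencies_untouched(self, two_condition_table):
        out = ft.normalize_strengths(two_condition_table, "ipi_variation")
        assert (out["mean_lat1"] == 8.0).all()
        assert (out["mean_lat2"] == 6.0).all()

    def test_zero_reference_rejected(self, two_condition_table):
        t = two_condition_table.copy()
        t.loc[t["ipi_ms"] == 500.0, "mean_count_total"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            ft.normalize_strengths(t, "ipi_variation")

    def test_intensity_normalization_worked_example(self):
        out = ft.normalize_intensity([70.0, 100.0, 170.0])
        assert np.allclose(out, [70 / 170, 100 / 170, 1.0])
        assert out.max() == 1.0

    def test_single_current_maps_to_one(self):
        assert ft.normalize_intensity([55.0]).tolist() == [1.0]

    def test_nonpositive_current_rejected(self):
        with pytest.raises(ValueError):
            ft.normalize_intensity([100.0, -5.0])
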