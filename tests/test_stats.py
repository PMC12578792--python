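"""ROI aggregation, one-tailed t-tests, effect size, power, FDR, and the model API."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from natattn.reference import FULL_SAMPLE_N, ROI_SUMMARY, closure_table
from natattn.stats import (
    SustainedAttentionModel,
    channelwise_stats,
    cohens_d,
    fdr_adjust,
    load_roi_map,
    one_sample_t,
    posthoc_power,
    roi_aggregate,
    roi_stats,
)


class TestRoiAggregate:
    def test_single_channel_roi_is_identity(self):
        df = pd.DataFrame(
            {"participant": ["a", "b"], "channel": [3, 3], "response": [1.5, -0.5]}
        )
        agg = roi_aggregate(df, {"solo": [3]})
        assert list(agg.value) == [1.5, -0.5]

    def test_participant_missing_all_roi_channels_dropped_from_that_roi_only(self):
        rows = []
        for pid in ("a", "b", "c"):
            for ch in (0, 1, 4, 5):
                if pid == "c" and ch in (4, 5):
                    continue  # c lost both STS-like channels
                rows.append({"participant": pid, "channel": ch, "response": 1.0})
        agg = roi_aggregate(pd.DataFrame(rows), {"mfg": [0, 1], "sts": [4, 5]})
        assert set(agg[agg.roi == "mfg"].participant) == {"a", "b", "c"}
        assert set(agg[agg.roi == "sts"].participant) == {"a", "b"}

    def test_matches_brute_force_over_random_masks(self, rng):
        roi_map = {"r1": [0, 1, 2], "r2": [3, 4]}
        for _ in range(50):
            rows = []
            for pid in ("a", "b", "c", "d"):
                for ch in range(5):
                    if rng.random() < 0.3:
                        continue
                    rows.append(
                        {"participant": pid, "channel": ch, "response": float(rng.normal())}
                    )
            df = pd.DataFrame(rows)
            agg = roi_aggregate(df, roi_map)
            for roi, chans in roi_map.items():
                for pid in "abcd":
                    vals = [
                        r["response"]
                        for r in rows
                        if r["participant"] == pid and r["channel"] in chans
                    ]
                    got = agg[(agg.roi == roi) & (agg.participant == pid)].value
                    if vals:
                        assert got.iloc[0] == pytest.approx(np.mean(vals))
                    else:
                        assert got.empty

    def test_empty_roi_rejected(self):
        df = pd.DataFrame({"participant": ["a"], "channel": [0], "response": [1.0]})
        with pytest.raises(ValueError, match="empty"):
            roi_aggregate(df, {"bad": []})

    def test_default_roi_map_valid(self):
        roi_map = load_roi_map()
        assert set(roi_map) == {"lMFG", "rMFG", "lSTS", "rSTS", "lTPJ", "rTPJ"}
        assert sum(len(v) for v in roi_map.values()) == 22


class TestOneSampleT:
    def test_symmetric_values_give_null(self):
        t, df, p = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_p_matches_numerically_integrated_t_density(self, rng):
        for n in (5, 11, 12):
            x = rng.normal(0.3, 1.0, size=n)
            t, df, p = one_sample_t(x)
            dens = lambda u: sps.t.pdf(u, df)
            quad, _ = integrate.quad(dens, t, np.inf)
            assert p == pytest.approx(quad, abs=1e-8)

    def test_less_alternative_is_lower_tail(self):
        x = [-1.0, -2.0, -1.5, -0.5]
        t, df, p_less = one_sample_t(x, "less")
        assert t < 0 and p_less < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0])


class TestCohensD:
    def test_d_equals_t_over_sqrt_n(self, rng):
        for _ in range(20):
            x = rng.normal(0.2, 1.0, size=rng.integers(3, 30))
            t, _, _ = one_sample_t(x)
            assert cohens_d(x) == pytest.approx(t / np.sqrt(len(x)))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cohens_d([3.0, 3.0, 3.0])


class TestPosthocPower:
    def test_null_effect_gives_alpha(self):
        assert posthoc_power(0.0, 12) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_effect_and_n(self):
        ds = np.linspace(0.0, 2.0, 9)
        powers = [posthoc_power(d, 12) for d in ds]
        assert np.all(np.diff(powers) > 0)
        ns = [4, 8, 12, 24, 48]
        powers_n = [posthoc_power(0.5, n) for n in ns]
        assert np.all(np.diff(powers_n) > 0)

    def test_matches_monte_carlo(self, rng):
        """10^5 simulated experiments at d=0.68, n=11 vs the analytic value."""
        d, n = 0.68, 11
        x = rng.normal(d, 1.0, size=(100_000, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        mc = np.mean(t > sps.t.ppf(0.95, n - 1))
        assert posthoc_power(d, n) == pytest.approx(mc, abs=0.01)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # q_i = min_{j>=i} p_j * m / j -> all 0.04 for this ladder
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_order_preserved(self, rng):
        p = rng.uniform(size=20)
        q = fdr_adjust(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_storey_mode_scales_by_pi0(self):
        q_bh = fdr_adjust([0.01, 0.2, 0.5])
        q_st = fdr_adjust([0.01, 0.2, 0.5], method="storey", pi0=0.5)
        np.testing.assert_allclose(q_st, q_bh * 0.5)
        with pytest.raises(ValueError, match="pi0"):
            fdr_adjust([0.5], method="storey")

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0


class TestPublishedTableClosure:
    """Recomputing t, p, d and power from the published per-ROI (M, SD, df)."""

    def test_t_matches_to_3_decimals(self):
        tab = closure_table()
        np.testing.assert_allclose(tab.t_calc.round(3), tab.t)

    def test_one_tailed_p_matches_to_3_decimals(self):
        tab = closure_table()
        np.testing.assert_allclose(tab.p_calc.round(3), tab.p)

    def test_d_matches_to_2_decimals(self):
        tab = closure_table()
        np.testing.assert_allclose(tab.d_calc.round(2), tab.d)

    def test_power_matches_to_2_decimals_at_full_sample_n(self):
        tab = closure_table()
        np.testing.assert_allclose(tab.power_calc.round(2), tab.power)

    def test_lsts_row_values(self):
        row = ROI_SUMMARY.set_index("roi").loc["lSTS"]
        t, df, p = one_sample_t(
            _sample_with_moments(row["mean"], row["sd"], int(row.df) + 1)
        )
        assert round(t, 3) == 2.263
        assert round(p, 3) == 0.024
        assert FULL_SAMPLE_N == 12


def _sample_with_moments(mean, sd, n, seed=0):
    """Any n-vector with exactly the requested sample mean and SD."""
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestChannelwise:
    def test_null_type_one_error_near_alpha(self, rng):
        """44 independent null channels x 300 repeats: ~5% uncorrected rejections."""
        rejections = []
        for _ in range(300):
            x = rng.normal(size=(12, 44))
            df = pd.DataFrame(
                [
                    {"participant": f"p{i}", "channel": c, "response": x[i, c]}
                    for i in range(12)
                    for c in range(44)
                ]
            )
            tab = channelwise_stats(df)
            rejections.append((tab.p < 0.05).mean())
        rate = np.mean(rejections)
        assert 0.04 < rate < 0.06

    def test_active_channels_rank_top(self, study):
        import natattn as na

        cfg, hb, events, _ = study
        shifted = na.exclude_short_isi(na.apply_shift(events))
        blocks = []
        for pid, series in hb.items():
            blocks.extend(
                na.extract_blocks(series, [e for e in shifted if e.participant_id == pid])
            )
        resp = na.peak_window_mean(blocks)
        tab = channelwise_stats(resp).sort_values("t", ascending=False)
        assert set(tab.head(3).channel) == set(cfg.active_channels)

    def test_all_zero_responses_rejected(self):
        df = pd.DataFrame(
            {"participant": list("abcd"), "channel": [0] * 4, "response": [0.0] * 4}
        )
        with pytest.raises(ValueError):
            channelwise_stats(df)


class TestModelApi:
    def _responses(self, rng, effect_channels=(8, 9, 10)):
        rows = []
        for i in range(12):
            for ch in range(44):
                mu = 3e-7 if ch in effect_channels else 0.0
                rows.append(
                    {"participant": f"p{i:02d}", "channel": ch, "response": rng.normal(mu, 2e-7)}
                )
        return pd.DataFrame(rows)

    def test_fit_returns_tables_and_summary(self, rng):
        import natattn as na

        model = SustainedAttentionModel(self._responses(rng), adjacency=na.load_adjacency())
        res = model.fit(n_perm=200, seed=3)
        assert set(res.roi_table.roi) == set(load_roi_map())
        assert len(res.channel_table) == 44
        assert "lSTS" in res.significant_rois()
        text = res.summary()
        assert "Cluster" in text and "ROI" in text

    def test_hbr_direction_flips(self, rng):
        resp = self._responses(rng)
        resp["response"] = -resp["response"]
        res = SustainedAttentionModel(resp, chromophore="hbr").fit()
        assert res.roi_table.set_index("roi").loc["lSTS", "p"] < 0.05

    def test_roi_stats_requires_data_for_every_roi(self):
        df = pd.DataFrame(
            {"participant": ["a", "b", "c"], "channel": [0, 0, 0], "response": [1.0, 2.0, 0.5]}
        )
        with pytest.raises(ValueError, match="no data"):
            roi_stats(df, {"mfg": [0], "sts": [5]})
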