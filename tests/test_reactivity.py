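import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmsmap as d
from conftest import counts_from_rates


def profile_from_raw(rates, base="A", transcript_id="t1"):
    """Unmasked raw-rate profile with exact float rates (no count rounding)."""
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    bases = list(base * n) if len(base) == 1 else list(base)
    return pd.DataFrame(
        {
            "transcript_id": transcript_id,
            "pos": np.arange(1, n + 1),
            "ref_base": bases,
            "channel": [{"A": "AC", "C": "AC", "G": "GU", "U": "GU"}[b]
                        for b in bases],
            "raw_rate": rates,
            "normalized": np.nan,
            "mask_reason": "none",
        }
    )


class TestRawRates:
    def test_rate_arithmetic(self):
        counts = pd.DataFrame(
            [["t1", 5, "A", 5000, 40, 10]],
            columns=["transcript_id", "pos", "ref_base", "coverage",
                     "sub_count", "del_count"],
        )
        profile = d.compute_raw_rates(counts, min_coverage=2500)
        assert profile.loc[0, "raw_rate"] == pytest.approx(0.01)
        assert profile.loc[0, "channel"] == "AC"
        assert profile.loc[0, "mask_reason"] == "none"

    @pytest.mark.parametrize(
        "coverage, expected", [(2499, "low_coverage"), (2500, "none")]
    )
    def test_coverage_threshold_is_at_least_2500(self, coverage, expected):
        counts = counts_from_rates([0.01], "A", coverage=coverage)
        profile = d.compute_raw_rates(counts)
        assert profile.loc[0, "mask_reason"] == expected

    def test_mask_reasons(self):
        counts = counts_from_rates([0.01] * 6, "AACGUC")
        masks = {"t1": d.MaskSet(primer_ranges=[(1, 1)], editing_sites=[3],
                                 modified_sites=[5])}
        profile = d.compute_raw_rates(counts, masks)
        assert list(profile["mask_reason"]) == [
            "primer", "none", "editing_site", "none", "modified_site", "none"
        ]
        assert profile.loc[profile["mask_reason"] != "none", "raw_rate"].isna().all()

    def test_duplicate_position_rejected(self):
        counts = pd.concat([counts_from_rates([0.01], "A")] * 2,
                           ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            d.compute_raw_rates(counts)


class TestNormalization:
    def test_percentile_window_oracle(self):
        """100 rates equal to 1..100 x 1e-3: divisor is the mean of ranks
        91..99 (= 95 x 1e-3), so the maximum normalized value is 100/95."""
        rates = np.arange(1, 101) * 1e-3
        profile = d.normalize_two_channel(
            d.compute_raw_rates(counts_from_rates(rates, "A" * 100)))
        status = profile.attrs["normalization"][("t1", "AC")]
        assert status["divisor"] == pytest.approx(95e-3, rel=1e-12)
        assert profile["normalized"].max() == pytest.approx(100 / 95, rel=1e-9)

    def test_scale_invariance(self):
        """normalize(k*x) == normalize(x) for any k > 0 (raw rates set
        directly so no count quantization interferes)."""
        rng = np.random.default_rng(0)
        base = rng.gamma(0.5, 0.01, size=80)
        ref = d.normalize_two_channel(profile_from_raw(base, "C"))
        for k in rng.uniform(0.1, 10, size=10):
            scaled = d.normalize_two_channel(profile_from_raw(base * k, "C"))
            np.testing.assert_allclose(scaled["normalized"], ref["normalized"],
                                       rtol=1e-9)

    def test_window_mean_is_one_after_normalization(self, rrn16_sim):
        profile = d.normalize_two_channel(d.compute_raw_rates(rrn16_sim["counts"]))
        for (tid, ch), status in profile.attrs["normalization"].items():
            assert status["status"] == "ok"
            sel = (profile["transcript_id"] == tid) & (profile["channel"] == ch)
            v = profile.loc[sel, "normalized"].dropna().to_numpy()
            lo, hi = np.percentile(v, 90), np.percentile(v, 99)
            window = v[(v > lo) & (v <= hi)]
            assert abs(window.mean() - 1.0) < 1e-9

    def test_all_equal_rates_normalize_to_one(self):
        profile = d.normalize_two_channel(
            d.compute_raw_rates(counts_from_rates([0.004] * 30, "A" * 30)))
        np.testing.assert_allclose(profile["normalized"], 1.0)

    def test_channels_normalized_separately(self):
        """Permuting G/U raw rates never changes any A/C normalized value."""
        rng = np.random.default_rng(1)
        ac = rng.gamma(1.0, 0.01, size=50)
        gu = rng.gamma(1.0, 0.003, size=50)
        bases = "A" * 50 + "G" * 50
        prof1 = d.normalize_two_channel(d.compute_raw_rates(
            counts_from_rates(np.r_[ac, gu], bases)))
        prof2 = d.normalize_two_channel(d.compute_raw_rates(
            counts_from_rates(np.r_[ac, rng.permutation(gu)], bases)))
        np.testing.assert_array_equal(
            prof1.loc[prof1["channel"] == "AC", "normalized"],
            prof2.loc[prof2["channel"] == "AC", "normalized"],
        )

    def test_too_few_positions_flags_channel(self):
        profile = d.normalize_two_channel(
            d.compute_raw_rates(counts_from_rates([0.01] * 5, "A" * 5)))
        status = profile.attrs["normalization"][("t1", "AC")]
        assert status["status"] == "too_few_positions"
        assert profile["normalized"].isna().all()

    def test_all_zero_channel_flagged_not_scaled(self):
        profile = d.normalize_two_channel(
            d.compute_raw_rates(counts_from_rates([0.0] * 30, "A" * 30)))
        assert (profile.attrs["normalization"][("t1", "AC")]["status"]
                == "zero_divisor")
        assert profile["normalized"].isna().all()


class TestWinsorization:
    def test_outlier_capped_others_unchanged(self):
        rates = np.linspace(0.001, 0.01, 99).tolist() + [0.5]
        profile = d.normalize_two_channel(
            d.compute_raw_rates(counts_from_rates(rates, "A" * 100)))
        wins = d.winsorize_99(profile)
        v, w = profile["normalized"].to_numpy(), wins["normalized"].to_numpy()
        cap = np.percentile(v, 99, method="lower")
        assert w[-1] == pytest.approx(cap)
        np.testing.assert_array_equal(w[:-1][v[:-1] <= cap], v[:-1][v[:-1] <= cap])
        assert w.max() <= cap + 1e-12

    def test_idempotent(self, rrn16_sim):
        once = d.winsorize_99(d.normalize_two_channel(
            d.compute_raw_rates(rrn16_sim["counts"])))
        twice = d.winsorize_99(once)
        np.testing.assert_allclose(twice["normalized"], once["normalized"],
                                   rtol=1e-12)

    def test_constant_values_unchanged(self):
        profile = d.normalize_two_channel(
            d.compute_raw_rates(counts_from_rates([0.01] * 30, "A" * 30)))
        wins = d.winsorize_99(profile)
        np.testing.assert_array_equal(wins["normalized"], profile["normalized"])


class TestPipeline:
    def test_deterministic(self, rrn16_sim):
        a = d.reactivity_pipeline(rrn16_sim["counts"])
        b = d.reactivity_pipeline(rrn16_sim["counts"])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_counts_give_empty_profile(self):
        profile = d.reactivity_pipeline(pd.DataFrame(
            columns=["transcript_id", "pos", "ref_base", "coverage",
                     "sub_count", "del_count"]))
        assert profile.empty

    def test_masked_positions_never_normalized(self, rrn16_sim):
        counts = rrn16_sim["counts"]
        masks = {"rrn16_like": d.MaskSet(primer_ranges=[(1, 40)],
                                         editing_sites=[100, 200])}
        profile = d.reactivity_pipeline(counts, masks)
        masked = profile["mask_reason"] != "none"
        assert masked.sum() >= 42
        assert profile.loc[masked, "normalized"].isna().all()
        assert profile.loc[masked, "raw_rate"].isna().all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=0.2), min_size=25,
                    max_size=60))
    def test_normalized_values_nonnegative_and_finite(self, rates):
        profile = d.reactivity_pipeline(counts_from_rates(rates, "A" * len(rates)))
        vals = profile["normalized"].dropna()
        assert (vals >= 0).all()
        assert np.isfinite(vals).all()
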