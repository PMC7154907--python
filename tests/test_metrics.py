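import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmsmap as d
from test_reactivity import profile_from_raw


def brute_force_gini(x, form="population"):
    x = np.asarray(x, dtype=float)
    n = x.size
    total = np.abs(x[:, None] - x[None, :]).sum()
    denom = 2 * n * n * x.mean() if form == "population" else 2 * n * (n - 1) * x.mean()
    return total / denom


def brute_force_auc(scores, labels):
    """Concordant-pair counting (ties worth 1/2)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestResolveRegions:
    @staticmethod
    def regions_for(start, length=400, cds_end=None):
        t = d.Transcript("t", "A" * length)
        cds_end = cds_end or start + 89
        ann = d.GeneAnnotation("g", "t", start, cds_end)
        return {r.kind: r for r in d.resolve_regions(ann, t)}

    def test_windows_relative_to_start_codon(self):
        r = self.regions_for(100)
        assert (r["tir"].start, r["tir"].end) == (75, 104)
        assert (r["sd_window"].start, r["sd_window"].end) == (78, 98)
        assert (r["start_codon"].start, r["start_codon"].end) == (100, 102)
        assert (r["cds"].start, r["cds"].end) == (100, 189)
        assert r["tir"].length == 30 and r["sd_window"].length == 21

    def test_boundary_start_26_gives_full_tir(self):
        r = self.regions_for(26)
        assert (r["tir"].start, r["tir"].end) == (1, 30)
        assert not r["tir"].truncated

    def test_short_utr_truncates_and_flags(self):
        r = self.regions_for(10)
        assert (r["tir"].start, r["tir"].end) == (1, 14)
        assert r["tir"].truncated

    def test_no_relative_position_zero(self):
        from dmsmap.metrics import rel_to_abs
        assert rel_to_abs(100, -1) == 99
        assert rel_to_abs(100, 1) == 100
        with pytest.raises(ValueError):
            rel_to_abs(100, 0)

    def test_pure_function_of_annotation(self):
        a = self.regions_for(100)
        b = self.regions_for(100)
        assert a == b


class TestRegionMean:
    def test_single_adenosine(self):
        profile = profile_from_raw([0.1, 0.2, 0.3], "AUG")
        profile["normalized"] = [0.9, 0.1, 0.2]
        region = d.RegionSpec("g", "start_codon", 1, 3)
        mean, n = d.region_mean_reactivity(profile, region, "A")
        assert (mean, n) == (0.9, 1)

    def test_ac_mean(self):
        profile = profile_from_raw([0.1] * 4, "ACGU")
        profile["normalized"] = [0.2, 0.6, 5.0, 5.0]
        region = d.RegionSpec("g", "sd_window", 1, 4)
        mean, n = d.region_mean_reactivity(profile, region, "AC")
        assert mean == pytest.approx(0.4) and n == 2

    def test_all_masked_gives_missing_not_zero(self):
        profile = profile_from_raw([0.1] * 3, "ACA")
        profile["normalized"] = 1.0
        profile["mask_reason"] = "primer"
        mean, n = d.region_mean_reactivity(
            profile, d.RegionSpec("g", "tir", 1, 3), "AC")
        assert np.isnan(mean) and n == 0


class TestGini:
    def test_constant_values_give_zero(self):
        assert d.gini([3.0] * 10).value == pytest.approx(0.0, abs=1e-15)

    def test_population_form_of_0_1(self):
        assert d.gini([0.0, 1.0]).value == pytest.approx(0.5, rel=1e-12)

    def test_sample_form_of_0_1(self):
        assert d.gini([0.0, 1.0], form="sample").value == pytest.approx(1.0)

    @pytest.mark.parametrize("form", ["population", "sample"])
    def test_matches_brute_force(self, form):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.gamma(0.7, 1.0, size=rng.integers(2, 200))
            assert d.gini(x, form=form).value == pytest.approx(
                brute_force_gini(x, form), abs=1e-12)

    def test_maximal_concentration_approaches_one(self):
        x = np.zeros(10000)
        x[-1] = 1.0
        assert d.gini(x).value == pytest.approx(1.0, abs=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=2,
                    max_size=50),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, values, k):
        x = np.asarray(values)
        assert d.gini(k * x).value == pytest.approx(d.gini(x).value,
                                                    abs=1e-9)

    @pytest.mark.parametrize("bad", [[1.0], [0.0, 0.0], [-1.0, 2.0]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            d.gini(bad)


class TestAccessibilityLabels:
    def test_positive_requires_unpaired_and_accessible(self):
        s = d.ReferenceStructure(
            "t", np.array([0, 0, 4, 3]),
            np.array([True, False, True, False]))
        labels = d.accessibility_labels(s)
        # unpaired+accessible, unpaired+buried, paired+accessible, paired+buried
        assert list(labels) == [True, False, False, False]


class TestRoc:
    def test_perfect_separation(self):
        profile = profile_from_raw([0.1] * 6, "A" * 6)
        profile["normalized"] = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        assert d.roc_auc(profile, labels, "A").auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        n = 4000
        profile = profile_from_raw(rng.random(n), "A")
        profile["normalized"] = rng.random(n)
        labels = rng.random(n) < 0.5
        auc = d.roc_auc(profile, labels, "A").auc
        se = np.sqrt(auc * (1 - auc) * 3 / n)  # conservative AUC SE bound
        assert abs(auc - 0.5) < 3 * se

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(5)
        for trial in range(40):
            n = int(rng.integers(4, 51))
            scores = rng.random(n)
            if trial % 2:  # force ties half the time
                scores = np.round(scores, 1)
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=max(1, n // 3), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            profile = profile_from_raw(scores, "A")
            profile["normalized"] = scores
            auc = d.roc_auc(profile, labels, "A").auc
            assert auc == pytest.approx(brute_force_auc(scores, labels),
                                        abs=1e-12)

    def test_score_negation_flips_auc(self):
        rng = np.random.default_rng(9)
        scores = rng.random(60)
        labels = rng.random(60) < 0.4
        p1 = profile_from_raw(scores, "A")
        p1["normalized"] = scores
        p2 = profile_from_raw(scores, "A")
        p2["normalized"] = 1.0 - scores  # order-reversing, stays >= 0
        a1 = d.roc_auc(p1, labels, "A").auc
        a2 = d.roc_auc(p2, labels, "A").auc
        assert a1 == pytest.approx(1.0 - a2, abs=1e-12)

    def test_degenerate_labels_rejected(self):
        profile = profile_from_raw([0.1] * 4, "A" * 4)
        profile["normalized"] = 0.5
        with pytest.raises(ValueError, match="positive"):
            d.roc_auc(profile, np.ones(4, bool), "A")

    def test_curve_monotone_and_auc_is_trapezoid_area(self, rrn16_sim):
        labels = d.accessibility_labels(rrn16_sim["structure"])
        roc = d.roc_auc(rrn16_sim["profile"], labels, "AC")
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-12)

    def test_ac_auc_exceeds_gu_auc_on_simulated_control(self):
        """The two-channel simulation reproduces the channel ordering: the
        strongly separated A/C channel validates better than G/U."""
        for seed in (21, 22, 23):
            t, s = d.rrn16_like(seed=seed)
            cfg = d.SimulationConfig(seed=seed)
            track = d.assign_true_rates(t, s, cfg)
            profile = d.reactivity_pipeline(d.simulate_counts(track, cfg, seed))
            labels = d.accessibility_labels(s)
            auc = {ch: d.roc_auc(profile, labels, ch).auc for ch in ("AC", "GU")}
            assert auc["AC"] > auc["GU"]


class TestCompareConditions:
    def test_identical_profiles_give_zero_differences(self, rrn16_sim):
        t = rrn16_sim["transcript"]
        ann = d.GeneAnnotation("g", t.id, 61, 61 + 299 * 3 + 2)
        regions = d.resolve_regions(ann, t)
        table = d.compare_conditions(rrn16_sim["profile"], rrn16_sim["profile"],
                                     regions)
        ok = table["flag"] == "ok"
        assert ok.any()
        assert (table.loc[ok, "mean_diff"].abs() < 1e-12).all()
        gd = table["gini_diff"].dropna()
        assert (gd.abs() < 1e-12).all()

    def test_footprint_release_raises_start_codon_reactivity(self):
        fx = d.footprint_fixture(seed=8)
        cfg = d.SimulationConfig(seed=8)
        tables = d.make_paired_conditions(fx["transcript"], fx["structure"],
                                          fx["footprint_range"], cfg)
        pv = d.reactivity_pipeline(tables["in_vivo"])
        pt = d.reactivity_pipeline(tables["in_vitro"])
        regions = d.resolve_regions(fx["annotation"], fx["transcript"])
        table = d.compare_conditions(pv, pt, regions).set_index("region")
        assert table.loc["start_codon", "mean_diff"] > 0

    def test_flat_rates_less_concentrated_than_structured(self):
        """Gini of an unstructured (flat-rate) profile is below the Gini of a
        structured one — computed on the configured rate tracks themselves."""
        t, s = d.rrn16_like(seed=2)
        cfg = d.SimulationConfig(seed=2)
        structured = d.assign_true_rates(t, s, cfg).rates
        flat = np.full_like(structured, cfg.rate_unpaired_AC)
        flat[:10] = cfg.rate_unpaired_AC * 1.01  # keep dispersion nonzero
        assert d.gini(flat).value < d.gini(structured).value
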