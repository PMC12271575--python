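import numpy as np
import pandas as pd
import pytest

from metageno import genodata, riskstrat, simulate
from metageno.model import BackboneConfig, MetaGenoModel
from metageno.riskstrat import (bin_hazard_ratios, c_index,
                                c_index_by_task_combination,
                                chromosome_attention_report,
                                cumulative_incidence, risk_decile_mask,
                                to_percentiles)


def brute_force_c_index(scores, age, event):
    """Independent O(n^2) enumeration of permissible pairs."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if age[j] > age[i]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestToPercentiles:
    def test_midrank_on_four_reference_points(self):
        strata = to_percentiles([2.5], [1, 2, 3, 4])
        assert strata.percentile[0] == pytest.approx(50.0)

    def test_above_all_reference(self):
        strata = to_percentiles([99.0], [1, 2, 3, 4])
        assert strata.percentile[0] == pytest.approx(100.0)

    def test_reference_median_score(self):
        ref = np.arange(101.0)
        strata = to_percentiles([50.0], ref)
        assert abs(strata.percentile[0] - 50.0) <= 100 / (2 * len(ref))

    def test_monotone_in_score(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=500)
        scores = np.sort(rng.normal(size=200))
        pct = to_percentiles(scores, ref).percentile
        assert (np.diff(pct) >= 0).all()

    def test_every_sample_gets_exactly_one_tertile(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=300)
        strata = to_percentiles(rng.normal(size=300), ref)
        assert all(t in riskstrat.TERTILES for t in strata.tertile)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            to_percentiles([1.0], [])


def survival_frame(age, event):
    return pd.DataFrame({"age_end": age, "event_is": event})


class TestBinHazardRatios:
    def test_null_hazard_hr_near_one(self):
        rng = np.random.default_rng(2)
        n = 4000
        scores = rng.normal(size=n)
        age = 40 + rng.exponential(20, n)
        event = (rng.random(n) < 0.5).astype(int)
        strata = to_percentiles(scores, scores)
        hr = bin_hazard_ratios(strata, survival_frame(age, event), "tertiles")
        top = hr[hr.bin == "67-100"].iloc[0]
        assert 0.85 < top.hr < 1.15
        assert top.ci_low < 1.0 < top.ci_high

    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        group = (np.arange(n) % 2).astype(float)  # HR 2 for group 1
        age = 40 + rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * group)))
        event = np.ones(n, dtype=int)
        # build strata so that group 1 lands in the top tertile-like bin
        strata = to_percentiles(group + rng.normal(0, 1e-6, n), group)
        hr = bin_hazard_ratios(strata, survival_frame(age, event), "tertiles",
                               reference_bin="0-33")
        est = hr[hr.bin == "67-100"].iloc[0].hr
        assert 1.8 <= est <= 2.2

    def test_monotone_risk_monotone_hrs(self):
        rng = np.random.default_rng(4)
        n = 6000
        score = rng.random(n)
        lam = 0.02 * np.exp(1.5 * score)
        age = 40 + rng.exponential(1.0 / lam)
        event = np.ones(n, dtype=int)
        strata = to_percentiles(score, score)
        hr = bin_hazard_ratios(strata, survival_frame(age, event), "tertiles")
        mid = hr[hr.bin == "33-67"].iloc[0].hr
        top = hr[hr.bin == "67-100"].iloc[0].hr
        assert 1.0 < mid < top

    def test_zero_event_bin_reported_undefined(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        age = 40 + rng.exponential(10, 100)
        event = np.concatenate([np.ones(50, int), np.zeros(50, int)])
        strata = to_percentiles(scores, scores)
        with pytest.warns(UserWarning):
            hr = bin_hazard_ratios(strata, survival_frame(age, event),
                                   "tertiles")
        assert np.isnan(hr[hr.bin == "67-100"].iloc[0].hr)

    def test_percentile_scheme_has_expected_bins(self):
        rng = np.random.default_rng(6)
        n = 3000
        score = rng.random(n)
        age = 40 + rng.exponential(1.0 / (0.02 * np.exp(score)), n)
        strata = to_percentiles(score, score)
        hr = bin_hazard_ratios(strata, survival_frame(age, np.ones(n, int)),
                               "percentiles")
        assert set(hr.bin) == set(riskstrat.PERCENTILE_BINS) - {"reference 45-55"}


class TestCIndex:
    def test_perfect_anti_ranking(self):
        age = np.array([60.0, 70.0, 80.0, 90.0])
        scores = np.array([4.0, 3.0, 2.0, 1.0])  # earliest event, highest score
        assert c_index(scores, age, np.ones(4, dtype=int)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        n = 5000
        scores = rng.random(n)
        age = 40 + rng.exponential(20, n)
        event = (rng.random(n) < 0.4).astype(int)
        assert abs(c_index(scores, age, event) - 0.5) < 0.02

    def test_hand_fixture_matches_enumeration(self):
        # events at 60 and 70; censored at 65 and 80
        age = np.array([60.0, 70.0, 65.0, 80.0])
        event = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.2])
        assert c_index(scores, age, event) == pytest.approx(
            brute_force_c_index(scores, age, event))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = rng.integers(0, 4, n) / 3.0
        age = np.round(40 + rng.exponential(20, n), 1)
        event = (rng.random(n) < 0.5).astype(int)
        if event.sum() == 0:
            pytest.skip("no events drawn")
        assert c_index(scores, age, event) == pytest.approx(
            brute_force_c_index(scores, age, event))

    def test_no_permissible_pairs_rejected(self):
        with pytest.raises(ValueError):
            c_index([1.0, 2.0], [50.0, 40.0], [0, 0])

    def test_combination_table_one_row_per_combo(self):
        rng = np.random.default_rng(8)
        n = 200
        surv = survival_frame(40 + rng.exponential(20, n),
                              (rng.random(n) < 0.5).astype(int))
        combos = [("IS",), ("IS", "HT"), ("IS", "AF"), ("all",)]
        table = c_index_by_task_combination(
            lambda combo: rng.random(n), combos, surv)
        assert len(table) == len(combos)
        assert "c_index" in table.columns


class TestCumulativeIncidence:
    def test_no_events_identically_zero(self):
        surv = survival_frame([50.0, 60.0, 70.0], [0, 0, 0])
        (est,) = cumulative_incidence(surv, {"all": np.ones(3, bool)})
        assert (est.cumulative_incidence == 0).all()

    def test_hand_worked_km_steps(self):
        # events at 60 and 70, one censored later at 75:
        # S(60) = 2/3, S(70) = 2/3 * 1/2 -> incidence 1/3 then 2/3
        surv = survival_frame([60.0, 70.0, 75.0], [1, 1, 0])
        (est,) = cumulative_incidence(surv, {"all": np.ones(3, bool)})
        by_time = dict(zip(est.times, est.cumulative_incidence))
        assert by_time[60.0] == pytest.approx(1 / 3)
        assert by_time[70.0] == pytest.approx(2 / 3)

    def test_km_without_censoring_equals_empirical_cdf(self):
        rng = np.random.default_rng(9)
        age = np.sort(40 + rng.exponential(15, 100))
        surv = survival_frame(age, np.ones(100, int))
        (est,) = cumulative_incidence(surv, {"all": np.ones(100, bool)})
        for t, ci in zip(est.times, est.cumulative_incidence):
            if t > 0:
                assert ci == pytest.approx((age <= t).mean())

    def test_harder_hazard_group_dominates(self):
        rng = np.random.default_rng(10)
        n = 3000
        group = np.arange(n) % 2 == 1
        lam = np.where(group, 0.06, 0.02)
        surv = survival_frame(40 + rng.exponential(1.0 / lam),
                              np.ones(n, int))
        hard, easy = cumulative_incidence(
            surv, {"hard": group, "easy": ~group})
        grid = np.linspace(41, 80, 50)
        hard_interp = np.interp(grid, hard.times, hard.cumulative_incidence)
        easy_interp = np.interp(grid, easy.times, easy.cumulative_incidence)
        assert (hard_interp >= easy_interp - 1e-9).all()

    def test_empty_group_skipped_with_warning(self):
        surv = survival_frame([50.0], [1])
        with pytest.warns(UserWarning):
            out = cumulative_incidence(surv, {"none": np.zeros(1, bool)})
        assert out == []

    def test_incidence_monotone_and_bounded(self, null_cohort):
        _, cohort = null_cohort
        surv = survival_frame(cohort.age_end, cohort.event_is)
        (est,) = cumulative_incidence(surv, {"all": np.ones(len(surv), bool)})
        assert (np.diff(est.cumulative_incidence) >= -1e-12).all()
        assert est.cumulative_incidence.min() >= 0
        assert est.cumulative_incidence.max() <= 1

    def test_risk_decile_mask(self):
        pct = np.array([1.0, 50.0, 95.0])
        np.testing.assert_array_equal(risk_decile_mask(pct, top=True),
                                      [False, False, True])
        np.testing.assert_array_equal(risk_decile_mask(pct, top=False),
                                      [True, False, False])


class TestAttentionReport:
    @pytest.fixture()
    def untrained_model(self):
        spec = simulate.make_null_spec(n_variants=44, seed=30)
        G = simulate.simulate_genotypes(32, spec)
        states, V = genodata.encode_states(G.dosages)
        groups = genodata.group_by_chromosome(G.panel)
        model = MetaGenoModel(groups, d=4, V=V,
                              backbone=BackboneConfig(depth=1, width=8,
                                                      heads=2, seed=0),
                              seed=0)
        return model, states

    def test_contract_22_entries_minmax(self, untrained_model):
        model, states = untrained_model
        rep = chromosome_attention_report(model, states)
        assert rep.raw.shape == (22,)
        assert rep.normalized.max() == pytest.approx(1.0)
        assert rep.normalized.min() == pytest.approx(0.0)

    def test_chromembed_source_available(self, untrained_model):
        model, states = untrained_model
        rep = chromosome_attention_report(model, states, source="chromembed")
        assert rep.raw.shape == (22,)

    def test_symmetric_untrained_chromembed_sum_degenerates(self):
        # equal SNP counts + identical parameters: the raw attention sum per
        # chromosome is exactly m everywhere -> degenerate report, flagged
        spec = simulate.make_null_spec(n_variants=44, seed=31)
        G = simulate.simulate_genotypes(16, spec)
        states, V = genodata.encode_states(G.dosages)
        groups = genodata.group_by_chromosome(G.panel)
        model = MetaGenoModel(groups, d=4, V=V,
                              backbone=BackboneConfig(depth=1, width=8,
                                                      heads=2, seed=0),
                              seed=0)
        # neutralize per-SNP identity so every chromosome looks identical
        model.embedding.params.P.data[:] = 0.0
        incoming_total = np.zeros(22)
        from metageno.autodiff import no_grad
        with no_grad():
            model.forward_logits(states, keep_attention=True)
        for gi, alpha, v in model.embedding.last_attention:
            incoming_total[gi] = alpha.sum() / len(states)
        np.testing.assert_allclose(incoming_total, 2.0, atol=1e-9)  # m = 2

    def test_non_chromosome_wise_mode_rejected(self):
        spec = simulate.make_null_spec(n_variants=44, seed=32)
        G = simulate.simulate_genotypes(8, spec)
        states, V = genodata.encode_states(G.dosages)
        groups = genodata.group_by_chromosome(G.panel)
        model = MetaGenoModel(groups, d=4, V=V, mode="one_hot",
                              backbone=BackboneConfig(depth=1, width=8,
                                                      heads=2, seed=0), seed=0)
        with pytest.raises(ValueError):
            chromosome_attention_report(model, states)

    def test_depth_zero_backbone_requires_chromembed_source(self):
        spec = simulate.make_null_spec(n_variants=44, seed=33)
        G = simulate.simulate_genotypes(8, spec)
        states, V = genodata.encode_states(G.dosages)
        groups = genodata.group_by_chromosome(G.panel)
        model = MetaGenoModel(groups, d=4, V=V,
                              backbone=BackboneConfig(depth=0, seed=0), seed=0)
        with pytest.raises(ValueError, match="depth"):
            chromosome_attention_report(model, states)
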