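"""Threshold-sweep ROC statistic, permutation null and population
selectivity, checked against independent pair-count and exhaustive
enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmsephys import (BehaviorGenConfig, SelectivityConfig, UnitGenConfig,
                      assign_preferred, compare_conditions, permutation_test,
                      population_selectivity, roc_timecourse, roc_value,
                      simulate_population, simulate_session, simulate_unit)
from dmsephys.spiketrains import EpochWindow
from dmsephys.synth import mixture_sampler, passive_preset


def pair_count_auc(a, b):
    """Independent oracle: Mann-Whitney pair-count AUC, ties half credit."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return wins / (a.size * b.size)


def exhaustive_two_sided_p(pref, nonpref, n_thresholds=12):
    """Independent oracle: enumerate every split of the pooled trials into
    groups of the original sizes and form the two-sided tail probability."""
    values = np.concatenate([pref, nonpref])
    n, n1 = values.size, len(pref)
    actual = roc_value(pref, nonpref, n_thresholds)
    null = []
    for idx in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        null.append(roc_value(values[mask], values[~mask], n_thresholds))
    null = np.asarray(null)
    eps = 1e-12
    tail = min(np.sum(null >= actual - eps), np.sum(null <= actual + eps))
    return min(1.0, 2.0 * tail / null.size)


class TestRocValue:
    def test_complete_separation_is_one(self):
        assert roc_value([10, 12, 11], [1, 2, 3]) == 1.0

    def test_reversed_separation_is_zero(self):
        assert roc_value([1, 2, 3], [10, 12, 11]) == 0.0

    def test_identical_samples_give_half(self):
        assert roc_value([5, 7], [5, 7]) == 0.5

    def test_degenerate_range_gives_half(self):
        assert roc_value([4, 4, 4], [4, 4]) == 0.5

    def test_tied_example_close_to_pair_count_oracle(self):
        pref, nonpref = [3, 5, 5, 8], [4, 5, 6, 6]
        assert abs(roc_value(pref, nonpref) - pair_count_auc(pref, nonpref)) < 0.06

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roc_value([], [1, 2])

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_swap_antisymmetry(self, data):
        n1 = data.draw(st.integers(3, 25))
        n2 = data.draw(st.integers(3, 25))
        lam = data.draw(st.floats(0.2, 4.0))
        seed = data.draw(st.integers(0, 2**20))
        rng = np.random.default_rng(seed)
        a = rng.poisson(lam, n1) / 0.1
        b = rng.poisson(lam, n2) / 0.1
        auc = roc_value(a, b)
        assert 0.0 <= auc <= 1.0
        # swapping the groups reflects the statistic about 0.5, up to the
        # strict-inequality asymmetry bounded by the threshold spacing
        assert abs(auc + roc_value(b, a) - 1.0) <= 1 / 12 + 1e-9

    def test_converges_to_pair_count_auc(self):
        """At 200 thresholds the sweep statistic matches the pair-count
        (tie half-credit) AUC on count-valued epoch rates."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            n1, n2 = rng.integers(10, 40, 2)
            lam = rng.uniform(0.2, 4.0)
            a = rng.poisson(lam, n1) / 0.1
            b = rng.poisson(rng.uniform(0.5, 2.0) * lam, n2) / 0.1
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            worst = max(worst, abs(roc_value(a, b, 200) - pair_count_auc(a, b)))
        assert worst < 0.02


class TestPermutationTest:
    def test_tiny_groups_match_exhaustive_enumeration(self):
        """For 3+3 trials every one of the 20 splits is enumerated; the
        two-sided p is the minimal attainable 2 * 1/20 and is reproduced
        exactly by the independent oracle."""
        res = permutation_test([10, 10, 10], [0, 0, 0])
        assert res.method == "exhaustive" and res.n_permutations == 20
        assert res.auc == 1.0
        assert res.p_value == exhaustive_two_sided_p([10, 10, 10], [0, 0, 0])
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("pref, nonpref", [
        ([9, 7, 5, 3], [4, 4, 6, 2]),
        ([0, 1, 0], [2, 3, 1, 0]),
        ([5, 5, 5, 8], [5, 6, 5]),
    ])
    def test_small_groups_match_oracle(self, pref, nonpref):
        res = permutation_test(pref, nonpref)
        assert res.method == "exhaustive"
        assert res.p_value == pytest.approx(exhaustive_two_sided_p(pref, nonpref))

    def test_type_one_error_calibrated(self):
        """Exchangeable Poisson epoch rates: the default total-5% two-sided
        convention flags about 5% of null units."""
        rng = np.random.default_rng(0)
        cfg = SelectivityConfig(n_permutations=1000)
        n = 400
        sig = sum(
            permutation_test(rng.poisson(0.8, 30) / 0.1,
                             rng.poisson(0.8, 30) / 0.1, cfg,
                             seed=int(rng.integers(2**31))).significant
            for _ in range(n))
        band = 2.576 * np.sqrt(0.05 * 0.95 / n)  # binomial 99% CI
        assert abs(sig / n - 0.05) < band

    def test_per_tail_convention_is_more_permissive(self):
        rng = np.random.default_rng(3)
        total = SelectivityConfig(n_permutations=500, tail_convention="total")
        per_tail = SelectivityConfig(n_permutations=500,
                                     tail_convention="per_tail")
        n_sig_total = n_sig_tail = 0
        for i in range(200):
            a = rng.poisson(0.8, 20) / 0.1
            b = rng.poisson(0.8, 20) / 0.1
            n_sig_total += permutation_test(a, b, total, seed=i).significant
            n_sig_tail += permutation_test(a, b, per_tail, seed=i).significant
        assert n_sig_tail >= n_sig_total

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        a, b = rng.poisson(1.5, 30) / 0.1, rng.poisson(0.9, 30) / 0.1
        cfg = SelectivityConfig(n_permutations=500, seed=77)
        r1, r2 = permutation_test(a, b, cfg), permutation_test(a, b, cfg)
        assert r1.p_value == r2.p_value and r1.auc == r2.auc

    def test_degenerate_and_guards(self):
        res = permutation_test([3, 3, 3], [3, 3, 3])
        assert res.p_value == 1.0 and not res.significant and res.auc == 0.5
        with pytest.raises(ValueError):
            permutation_test([1, 2], [3], SelectivityConfig())
        with pytest.raises(ValueError):
            SelectivityConfig(n_permutations=0)


class TestAssignPreferred:
    def test_larger_mean_wins_and_ties_break_low(self, balanced_session):
        cfg = UnitGenConfig(r0=2.0, a_pref=20.0, a_nonpref=2.0,
                            preferred_stimulus=12000.0, seed=30)
        u = simulate_unit(cfg, balanced_session)
        assert assign_preferred(u) == 12000.0
        # exact tie: a silent unit has equal (zero) means everywhere
        silent = simulate_unit(UnitGenConfig(r0=0.0, a_pref=0.0, a_nonpref=0.0,
                                             seed=31), balanced_session)
        assert assign_preferred(silent) == 3000.0

    def test_generator_label_recovery(self, balanced_session):
        recovered = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = UnitGenConfig(r0=4.0, a_pref=15.0, a_nonpref=5.0,
                                preferred_stimulus=3000.0, seed=seed)
            u = simulate_unit(cfg, balanced_session)
            recovered += assign_preferred(u) == 3000.0
        assert recovered >= int(0.95 * n_rep)

    def test_requires_both_stimuli(self, task):
        cfg = BehaviorGenConfig(n_match_trials=10, n_nonmatch_trials=10, seed=1)
        sess = simulate_session(cfg)
        for t in sess.trials:
            t.sample_stimulus = 3000.0
            t.test_stimulus = 3000.0 if t.is_match else 12000.0
        u = simulate_unit(UnitGenConfig(seed=2), sess)
        with pytest.raises(ValueError, match="distinct"):
            assign_preferred(u)


class TestRocTimecourse:
    def test_selective_unit_significance_ends_at_truncation(self, balanced_session):
        """Evoked selectivity truncated 1.0 s after onset: significant
        epochs stop by the epoch containing 1.0 s (+/- one epoch)."""
        cfg = UnitGenConfig(r0=4.0, a_pref=22.0, a_nonpref=5.0,
                            t_end_from_onset=1.0, seed=40)
        u = simulate_unit(cfg, balanced_session)
        tc = roc_timecourse(u, SelectivityConfig(n_permutations=1000, seed=1))
        sig_epochs = [e for e, s in zip(tc.epochs, tc.significant) if s]
        assert sig_epochs, "selective unit should have significant epochs"
        assert max(e[1] for e in sig_epochs) <= 1.1 + 1e-9
        assert tc.significant[0] or tc.significant[1]  # stimulus epochs

    def test_null_unit_auc_near_half(self, null_unit):
        tc = roc_timecourse(null_unit,
                            SelectivityConfig(n_permutations=500, seed=2))
        assert np.all((tc.auc > 0.2) & (tc.auc < 0.8))
        assert tc.significant.mean() <= 0.2

    def test_silent_unit_all_half_none_significant(self, balanced_session):
        u = simulate_unit(UnitGenConfig(r0=0.0, a_pref=0.0, a_nonpref=0.0,
                                        seed=41), balanced_session)
        tc = roc_timecourse(u, SelectivityConfig(n_permutations=200, seed=3))
        assert np.all(tc.auc == 0.5) and not tc.significant.any()

    def test_epoch_grid_beyond_recording_rejected(self, selective_unit):
        with pytest.raises(ValueError, match="epoch grid"):
            roc_timecourse(selective_unit, SelectivityConfig(n_permutations=100),
                           t_stop=10.0)


class TestPopulationSelectivity:
    def _timecourses(self, n, cfg_unit, seed, n_perm=500):
        sess = simulate_session(BehaviorGenConfig(
            n_match_trials=40, n_nonmatch_trials=40, seed=seed))
        units = simulate_population(n, mixture_sampler(1.0, cfg_unit), sess,
                                    seed=seed)
        sel = SelectivityConfig(n_permutations=n_perm, seed=seed)
        return [roc_timecourse(u, sel) for u in units]

    def test_null_population_mean_auc_near_simulated_null(self):
        """Preferred labels are estimated from the sample epoch, so the
        null mean AUC sits slightly above 0.5 during the stimulus and near
        0.5 in late epochs."""
        tcs = self._timecourses(
            30, UnitGenConfig(r0=8.0, a_pref=6.0, a_nonpref=6.0), seed=50)
        pop = population_selectivity(tcs)
        late = pop[pop.epoch_start >= 1.2]["mean_auc"]
        assert np.all(np.abs(late - 0.5) < 0.05)
        sample_auc = pop["mean_auc"].iloc[0]
        assert 0.5 <= sample_auc < 0.65  # selection bias, bounded

    def test_mixture_fraction_significant(self):
        """A 50/50 selective/null mixture shows a sample-epoch significant
        fraction near 0.5*power + 0.5*alpha."""
        sess = simulate_session(BehaviorGenConfig(
            n_match_trials=60, n_nonmatch_trials=60, seed=51))
        sampler = mixture_sampler(
            0.5, UnitGenConfig(r0=4.0, a_pref=20.0, a_nonpref=5.0))
        units = simulate_population(60, sampler, sess, seed=51)
        sel = SelectivityConfig(n_permutations=500, seed=51)
        pop = population_selectivity([roc_timecourse(u, sel) for u in units])
        frac_sample = pop["frac_significant"].iloc[1]  # 0.1-0.2 s epoch
        assert 0.30 < frac_sample < 0.75  # ~0.5*1 + 0.5*0.05 with binomial noise

    def test_requires_three_units(self, selective_unit):
        with pytest.raises(ValueError, match="3 units"):
            population_selectivity(
                [roc_timecourse(selective_unit,
                                SelectivityConfig(n_permutations=100, seed=0))])


class TestCompareConditions:
    def _units(self, cfg_unit, seed, n=12):
        sess = simulate_session(BehaviorGenConfig(
            n_match_trials=40, n_nonmatch_trials=40, seed=seed))
        return simulate_population(n, mixture_sampler(1.0, cfg_unit), sess,
                                   seed=seed)

    def test_wm_vs_passive_differs_in_early_delay(self):
        wm_cfg = UnitGenConfig(r0=4.0, a_pref=22.0, a_nonpref=4.0,
                               tau_delay=0.5)
        sel = SelectivityConfig(n_permutations=300, seed=60)
        wm = [roc_timecourse(u, sel) for u in self._units(wm_cfg, 60)]
        passive = [roc_timecourse(u, sel)
                   for u in self._units(passive_preset(wm_cfg), 61)]
        cmp = compare_conditions(wm, passive)
        sig = cmp[cmp.significant]
        assert len(sig) >= 1
        # differences concentrate where the passive trace has ended but the
        # task-condition trace persists
        assert (sig["epoch_start"] >= 0.2).all()
        assert (sig["epoch_end"] <= 1.1 + 1e-9).all()

    def test_exchangeable_conditions_rarely_differ(self):
        cfg = UnitGenConfig(r0=6.0, a_pref=10.0, a_nonpref=10.0)
        sel = SelectivityConfig(n_permutations=200, seed=62)
        a = [roc_timecourse(u, sel) for u in self._units(cfg, 62)]
        b = [roc_timecourse(u, sel) for u in self._units(cfg, 63)]
        cmp = compare_conditions(a, b)
        assert cmp["significant"].mean() <= 0.2

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="3 units"):
            compare_conditions([], [])
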