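"""Unit responsiveness, auROC profiles, clustering, and coding tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from olfrl import synth, units as U
from olfrl.task import TaskConfig, generate_trial_sequence


def brute_force_auroc(x, y):
    """Pair-counting oracle with midrank tie handling."""
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)
    return wins / (len(x) * len(y))


class TestAuroc:
    def test_identical_distributions_give_half(self):
        x = np.array([1.0, 2.0, 3.0])
        assert U.auroc(x, x) == pytest.approx(0.5)

    def test_fully_separated_gives_one(self):
        assert U.auroc([5, 6, 7], [1, 2, 3]) == pytest.approx(1.0)

    def test_midrank_hand_example(self):
        # window {2,3} vs baseline {1,2}: (1 + 0.5 + 1 + 1)/4 = 0.875
        assert U.auroc([2, 3], [1, 2]) == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
        assert U.auroc(x, y) == pytest.approx(brute_force_auroc(x, y), abs=1e-12)

    def test_invariant_to_monotone_transform_and_complement(self):
        rng = np.random.default_rng(1)
        x, y = rng.gamma(2, size=10), rng.gamma(3, size=8)
        a = U.auroc(x, y)
        assert U.auroc(np.exp(x), np.exp(y)) == pytest.approx(a)
        assert U.auroc(y, x) == pytest.approx(1.0 - a)


class TestResponsiveness:
    def test_identical_rates_are_none(self):
        # window rate equals baseline rate on every trial
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "cs": ["CS100"] * 20 + ["CS50"] * 20 + ["CS0"] * 20,
            "rewarded": [True] * 60,
            "baseline": rng.poisson(4.0, 60).astype(float),
        })
        for w in ("cs_win", "wait", "us"):
            df[w] = df["baseline"]
        table = U.test_responsiveness({"u0": df}, windows=("cs_win", "wait", "us"))
        assert (table["label"] == "none").all()

    def test_strong_cs_response_labeled_excited(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "cs": ["CS100"] * 25 + ["CS50"] * 25 + ["CS0"] * 25,
            "rewarded": [True] * 75,
            "baseline": rng.poisson(4.0, 75).astype(float),
        })
        df["cs_win"] = df["baseline"] + np.where(df["cs"] == "CS100",
                                                rng.poisson(5.0, 75), 0)
        df["wait"] = df["baseline"]
        df["us"] = df["baseline"]
        table = U.test_responsiveness({"u0": df}, windows=("cs_win", "wait", "us"))
        row = table[(table["cs"] == "CS100") & (table["window"] == "cs_win")]
        assert row["label"].iloc[0] == "excited"

    def test_null_simulation_five_percent_raw_positives(self):
        rng = np.random.default_rng(2)
        raw_p = []
        for _ in range(400):
            base = rng.poisson(4.0, 25).astype(float)
            win = rng.poisson(4.0, 25).astype(float)
            raw_p.append(U._paired_pvalue(win, base, "wilcoxon"))
        rate = np.mean(np.asarray(raw_p) < 0.05)
        assert 0.02 <= rate <= 0.08

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        _, want, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(U.benjamini_hochberg(p), want, atol=1e-12)


class TestClustering:
    def test_two_planted_archetypes_recovered_with_high_purity(self):
        seq = generate_trial_sequence(TaskConfig(seed=31))
        arch = synth.PopulationArchetypes(
            weights={"transient": 0.5, "ramping": 0.5, "inhibited": 0.0,
                     "sustained": 0.0, "baseline": 0.0}
        )
        pop = synth.simulate_population(seq, archetypes=arch, n_units=60, rng=32)
        profs = U.auroc_profiles(pop["rasters"], seq)
        res = U.cluster_units(profs)
        truth = pop["unit_table"].set_index("unit").loc[profs.unit_ids, "archetype"]
        purity = np.mean(res["groups"] == truth.to_numpy())
        assert purity >= 0.95

    def test_single_archetype_forms_one_cluster(self):
        seq = generate_trial_sequence(TaskConfig(n_trials=90, seed=33))
        arch = synth.PopulationArchetypes(
            weights={"transient": 1.0, "ramping": 0.0, "inhibited": 0.0,
                     "sustained": 0.0, "baseline": 0.0},
            frac_monotonic=1.0,
        )
        pop = synth.simulate_population(seq, archetypes=arch, n_units=20, rng=34)
        profs = U.auroc_profiles(pop["rasters"], seq)
        res = U.cluster_units(profs, cutoff=0.85)
        # cutting below the top merge always splits off something, so a
        # homogeneous population shows one dominant cluster plus small
        # outlier clusters, never a second comparable cluster
        counts = sorted(np.unique(res["labels"], return_counts=True)[1])
        assert counts[-1] >= 0.8 * len(profs.unit_ids)

    def test_inhibited_units_assigned_to_inhibited_group(self):
        seq = generate_trial_sequence(TaskConfig(seed=35))
        arch = synth.PopulationArchetypes(
            weights={"transient": 0.5, "ramping": 0.0, "inhibited": 0.5,
                     "sustained": 0.0, "baseline": 0.0}
        )
        pop = synth.simulate_population(seq, archetypes=arch, n_units=40, rng=36)
        profs = U.auroc_profiles(pop["rasters"], seq)
        res = U.cluster_units(profs)
        truth = pop["unit_table"].set_index("unit").loc[profs.unit_ids, "archetype"]
        inh = truth.to_numpy() == "inhibited"
        assert np.mean(res["groups"][inh] == "inhibited") >= 0.9


class TestMonotonicRP:
    def test_clear_separation_is_monotonic(self):
        rng = np.random.default_rng(0)
        res = U.test_monotonic_rp(
            rng.normal(1, 0.3, 30), rng.normal(5, 0.3, 30), rng.normal(9, 0.3, 30)
        )
        assert res["label"] == "monotonic"

    def test_identical_distributions_are_neither(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 1, 30)
        res = U.test_monotonic_rp(x, x.copy(), x.copy())
        assert res["label"] == "neither"

    def test_cs50_only_responder_is_dominant(self):
        rng = np.random.default_rng(2)
        res = U.test_monotonic_rp(
            rng.normal(1, 0.3, 30), rng.normal(8, 0.3, 30), rng.normal(1, 0.3, 30)
        )
        assert res["label"] == "dominant-CS50"

    def test_inhibited_direction_reversed(self):
        rng = np.random.default_rng(3)
        res = U.test_monotonic_rp(
            rng.normal(9, 0.3, 30), rng.normal(5, 0.3, 30), rng.normal(1, 0.3, 30),
            inhibited=True,
        )
        assert res["label"] == "monotonic"

    def test_scaling_invariance(self):
        rng = np.random.default_rng(4)
        r0, r50, r100 = (rng.normal(m, 0.5, 25) for m in (1, 4, 8))
        a = U.test_monotonic_rp(r0, r50, r100)["label"]
        b = U.test_monotonic_rp(3 * r0, 3 * r50, 3 * r100)["label"]
        assert a == b

    def test_too_few_trials_flagged(self):
        res = U.test_monotonic_rp([1, 2], [3, 4], [5, 6])
        assert res["label"] == "neither" and res["flag"]


class TestDistributedCoding:
    def test_value_scaled_responder_counts_give_population_monotonicity(self):
        # single-cue responders whose counts scale with reward probability
        rng = np.random.default_rng(5)
        n_trials = 40
        counts = {"R0": 2, "R50": 6, "R100": 10}  # responders per cue
        sums = {k: rng.poisson(4.0 * counts[k], n_trials) + rng.poisson(20, n_trials)
                for k in counts}
        res = U.distributed_coding_test(sums)
        assert res["monotonic"]

    def test_noise_remainder_is_not_monotonic(self):
        rng = np.random.default_rng(6)
        sums = {k: rng.poisson(20.0, 40) for k in ("R0", "R50", "R100")}
        assert not U.distributed_coding_test(sums)["monotonic"]


class TestSurpriseAndDiscrimination:
    def _rates(self, d50, d100, rng):
        rows = []
        for _ in range(25):
            p = rng.poisson(4.0)
            rows.append({"cs": "CS50", "rewarded": True, "prior": p,
                         "after_short": p + d50 + rng.normal(0, 0.5),
                         "after_long": p})
            rows.append({"cs": "CS50", "rewarded": False, "prior": p,
                         "after_short": p + rng.normal(0, 0.5), "after_long": p})
            rows.append({"cs": "CS100", "rewarded": True, "prior": p,
                         "after_short": p + d100 + rng.normal(0, 0.5),
                         "after_long": p})
        return pd.DataFrame(rows)

    def test_equal_jumps_are_not_surprise(self):
        rates = self._rates(2.0, 2.0, np.random.default_rng(0))
        assert not U.test_reward_surprise_unit(rates)

    def test_larger_cs50_jump_is_surprise(self):
        rates = self._rates(4.0, 1.0, np.random.default_rng(1))
        assert U.test_reward_surprise_unit(rates)

    def test_inverted_criterion_for_inhibited_units(self):
        rates = self._rates(-4.0, -1.0, np.random.default_rng(2))
        assert U.test_reward_surprise_unit(rates, inhibited=True)
        assert not U.test_reward_surprise_unit(rates, inhibited=False)

    def test_outcome_discrimination_positive_effect(self):
        rates = self._rates(5.0, 5.0, np.random.default_rng(3))
        assert U.test_outcome_discrimination(rates)

    def test_outcome_discrimination_equal_distributions_false(self):
        rates = self._rates(0.0, 0.0, np.random.default_rng(4))
        assert not U.test_outcome_discrimination(rates)

    def test_opposite_direction_not_counted_for_excited(self):
        rates = self._rates(-5.0, 0.0, np.random.default_rng(5))
        assert not U.test_outcome_discrimination(rates)


class TestChanceLevel:
    def _disc_unit(self, rng, means):
        return {k: rng.normal(m, 0.2, 25) for k, m in zip(("R0", "R50", "R100"), means)}

    def test_twelve_discriminative_units_give_chance_two(self):
        rng = np.random.default_rng(0)
        units = [self._disc_unit(rng, rng.permutation([1.0, 5.0, 9.0]))
                 for _ in range(12)]
        res = U.chance_level_monotonic(units)
        assert res["n_discriminative"] == 12
        assert res["chance_per_ordering"] == pytest.approx(2.0)

    def test_no_discriminative_units_give_zero(self):
        rng = np.random.default_rng(1)
        units = [{k: rng.normal(3, 1, 20) for k in ("R0", "R50", "R100")}
                 for _ in range(10)]
        res = U.chance_level_monotonic(units)
        assert res["chance_per_ordering"] == pytest.approx(res["n_discriminative"] / 6)

    def test_ordering_counts_exchangeable_under_label_permutation(self):
        # with symmetric (exchangeable) cue distributions every strict
        # ordering is equally likely: counts should be near n/6
        rng = np.random.default_rng(2)
        units = [self._disc_unit(rng, rng.permutation([1.0, 5.0, 9.0]))
                 for _ in range(240)]
        res = U.chance_level_monotonic(units)
        observed = np.array(list(res["observed"].values()))
        expected = res["n_discriminative"] / 6
        # chi-square against the uniform expectation
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=5)


class TestHistorySatiety:
    def test_history_effect_detected(self):
        rng = np.random.default_rng(0)
        groups = {
            "lastR": rng.normal(6, 1, 30), "lastN": rng.normal(3, 1, 30),
            "priorCS100": rng.normal(4.5, 1, 30), "priorCS0": rng.normal(4.5, 1, 30),
        }
        res = U.history_satiety_effects(groups)
        assert res["history_significant"] and not res["satiety_significant"]

    def test_satiety_effect_detected(self):
        rng = np.random.default_rng(1)
        groups = {
            "lastR": rng.normal(4.5, 1, 30), "lastN": rng.normal(4.5, 1, 30),
            "priorCS100": rng.normal(3, 1, 30), "priorCS0": rng.normal(6, 1, 30),
        }
        res = U.history_satiety_effects(groups)
        assert res["satiety_significant"] and not res["history_significant"]

    def test_empty_groups_flagged(self):
        res = U.history_satiety_effects({"lastR": [1, 2, 3]})
        assert res["flag"]
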