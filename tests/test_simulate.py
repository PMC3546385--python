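"""Null-scheme simulation: weights, sire draws, ensembles, determinism."""

import numpy as np
import pandas as pd
import pytest

from matekin.simulate import (
    WEIGHT_EPSILON,
    abs_records,
    build_eligibility,
    draw_sire_codes,
    fit_age_weights,
    fit_lbs_weights,
    replicate_seed,
    run_ensemble,
    simulate_pedigree,
)
from matekin.stats import SIRE_ONLY_STATS, stat_block


class TestAgeWeights:
    def test_quadratic_recovery(self):
        rng = np.random.default_rng(0)
        ages = rng.integers(5, 15, size=500)
        true = -((ages - 9.0) ** 2) + 16.0
        recs = pd.DataFrame({"age": ages, "abs": true + rng.normal(0, 0.5, 500)})
        model = fit_age_weights(recs)
        # coefficients of abs = 16 - (age-9)^2 = -65 + 18 age - age^2
        for est, se, truth in zip(model.params, model.bse, (-65.0, 18.0, -1.0)):
            assert abs(est - truth) < 3 * se
        grid = np.linspace(2, 20, 500)
        assert 8 <= grid[np.argmax(model.weight(grid))] <= 10

    def test_constant_abs_gives_constant_weight(self):
        recs = pd.DataFrame({"age": [5, 8, 11, 14], "abs": [3.0] * 4})
        model = fit_age_weights(recs)
        assert np.allclose(model.weight([2, 9, 18]), 3.0, atol=1e-8)

    def test_negative_predictions_floored(self):
        rng = np.random.default_rng(1)
        ages = rng.integers(5, 15, size=200)
        recs = pd.DataFrame(
            {"age": ages, "abs": -((ages - 9.0) ** 2) + 4.0}
        )  # negative at extremes
        model = fit_age_weights(recs)
        w = model.weight([1, 25])
        assert (w >= WEIGHT_EPSILON).all() and (w <= 2 * WEIGHT_EPSILON).all()

    def test_too_few_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_age_weights(pd.DataFrame({"age": [7, 7, 9], "abs": [1, 2, 3]}))


class TestLbsWeights:
    def test_mean_abs(self):
        recs = pd.DataFrame({"male_id": ["A", "A", "B"], "abs": [2, 4, 0]})
        table = fit_lbs_weights(recs)
        assert table["A"] == 3.0
        assert table["B"] == WEIGHT_EPSILON  # all-zero ABS floored

    def test_missing_candidate_gets_floor(self):
        recs = pd.DataFrame({"male_id": ["A"], "abs": [2]})
        table = fit_lbs_weights(recs, candidate_males=["A", "B"])
        assert table["B"] == WEIGHT_EPSILON


class TestDraws:
    def test_single_eligible_male_is_certain(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        idx = build_eligibility(ped, calv, cen, "RANDOM", small_study.matrilines)
        # force one calf to a single-male table
        idx.tables[0] = (idx.tables[0][0][:1], np.array([1.0]))
        codes = draw_sire_codes(idx, np.random.default_rng(0))
        assert codes[idx.calf_table == 0][0] == idx.tables[0][0][0]

    def test_weighted_sampling_proportions(self):
        # 1:2:3 weights over three males
        from matekin.simulate import EligibilityIndex
        from matekin.schemes import RANDOM as R

        w = np.array([1.0, 2.0, 3.0])
        cp = np.cumsum(w) / w.sum()
        codes = np.array([0, 1, 2])

        class _Eng:
            male_ids = ["a", "b", "c"]

        idx = EligibilityIndex(
            scheme=R, engine=_Eng(), calf_ids=["c0"], eligible=[codes], cumprob=[cp]
        )
        rng = np.random.default_rng(5)
        draws = np.concatenate(
            [draw_sire_codes(idx, rng) for _ in range(100_000)]
        )
        n = len(draws)
        for k, p in enumerate(w / w.sum()):
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs((draws == k).mean() - p) < 3 * sigma

    def test_uniform_choice_is_even(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        idx = build_eligibility(ped, calv, cen, "RANDOM", small_study.matrilines)
        rng = np.random.default_rng(3)
        table0 = idx.tables[0][0]
        counts = np.zeros(len(table0))
        sel = idx.calf_table == 0
        n_draws = 4000
        for _ in range(n_draws):
            codes = draw_sire_codes(idx, rng)
            c = codes[sel][0]
            counts[np.searchsorted(table0, c)] += 1
        p = 1 / len(table0)
        assert abs(counts[0] / n_draws - p) < 3 * np.sqrt(p * (1 - p) / n_draws)


class TestSimulatedPedigree:
    def test_sires_eligible_and_mothers_fixed(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        idx = build_eligibility(ped, calv, cen, "SPATIAL_500", small_study.matrilines)
        sim = simulate_pedigree(ped, idx, master_seed=1, replicate_index=0)
        base = ped.to_frame().set_index("id")
        new = sim.pedigree.to_frame().set_index("id")
        pd.testing.assert_series_equal(base["mother_id"], new["mother_id"])
        for k, calf in enumerate(idx.calf_ids):
            sire = sim.replaced_sires[calf]
            assert idx.engine.male_code(sire) in idx.eligible[k]

    def test_determinism(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        idx = build_eligibility(ped, calv, cen, "TEMPORAL", small_study.matrilines)
        a = simulate_pedigree(ped, idx, master_seed=9, replicate_index=3)
        b = simulate_pedigree(ped, idx, master_seed=9, replicate_index=3)
        assert a.replaced_sires == b.replaced_sires
        c = simulate_pedigree(ped, idx, master_seed=9, replicate_index=4)
        assert c.replaced_sires != a.replaced_sires


class TestEnsembles:
    def test_bit_identical_under_same_seed(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        kw = dict(n_replicates=5, master_seed=11, statistics=SIRE_ONLY_STATS,
                  matrilines=small_study.matrilines)
        e1 = run_ensemble(ped, calv, cen, "RANDOM", **kw)
        e2 = run_ensemble(ped, calv, cen, "RANDOM", **kw)
        pd.testing.assert_frame_equal(e1.stats, e2.stats)

    def test_fast_path_equals_full_stat_block(self, small_study):
        """Vectorised engine and pedigree-rebuild path agree replicate by replicate."""
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        mats = small_study.matrilines
        fast = run_ensemble(ped, calv, cen, "RANDOM", n_replicates=3, master_seed=2,
                            statistics=SIRE_ONLY_STATS, matrilines=mats)
        slow = run_ensemble(ped, calv, cen, "RANDOM", n_replicates=3, master_seed=2,
                            statistics=None, matrilines=mats)
        pd.testing.assert_frame_equal(
            fast.stats, slow.stats[list(SIRE_ONLY_STATS)], check_dtype=False
        )

    def test_temporal_concentration_raises_remating(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        mats = small_study.matrilines
        means = {}
        for scheme in ("RANDOM", "TEMPORAL"):
            ens = run_ensemble(ped, calv, cen, scheme, n_replicates=300, master_seed=4,
                               statistics=("pct_pairs_remating",), matrilines=mats)
            means[scheme] = ens.mean()["pct_pairs_remating"]
        assert means["TEMPORAL"] >= means["RANDOM"]

    def test_ensemble_statistics_roughly_normal(self, small_study):
        from scipy.stats import skew

        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        ens = run_ensemble(ped, calv, cen, "RANDOM", n_replicates=1000, master_seed=6,
                           statistics=("pct_pairs_remating", "mean_full_sibship"),
                           matrilines=small_study.matrilines)
        assert abs(skew(ens.stats["mean_full_sibship"])) < 1
        assert abs(skew(ens.stats["pct_pairs_remating"])) < 1

    def test_replicate_seed_is_stable(self):
        s = replicate_seed(42, 7)
        assert s.entropy == 42 and s.spawn_key == (7,)
        a = np.random.default_rng(replicate_seed(42, 7)).random(3)
        b = np.random.default_rng(replicate_seed(42, 7)).random(3)
        assert np.array_equal(a, b)


class TestAbsRecords:
    def test_counts_and_zero_years(self, small_study):
        recs = abs_records(small_study.pedigree, small_study.calvings, small_study.census)
        truth = small_study.truth
        # total ABS equals the number of sired focal calves
        assert recs["abs"].sum() == len(truth)
        per_male_year = truth.groupby(["sire_id", "rut_year"]).size()
        merged = recs.set_index(["male_id", "rut_year"])["abs"]
        for (m, y), n in per_male_year.items():
            assert merged[(m, y)] == n
        assert (recs["abs"] == 0).any()  # unsuccessful candidate male-years exist
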