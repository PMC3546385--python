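"""The ten pedigree statistics and their engine equivalence."""

import numpy as np
import pandas as pd
import pytest

from matekin.pedigree import Pedigree, compute_kinship
from matekin.simulate import build_eligibility, draw_sire_codes, replicate_seed
from matekin.stats import (
    PairOpportunity,
    female_mate_diversity,
    inbreeding_stats,
    intralineage_stat,
    pair_opportunities,
    relatedness_stat,
    remating_stats,
    stat_block,
)
from matekin.synthetic import GeneratorConfig, generate_viable_study

from .oracles import kinship_oracle, parents_dict, random_pedigree


def _pair(f, m, mated, opp):
    return PairOpportunity(f, m, frozenset(mated), frozenset(opp))


class TestRematingStats:
    def test_printed_arithmetic(self):
        """134 re-mated of 1456 multi-opportunity pairs is 9.2%."""
        pairs = [
            _pair(f"F{i}", f"M{i % 400}", {1990, 1991} if i < 134 else {1990}, {1990, 1991})
            for i in range(1456)
        ]
        pct_pairs, _, _ = remating_stats(pairs)
        assert round(pct_pairs, 1) == 9.2

    def test_no_remating(self):
        pairs = [_pair("F1", "M1", {1990}, {1990, 1991})]
        assert remating_stats(pairs)[0] == 0.0

    def test_single_remated_pair_is_100pct(self):
        pairs = [_pair("F1", "M1", {1990, 1992}, {1990, 1992})]
        assert remating_stats(pairs) == (100.0, 100.0, 100.0)

    def test_zero_denominator_reported_missing(self):
        pairs = [_pair("F1", "M1", {1990}, {1990})]
        assert all(np.isnan(v) for v in remating_stats(pairs))

    def test_denominators_share_pair_set(self):
        # one female in a re-mated pair and one only with opportunity
        pairs = [
            _pair("F1", "M1", {1990, 1991}, {1990, 1991}),
            _pair("F2", "M1", {1990}, {1990, 1992}),
            _pair("F3", "M2", {1991}, {1991}),  # no multi-year opportunity
        ]
        pct_pairs, pct_females, pct_males = remating_stats(pairs)
        assert pct_pairs == 50.0  # 1 of 2 multi-opportunity pairs
        assert pct_females == 50.0  # F1 of {F1, F2}; F3 not in denominator
        assert pct_males == 100.0  # M1 is the only multi-opportunity male


class TestPairOpportunities:
    def _study(self):
        individuals = pd.DataFrame(
            {
                "id": ["F1", "M1", "C1", "C2"],
                "sex": ["F", "M", "F", "M"],
                "birth_year": [1990, 1990, 1996, 1998],
                "mother_id": [None, None, "F1", "F1"],
                "father_id": [None, None, "M1", "M1"],
            }
        )
        census = pd.DataFrame(
            {
                "rut_year": [1995, 1997],
                "date": ["1995-10-09", "1997-10-09"],
                "individual_id": ["M1", "M1"],
                "easting": [100, 100],
                "northing": [200, 200],
                "harem_holder": [True, True],
            }
        )
        calvings = pd.DataFrame(
            {
                "female_id": ["F1", "F1"],
                "calf_id": ["C1", "C2"],
                "calf_birth_date": ["1996-06-01", "1998-06-01"],
            }
        )
        return Pedigree(individuals), calvings, census

    def test_mated_years_and_gap_remating(self):
        ped, calvings, census = self._study()
        (p,) = pair_opportunities(ped, calvings, census)
        assert p.mated_years == {1995, 1997}
        assert p.opportunity_years == {1995, 1997}
        assert remating_stats([p])[0] == 100.0

    def test_opportunity_requires_male_census(self):
        ped, calvings, census = self._study()
        census = census.iloc[:1]  # male absent in 1997
        calvings = calvings.iloc[:1]  # only the 1995 conception
        ped = Pedigree(ped.to_frame().iloc[:3])  # drop C2
        (p,) = pair_opportunities(ped, calvings, census)
        assert p.opportunity_years == {1995}

    def test_opportunity_includes_calving_plus_census_year(self):
        ped, calvings, census = self._study()
        # C2 sired by another male: F1 calved in 1997 and M1 was censused,
        # so (F1, M1) had the opportunity but did not re-mate
        df = ped.to_frame()
        df.loc[df["id"] == "C2", "father_id"] = "M2"
        df = pd.concat(
            [df, pd.DataFrame([{"id": "M2", "sex": "M", "birth_year": 1990}])]
        )
        pairs = pair_opportunities(Pedigree(df), calvings, census)
        p1 = next(p for p in pairs if p.male_id == "M1")
        assert p1.mated_years == {1995}
        assert p1.opportunity_years == {1995, 1997}

    def test_sire_without_dam_rejected(self):
        ped, calvings, census = self._study()
        df = ped.to_frame()
        df.loc[df["id"] == "C1", "mother_id"] = None
        with pytest.raises(ValueError):
            pair_opportunities(Pedigree(df, validate=False), calvings, census)


class TestDiversityRatios:
    def _ped(self, assignments):
        rows = [
            {"id": f, "sex": "F", "birth_year": 1990} for f in {a[0] for a in assignments}
        ]
        rows += [
            {"id": m, "sex": "M", "birth_year": 1990} for m in {a[1] for a in assignments}
        ]
        rows += [
            {"id": f"C{k}", "sex": "F", "birth_year": 1995 + k, "mother_id": f,
             "father_id": m}
            for k, (f, m) in enumerate(assignments)
        ]
        return Pedigree.from_records(rows)

    def test_female_all_distinct_sires(self):
        ped = self._ped([("F1", "M1"), ("F1", "M2"), ("F1", "M3")])
        assert female_mate_diversity(ped) == 1.0

    def test_female_repeat_sires(self):
        ped = self._ped([("F1", "M1"), ("F1", "M1"), ("F1", "M2"), ("F1", "M2")])
        assert female_mate_diversity(ped) == 0.5

    def test_intralineage_two_of_two_matrilines(self):
        ped = self._ped([("F1", "M1"), ("F2", "M1"), ("F3", "M1"), ("F4", "M1")])
        mats = pd.Series({"F1": "A", "F2": "A", "F3": "B", "F4": "B"})
        assert intralineage_stat(ped, mats) == 0.5

    def test_intralineage_all_different(self):
        ped = self._ped([("F1", "M1"), ("F2", "M1"), ("F3", "M1")])
        mats = pd.Series({"F1": "A", "F2": "B", "F3": "C"})
        assert intralineage_stat(ped, mats) == 1.0

    def test_single_mate_contributes_one(self):
        ped = self._ped([("F1", "M1")])
        assert intralineage_stat(ped, pd.Series({"F1": "A"})) == 1.0

    def test_unknown_matriline_is_singleton(self):
        ped = self._ped([("F1", "M1"), ("F2", "M1")])
        mats = pd.Series({"F1": None, "F2": None})
        assert intralineage_stat(ped, mats) == 1.0


class TestKinshipAverages:
    def test_two_founders(self):
        ped = Pedigree.from_records(
            [
                {"id": "A", "sex": "F", "birth_year": 1990},
                {"id": "B", "sex": "M", "birth_year": 1990},
            ]
        )
        assert relatedness_stat(ped) == 0.0

    def test_parent_offspring_pair(self):
        ped = Pedigree.from_records(
            [
                {"id": "A", "sex": "F", "birth_year": 1990},
                {"id": "B", "sex": "M", "birth_year": 1995, "mother_id": "A"},
            ]
        )
        assert relatedness_stat(ped) == 0.5

    def test_mean_relatedness_matches_oracle(self):
        ped = random_pedigree(np.random.default_rng(12), n=25)
        parents = parents_dict(ped)
        memo = {}
        ids = ped.ids
        vals = [
            2.0 * kinship_oracle(parents, a, b, memo)
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
        ]
        assert relatedness_stat(ped) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_inbreeding_counts_and_threshold(self):
        rows = [
            {"id": "GM", "sex": "F", "birth_year": 1980},
            {"id": "GS", "sex": "M", "birth_year": 1980},
            {"id": "S1", "sex": "F", "birth_year": 1985, "mother_id": "GM", "father_id": "GS"},
            {"id": "S2", "sex": "M", "birth_year": 1986, "mother_id": "GM", "father_id": "GS"},
            {"id": "X", "sex": "F", "birth_year": 1990, "mother_id": "S1", "father_id": "S2"},
        ] + [{"id": f"O{k}", "sex": "F", "birth_year": 1990} for k in range(6)]
        mean_f, n_nonzero, n_close = inbreeding_stats(Pedigree.from_records(rows))
        assert n_nonzero == 1 and n_close == 1
        assert mean_f == pytest.approx(0.25 / 11)

    def test_deep_inbreeding_below_close_threshold(self):
        from matekin.examples import intralineage_inbreeding_pedigree

        mean_f, n_nonzero, n_close = inbreeding_stats(intralineage_inbreeding_pedigree())
        assert n_nonzero == 1 and n_close == 0  # 0.08008 < 0.125


class TestStatBlock:
    def test_fields_populated_and_deterministic(self, small_study):
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        b1 = stat_block(ped, calv, cen, small_study.matrilines)
        b2 = stat_block(ped, calv, cen, small_study.matrilines)
        assert b1 == b2
        s = b1.to_series()
        assert not s.isna().any()
        assert 0 <= s.pct_pairs_remating <= 100
        assert s.n_f_ge_0125 <= s.n_nonzero_f
        assert 0 < s.mean_males_per_offspring_ratio <= 1
        assert 0 < s.mean_matrilines_per_females_ratio <= 1
        assert s.mean_full_sibship >= 1

    def test_mother_only_statistics_unchanged_by_resiring(self, small_study):
        from matekin.simulate import simulate_pedigree

        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        idx = build_eligibility(ped, calv, cen, "RANDOM", small_study.matrilines)
        sim = simulate_pedigree(ped, idx, master_seed=5)
        base = ped.to_frame()
        new = sim.pedigree.to_frame()
        pd.testing.assert_series_equal(base["mother_id"], new["mother_id"])
        assert set(new["id"]) == set(base["id"])

    def test_engine_matches_definitional_statistics(self, small_study):
        """SireStatEngine equals the definitional functions on random draws."""
        ped, calv, cen = small_study.pedigree, small_study.calvings, small_study.census
        mats = small_study.matrilines
        idx = build_eligibility(ped, calv, cen, "TEMPORAL", mats)
        for r in range(3):
            rng = np.random.default_rng(replicate_seed(21, r))
            codes = draw_sire_codes(idx, rng)
            fast = idx.engine.compute(codes)
            sires = {c: idx.engine.male_ids[k] for c, k in zip(idx.calf_ids, codes)}
            sim = ped.with_fathers(sires)
            block = stat_block(sim, calv, cen, mats)
            for name, val in fast.items():
                assert val == pytest.approx(block[name], abs=1e-12), name


class TestBehaviouralTrends:
    def test_fidelity_raises_pair_remating(self):
        """phi = 0.5 produces clearly more re-mating than phi = 0."""
        def mean_pairs(phi):
            vals = []
            for seed in range(8):
                s = generate_viable_study(
                    GeneratorConfig.small(fidelity_phi=phi), seed=500 + seed
                )
                vals.append(
                    remating_stats(pair_opportunities(s.pedigree, s.calvings, s.census))[0]
                )
            return float(np.nanmean(vals))

        assert mean_pairs(0.5) > mean_pairs(0.0) + 3.0

    def test_monopolisation_lowers_intralineage_ratio(self):
        means = []
        for kappa in (0.0, 0.5, 1.0):
            vals = [
                intralineage_stat(s.pedigree, s.matrilines)
                for s in (
                    generate_viable_study(GeneratorConfig.small(kappa=kappa), seed=300 + k)
                    for k in range(8)
                )
            ]
            means.append(float(np.mean(vals)))
        assert means[0] > means[2] + 0.01
        assert means[0] >= means[1] - 0.005 >= means[2] - 0.01
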