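"""Null-model pedigree simulation: re-draw a sire for every focal calf.

A focal calf is a calf with an assigned sire in the observed pedigree; its
mother is never touched.  Under a scheme, each focal calf independently draws
a sire (with replacement) from the dam-year's eligible male set, uniformly or
proportionally to a male weight (age- or identity-predicted annual breeding
success).  An ensemble repeats this ``n_replicates`` times with per-replicate
seeds spawned deterministically from the master seed, computing the summary
statistics each time.

When a constrained scheme leaves a dam-year with no eligible male, the
constraint is widened for that dam-year only (SPATIAL_100 -> SPATIAL_500 ->
TEMPORAL -> RANDOM, stopping at the first non-empty set) and the widening is
logged; dropping such calves would change denominators between schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import census as census_mod
from .pedigree import Pedigree
from .schemes import (
    RANDOM,
    SPATIAL_100,
    SPATIAL_500,
    TEMPORAL,
    Scheme,
    get_scheme,
)
from .stats import SIRE_ONLY_STATS, STAT_NAMES, SireStatEngine, stat_block

logger = logging.getLogger(__name__)

#: sampling-weight floor: every eligible male stays drawable
WEIGHT_EPSILON = 1e-6

_FALLBACK = {
    "SPATIAL_100": SPATIAL_500,
    "AGE_CORRECTED": SPATIAL_500,
    "BS_CORRECTED": SPATIAL_500,
    "SPATIAL_500": TEMPORAL,
    "TEMPORAL": RANDOM,
}


# ---------------------------------------------------------------------------
# male weights


def abs_records(
    ped: Pedigree, calvings: pd.DataFrame, census: pd.DataFrame
) -> pd.DataFrame:
    """Annual breeding success per candidate male-year.

    One row per (male, rut year) in which the male held a harem, with his age
    that year and the number of focal calves he sired that were conceived
    that year (zero for unsuccessful candidate years).
    """
    calvings = census_mod.annotate_calvings(calvings)
    census = census_mod.normalise_census(census)
    df = ped.to_frame()
    birth = dict(zip(df["id"], df["birth_year"]))
    sire_of = dict(zip(df["id"], df["father_id"]))

    hh = census[census["harem_holder"]]
    rows = {
        (m, int(y)): 0
        for m, y in zip(hh["individual_id"], hh["rut_year"])
    }
    for row in calvings.itertuples(index=False):
        sire = sire_of.get(row.calf_id)
        if sire is None or pd.isna(sire):
            continue
        key = (str(sire), int(row.rut_year))
        if key in rows:
            rows[key] += 1
        else:  # sire without a census record that year: still an ABS event
            rows[key] = 1
    out = pd.DataFrame(
        [
            {
                "male_id": m,
                "rut_year": y,
                "age": (y - birth[m]) if m in birth and pd.notna(birth.get(m)) else np.nan,
                "abs": n,
            }
            for (m, y), n in sorted(rows.items())
        ]
    )
    return out


@dataclass
class AgeWeightModel:
    """Quadratic least-squares fit of annual breeding success on age."""

    params: np.ndarray  # intercept, age, age^2
    bse: np.ndarray
    epsilon: float = WEIGHT_EPSILON

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.params[0] + self.params[1] * age + self.params[2] * age**2

    def weight(self, age) -> np.ndarray:
        return np.maximum(self.predict(age), self.epsilon)


def fit_age_weights(records: pd.DataFrame, epsilon: float = WEIGHT_EPSILON) -> AgeWeightModel:
    """OLS of ABS on age + age²; weights are predictions floored at epsilon."""
    recs = records.dropna(subset=["age"])
    ages = recs["age"].astype(float)
    if ages.nunique() < 3:
        raise ValueError("need ABS records at >= 3 distinct ages")
    X = sm.add_constant(np.column_stack([ages, ages**2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate (collinear) age design")
    fit = sm.OLS(recs["abs"].astype(float), X).fit()
    return AgeWeightModel(params=np.asarray(fit.params), bse=np.asarray(fit.bse), epsilon=epsilon)


def fit_lbs_weights(
    records: pd.DataFrame,
    candidate_males=None,
    epsilon: float = WEIGHT_EPSILON,
) -> dict[str, float]:
    """Per-male weight = his mean ABS (identity-model fitted value), floored.

    Candidate males without any ABS record get the floor, with a warning.
    """
    means = records.groupby("male_id")["abs"].mean()
    table = {m: max(float(v), epsilon) for m, v in means.items()}
    if candidate_males is not None:
        missing = sorted(set(map(str, candidate_males)) - set(table))
        for m in missing:
            table[m] = epsilon
        if missing:
            logger.warning(
                "%d candidate males without ABS records assigned weight %.1e",
                len(missing), epsilon,
            )
    return table


# ---------------------------------------------------------------------------
# eligibility index and sire draws


@dataclass
class EligibilityIndex:
    """Per-focal-calf eligible male codes and cumulative sampling weights.

    Calves sharing one weight table (e.g. every calf of a year under RANDOM)
    reference the same arrays; ``calf_table`` maps calves to ``tables`` so
    draws can be vectorised per table.
    """

    scheme: Scheme
    engine: SireStatEngine
    calf_ids: list[str]
    eligible: list[np.ndarray]  # male codes per calf
    cumprob: list[np.ndarray]  # cumulative sampling probabilities per calf
    tables: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    calf_table: np.ndarray | None = None
    widened: dict[str, str] = field(default_factory=dict)  # calf -> scheme used

    def __post_init__(self):
        if not self.tables:
            seen: dict[bytes, int] = {}
            idx = np.empty(len(self.calf_ids), dtype=np.int64)
            for k, (codes, cp) in enumerate(zip(self.eligible, self.cumprob)):
                key = codes.tobytes() + cp.tobytes()
                if key not in seen:
                    seen[key] = len(self.tables)
                    self.tables.append((codes, cp))
                idx[k] = seen[key]
            self.calf_table = idx


def build_eligibility(
    ped: Pedigree,
    calvings: pd.DataFrame,
    census: pd.DataFrame,
    scheme: Scheme | str,
    matrilines: pd.Series | dict | None = None,
    age_model: AgeWeightModel | None = None,
    lbs_table: dict[str, float] | None = None,
    epsilon: float = WEIGHT_EPSILON,
) -> EligibilityIndex:
    """Resolve each focal calf's eligible male set and sampling weights.

    Fits the age/identity weight models from the observed pedigree when the
    scheme needs them and none are passed in.
    """
    scheme = get_scheme(scheme)
    calvings = census_mod.annotate_calvings(calvings)
    census = census_mod.normalise_census(census)
    from .pedigree import matriline_table

    if matrilines is None:
        matrilines = matriline_table(ped)

    df = ped.to_frame()
    sire_of = dict(zip(df["id"], df["father_id"]))
    birth = dict(zip(df["id"], df["birth_year"]))
    focal = [
        c for c in calvings["calf_id"]
        if c in sire_of and sire_of[c] is not None and pd.notna(sire_of[c])
    ]
    engine = SireStatEngine(calvings, census, matrilines, focal)

    if scheme.weighting == "age" and age_model is None:
        age_model = fit_age_weights(abs_records(ped, calvings, census))
    if scheme.weighting == "lbs" and lbs_table is None:
        lbs_table = fit_lbs_weights(
            abs_records(ped, calvings, census),
            candidate_males=engine.male_ids,
            epsilon=epsilon,
        )

    windows = census_mod.build_windows(calvings)
    candidates = census_mod.build_candidates(census, calvings)
    cal = calvings.set_index("calf_id")

    eligible, cumprob, widened = [], [], {}
    cache: dict[tuple, tuple] = {}
    for calf in focal:
        dam = str(cal.loc[calf, "female_id"])
        year = int(cal.loc[calf, "rut_year"])
        key = (dam, year)
        if key in cache:
            males, used = cache[key]
        else:
            males, used = [], scheme.name
            s = scheme
            while True:
                males = census_mod.eligible_males(
                    dam, year, s, census, windows, candidates
                )
                used = s.name
                if males or s.name not in _FALLBACK:
                    break
                s = _FALLBACK[s.name]
            cache[key] = (males, used)
        if not males:
            raise ValueError(
                f"no candidate males at all for dam {dam!r} in {year}"
            )
        if used != scheme.name:
            widened[calf] = used
            logger.info(
                "dam %s year %d: no eligible male under %s, widened to %s",
                dam, year, scheme.name, used,
            )
        codes = np.array([engine.male_code(m) for m in males])
        if scheme.weighting == "age":
            ages = np.array([year - birth[m] if pd.notna(birth.get(m)) else np.nan
                             for m in males], dtype=float)
            w = age_model.weight(np.nan_to_num(ages, nan=np.nanmean(ages)))
        elif scheme.weighting == "lbs":
            w = np.array([lbs_table.get(str(m), epsilon) for m in males])
        else:
            w = np.ones(len(males))
        w = np.maximum(w, epsilon)
        eligible.append(codes)
        cumprob.append(np.cumsum(w) / w.sum())

    return EligibilityIndex(
        scheme=scheme,
        engine=engine,
        calf_ids=list(focal),
        eligible=eligible,
        cumprob=cumprob,
        widened=widened,
    )


def replicate_seed(master_seed: int, replicate_index: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed: SeedSequence(master).spawn_key=(r,)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate_index,))


def draw_sire_codes(index: EligibilityIndex, rng: np.random.Generator) -> np.ndarray:
    """One sire draw per focal calf by inverse-CDF on the calf's weight table.

    One uniform per calf, consumed in calf order, so the draw is independent
    of how calves are grouped into shared tables.
    """
    u = rng.random(len(index.calf_ids))
    out = np.empty(len(index.calf_ids), dtype=np.int64)
    for t, (codes, cp) in enumerate(index.tables):
        sel = index.calf_table == t
        pos = np.searchsorted(cp, u[sel], side="right").clip(max=len(codes) - 1)
        out[sel] = codes[pos]
    return out


# ---------------------------------------------------------------------------
# simulated pedigrees and ensembles


@dataclass
class SimulatedPedigree:
    base: Pedigree
    replaced_sires: dict[str, str]
    scheme: Scheme
    replicate_index: int
    master_seed: int

    _ped: Pedigree | None = field(default=None, repr=False)

    @property
    def pedigree(self) -> Pedigree:
        if self._ped is None:
            self._ped = self.base.with_fathers(self.replaced_sires)
        return self._ped


def simulate_pedigree(
    observed: Pedigree,
    index: EligibilityIndex,
    master_seed: int = 0,
    replicate_index: int = 0,
) -> SimulatedPedigree:
    """One replicate pedigree: every focal calf re-sired under the scheme."""
    rng = np.random.default_rng(replicate_seed(master_seed, replicate_index))
    codes = draw_sire_codes(index, rng)
    sires = {
        calf: index.engine.male_ids[c] for calf, c in zip(index.calf_ids, codes)
    }
    return SimulatedPedigree(
        base=observed,
        replaced_sires=sires,
        scheme=index.scheme,
        replicate_index=replicate_index,
        master_seed=master_seed,
    )


@dataclass
class SimulationEnsemble:
    scheme: Scheme
    n_replicates: int
    master_seed: int
    stats: pd.DataFrame  # one row per replicate

    def mean(self) -> pd.Series:
        return self.stats.mean()

    def sd(self) -> pd.Series:
        return self.stats.std(ddof=1)


def run_ensemble(
    observed: Pedigree,
    calvings: pd.DataFrame,
    census: pd.DataFrame,
    scheme: Scheme | str,
    n_replicates: int = 1000,
    master_seed: int = 0,
    statistics: tuple[str, ...] | None = None,
    matrilines: pd.Series | dict | None = None,
    index: EligibilityIndex | None = None,
) -> SimulationEnsemble:
    """Simulate ``n_replicates`` pedigrees under a scheme and summarise each.

    ``statistics=None`` computes the full ten-statistic block per replicate
    (rebuilding the pedigree and kinship matrix each time).  When every
    requested statistic is sire-dependent and kinship-free, an exactly
    equivalent vectorised path is used; the sire draws are bit-identical
    either way because both run the same draw routine on the same
    per-replicate seed.
    """
    scheme = get_scheme(scheme)
    if matrilines is None:
        from .pedigree import matriline_table

        matrilines = matriline_table(observed)
    if index is None:
        index = build_eligibility(observed, calvings, census, scheme, matrilines)
    names = STAT_NAMES if statistics is None else tuple(statistics)
    unknown = set(names) - set(STAT_NAMES)
    if unknown:
        raise KeyError(f"unknown statistics {sorted(unknown)}")
    fast = set(names) <= set(SIRE_ONLY_STATS)

    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(replicate_seed(master_seed, r))
        codes = draw_sire_codes(index, rng)
        if fast:
            rows.append(index.engine.compute(codes))
        else:
            sires = {
                calf: index.engine.male_ids[c]
                for calf, c in zip(index.calf_ids, codes)
            }
            ped = observed.with_fathers(sires)
            rows.append(stat_block(ped, calvings, census, matrilines).to_series())
    stats = pd.DataFrame(rows, index=range(n_replicates))[list(names)]
    return SimulationEnsemble(
        scheme=scheme,
        n_replicates=n_replicates,
        master_seed=master_seed,
        stats=stats,
    )
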