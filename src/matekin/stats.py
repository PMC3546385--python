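"""The ten pedigree statistics compared between observed and null pedigrees.

Re-mating is scored per distinct (dam, sire) pair: a pair re-mated if it
produced calves conceived in more than one rut year, and it *could* have
re-mated if there was more than one year in which the dam conceived (calved
the following spring) while the sire was censused holding a harem.  The three
percentages share this pair set: pairs re-mating / pairs with multi-year
opportunity, and the same for the females and males appearing in those pairs.

The two diversity ratios summarise mate re-use from each sex's side:
per female, distinct sires over calves produced (1 = a new sire every calf);
per male, distinct matrilines among his mates over distinct mates (< 1 =
intralineage polygyny).  Relatedness and inbreeding statistics are whole-
pedigree averages from the kinship matrix.

Every statistic runs through the same code path for observed and simulated
pedigrees.  ``SireStatEngine`` is an equivalent vectorised implementation of
the sire-dependent, kinship-free statistics for ensemble work; tests pin it
to the definitional functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import census as census_mod
from .pedigree import (
    KinshipMatrix,
    Pedigree,
    compute_inbreeding,
    compute_kinship,
    full_sibship_sizes,
    matriline_table,
)

CLOSE_INBREEDING_THRESHOLD = 0.125

STAT_NAMES = (
    "pct_pairs_remating",
    "pct_females_remating",
    "pct_males_remating",
    "mean_full_sibship",
    "mean_males_per_offspring_ratio",
    "mean_matrilines_per_females_ratio",
    "mean_pairwise_relatedness",
    "mean_f",
    "n_nonzero_f",
    "n_f_ge_0125",
)

#: statistics that depend only on the sire assignment (no kinship matrix)
SIRE_ONLY_STATS = STAT_NAMES[:6]


@dataclass(frozen=True)
class StatBlock:
    pct_pairs_remating: float
    pct_females_remating: float
    pct_males_remating: float
    mean_full_sibship: float
    mean_males_per_offspring_ratio: float
    mean_matrilines_per_females_ratio: float
    mean_pairwise_relatedness: float
    mean_f: float
    n_nonzero_f: float
    n_f_ge_0125: float

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class PairOpportunity:
    """One mated (dam, sire) pair with its mated and opportunity rut years."""

    female_id: str
    male_id: str
    mated_years: frozenset
    opportunity_years: frozenset


def pair_opportunities(
    ped: Pedigree, calvings: pd.DataFrame, census: pd.DataFrame
) -> list[PairOpportunity]:
    """Every mated pair with the years it mated and could have mated.

    Opportunity years are the mated years plus every other year in which the
    dam conceived (has a calving with that rut year) and the sire was
    censused holding a harem.
    """
    calvings = census_mod.annotate_calvings(calvings)
    census = census_mod.normalise_census(census)
    df = ped.to_frame()
    sire_of = dict(zip(df["id"], df["father_id"]))
    dam_of = dict(zip(df["id"], df["mother_id"]))

    female_years: dict[str, set] = {}
    for row in calvings.itertuples(index=False):
        female_years.setdefault(row.female_id, set()).add(int(row.rut_year))
    hh = census[census["harem_holder"]]
    male_years = {m: set(g["rut_year"]) for m, g in hh.groupby("individual_id")}

    mated: dict[tuple[str, str], set] = {}
    for row in calvings.itertuples(index=False):
        sire = sire_of.get(row.calf_id)
        if sire is None or (isinstance(sire, float) and math.isnan(sire)):
            continue
        dam = dam_of.get(row.calf_id)
        if dam is None:
            raise ValueError(f"calf {row.calf_id!r} has a sire but no dam")
        mated.setdefault((str(dam), str(sire)), set()).add(int(row.rut_year))

    out = []
    for (dam, sire), years in sorted(mated.items()):
        opportunity = set(years)
        shared = female_years.get(dam, set()) & male_years.get(sire, set())
        opportunity |= shared
        out.append(
            PairOpportunity(
                female_id=dam,
                male_id=sire,
                mated_years=frozenset(years),
                opportunity_years=frozenset(opportunity),
            )
        )
    return out


def remating_stats(
    opportunities: list[PairOpportunity],
) -> tuple[float, float, float]:
    """(% pairs, % females, % males) re-mating among those with the opportunity.

    Denominators: pairs with a multi-year opportunity; females (males)
    appearing in at least one such pair.  A zero denominator yields nan.
    """
    multi = [p for p in opportunities if len(p.opportunity_years) >= 2]
    remated = [p for p in multi if len(p.mated_years) >= 2]

    def pct(num: set, den: set) -> float:
        return 100.0 * len(num) / len(den) if den else float("nan")

    pairs = pct(
        {(p.female_id, p.male_id) for p in remated},
        {(p.female_id, p.male_id) for p in multi},
    )
    females = pct({p.female_id for p in remated}, {p.female_id for p in multi})
    males = pct({p.male_id for p in remated}, {p.male_id for p in multi})
    return pairs, females, males


def female_mate_diversity(ped: Pedigree) -> float:
    """Mean over females of (distinct sires) / (calves with a known sire)."""
    df = ped.to_frame()
    known = df[df["mother_id"].notna() & df["father_id"].notna()]
    if known.empty:
        return float("nan")
    per_female = known.groupby("mother_id")["father_id"].agg(["nunique", "size"])
    return float((per_female["nunique"] / per_female["size"]).mean())


def intralineage_stat(ped: Pedigree, matrilines: pd.Series | None = None) -> float:
    """Mean over males of (distinct matrilines of mates) / (distinct mates).

    A mate with no known matriline counts as her own singleton lineage — the
    conservative direction, since collapsing unknowns into one lineage would
    manufacture intralineage polygyny.
    """
    df = ped.to_frame()
    known = df[df["mother_id"].notna() & df["father_id"].notna()]
    if known.empty:
        return float("nan")
    if matrilines is None:
        matrilines = matriline_table(ped)
    lineage = known["mother_id"].map(matrilines)
    lineage = lineage.fillna("singleton:" + known["mother_id"].astype(str))
    tmp = pd.DataFrame(
        {"sire": known["father_id"], "dam": known["mother_id"], "lineage": lineage}
    )
    per_male = tmp.groupby("sire").agg(
        mates=("dam", "nunique"), lineages=("lineage", "nunique")
    )
    return float((per_male["lineages"] / per_male["mates"]).mean())


def relatedness_stat(ped: Pedigree, kin: KinshipMatrix | None = None) -> float:
    """Mean additive relatedness 2K over all unordered distinct pairs."""
    n = len(ped)
    if n < 2:
        return float("nan")
    if kin is None:
        kin = compute_kinship(ped)
    K = kin.values
    total = K.sum() - np.trace(K)
    return float(2.0 * total / (n * (n - 1)))


def inbreeding_stats(
    ped: Pedigree, kin: KinshipMatrix | None = None
) -> tuple[float, int, int]:
    """(mean f over all individuals, #nonzero f, #f >= 0.125)."""
    f = compute_inbreeding(ped, kin).to_numpy()
    n_nonzero = int((f > 0).sum())
    n_close = int((f >= CLOSE_INBREEDING_THRESHOLD - 1e-12).sum())
    return float(f.mean()) if len(f) else float("nan"), n_nonzero, n_close


def stat_block(
    ped: Pedigree,
    calvings: pd.DataFrame,
    census: pd.DataFrame,
    matrilines: pd.Series | None = None,
) -> StatBlock:
    """Assemble all ten statistics for one pedigree."""
    pairs, females, males = remating_stats(pair_opportunities(ped, calvings, census))
    _, sibship_mean = full_sibship_sizes(ped)
    kin = compute_kinship(ped)
    mean_f, n_nonzero, n_close = inbreeding_stats(ped, kin)
    return StatBlock(
        pct_pairs_remating=pairs,
        pct_females_remating=females,
        pct_males_remating=males,
        mean_full_sibship=sibship_mean,
        mean_males_per_offspring_ratio=female_mate_diversity(ped),
        mean_matrilines_per_females_ratio=intralineage_stat(ped, matrilines),
        mean_pairwise_relatedness=relatedness_stat(ped, kin),
        mean_f=mean_f,
        n_nonzero_f=float(n_nonzero),
        n_f_ge_0125=float(n_close),
    )


class SireStatEngine:
    """Vectorised sire-dependent statistics for ensembles of sire draws.

    Precondition (holds for every scheme's draws and for generator truth):
    each calf's sire is censused holding a harem in the calf's rut year, so a
    pair's opportunity years are exactly the shared (dam conceived, male
    censused) years.

    Built once per study; ``compute(sires)`` then evaluates the six
    sire-dependent statistics for one assignment (array of male codes aligned
    with ``calf_ids``) in microseconds rather than by rebuilding a pedigree.
    """

    def __init__(
        self,
        calvings: pd.DataFrame,
        census: pd.DataFrame,
        matrilines: pd.Series | dict,
        focal_calves: list[str],
    ):
        calvings = census_mod.annotate_calvings(calvings)
        census = census_mod.normalise_census(census)
        cal = calvings.set_index("calf_id").loc[focal_calves]

        self.calf_ids = list(focal_calves)
        self.dam_ids = cal["female_id"].tolist()
        dams = pd.unique(cal["female_id"])
        self._dam_code = {d: k for k, d in enumerate(dams)}
        self.n_dams = len(dams)
        self.dam_codes = np.array([self._dam_code[d] for d in self.dam_ids])

        hh = census[census["harem_holder"]]
        self.male_ids = list(pd.unique(hh["individual_id"]))
        self._male_code = {m: k for k, m in enumerate(self.male_ids)}
        years = sorted(set(calvings["rut_year"]) | set(hh["rut_year"]))
        ycode = {y: k for k, y in enumerate(years)}
        self.year_codes = np.array([ycode[y] for y in cal["rut_year"]])

        FY = np.zeros((self.n_dams, len(years)), dtype=bool)
        for row in calvings.itertuples(index=False):
            d = self._dam_code.get(row.female_id)
            if d is not None:
                FY[d, ycode[int(row.rut_year)]] = True
        MY = np.zeros((len(self.male_ids), len(years)), dtype=bool)
        for m, y in zip(hh["individual_id"], hh["rut_year"]):
            MY[self._male_code[m], ycode[int(y)]] = True
        # pair (dam, male) has a multi-year opportunity iff >= 2 shared years
        self.multi_opportunity = (FY.astype(np.int32) @ MY.T.astype(np.int32)) >= 2

        if pd.Series(self.dam_ids).groupby(
            [self.dam_codes, self.year_codes]
        ).size().max() > 1:
            raise ValueError("a dam has two focal calves in one rut year")

        lin = pd.Series(self.dam_ids).map(dict(matrilines))
        lin = lin.fillna(pd.Series(self.dam_ids).radd("singleton:"))
        lin_codes = pd.factorize(lin)[0]
        # per-dam lineage code (constant within dam)
        self.dam_lineage = np.zeros(self.n_dams, dtype=np.int64)
        self.dam_lineage[self.dam_codes] = lin_codes
        self.calves_per_dam = np.bincount(self.dam_codes, minlength=self.n_dams)

    def male_code(self, male_id) -> int:
        return self._male_code[str(male_id)]

    def codes_for(self, sires) -> np.ndarray:
        return np.array([self._male_code[str(s)] for s in sires])

    def compute(self, sire_codes: np.ndarray) -> dict[str, float]:
        M = len(self.male_ids)
        pair = self.dam_codes.astype(np.int64) * M + sire_codes
        upair, counts = np.unique(pair, return_counts=True)
        udam = upair // M
        usire = upair % M

        multi = self.multi_opportunity[udam, usire]
        remated = counts >= 2

        def pct(num_mask, den_mask, labels):
            if not den_mask.any():
                return float("nan")
            return 100.0 * len(np.unique(labels[num_mask])) / len(
                np.unique(labels[den_mask])
            )

        n_multi = int(multi.sum())
        pct_pairs = 100.0 * int(remated.sum()) / n_multi if n_multi else float("nan")
        pct_females = pct(remated, multi, udam)
        pct_males = pct(remated, multi, usire)

        mean_sibship = float(counts.mean())

        distinct_sires = np.bincount(udam, minlength=self.n_dams)
        active = self.calves_per_dam > 0
        diversity = float(
            (distinct_sires[active] / self.calves_per_dam[active]).mean()
        )

        # intralineage: per sire, distinct lineages / distinct dams
        usires_all = np.unique(usire)
        mates = np.bincount(usire, minlength=M)  # distinct dams per sire (upair unique)
        pairlin = usire.astype(np.int64) * (self.dam_lineage.max() + 1) + self.dam_lineage[udam]
        ulin = np.unique(pairlin)
        lin_per_sire = np.bincount(
            (ulin // (self.dam_lineage.max() + 1)).astype(np.int64), minlength=M
        )
        intralineage = float(
            (lin_per_sire[usires_all] / mates[usires_all]).mean()
        )

        return {
            "pct_pairs_remating": pct_pairs,
            "pct_females_remating": pct_females,
            "pct_males_remating": pct_males,
            "mean_full_sibship": mean_sibship,
            "mean_males_per_offspring_ratio": diversity,
            "mean_matrilines_per_females_ratio": intralineage,
        }
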