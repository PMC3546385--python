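"""Synthetic polygynous study generator.

Emulates a multi-decade individual-based study of a harem-breeding deer
population: philopatric females clustered in matrilineal home ranges, males
returning each autumn to site-faithful rut locations and holding harems over
contiguous tenure blocks, an autumn rut with a concentrated oestrus peak,
and calves born after an exact 235-day gestation.  Two behavioural dials
drive the phenomena the analysis pipeline is built to detect:

* ``fidelity_phi`` — probability a conceiving female re-uses her previous
  sire when he is holding a harem on her conception day;
* ``natal_philopatry`` — probability a male's home rut site is placed near
  his mother's home range, which makes related males rut near one another.

Every conception's eligible set, chosen sire and fidelity flag are written to
a truth log so pipeline statistics can be audited against construction.

The generator is deterministic under a master seed and writes the four
standard CSVs (individuals, census, calvings, pedigree) plus the truth log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .census import GESTATION_DAYS
from .pedigree import FEMALE, MALE, Pedigree


class GenerationError(RuntimeError):
    pass


def _default_conception_prob() -> dict:
    # annual probability a female of the given age conceives
    return {2: 0.30, 3: 0.45, 4: 0.50, "prime": 0.55, "old": 0.45, "senescent": 0.25}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic population.

    Spatial units are metres on a grid of 100 m census cells; dates are real
    calendar dates.  Defaults describe the full-scale study: 36 rut years,
    85 founder matrilines, a 4 km x 2.5 km study area, male breeding success
    peaking at 8-10 years, a mid-October oestrus peak with most conceptions
    inside two weeks, and a fifth of females re-using their previous mate.
    """

    n_years: int = 36
    start_year: int = 1971
    n_founder_females: int = 85
    n_founder_males: int = 40
    grid_cells: tuple[int, int] = (40, 25)
    cell_size_m: float = 100.0

    # demography
    founder_female_ages: tuple[int, int] = (2, 12)
    founder_male_ages: tuple[int, int] = (4, 12)
    conception_prob: dict = field(default_factory=_default_conception_prob)
    female_survival: float = 0.85
    male_survival: float = 0.85
    old_age: int = 13
    senescent_survival: float = 0.70
    max_age: int = 18
    male_min_rut_age: int = 5
    male_max_rut_age: int = 16

    # male rut behaviour
    abs_peak_age: float = 9.0
    abs_peak_height: float = 16.0  # quadratic: height - (age - peak)^2
    tenure_mean_days: float = 14.0
    tenure_sd_days: float = 4.0
    tenure_min_days: int = 5
    male_date_offset_sd: float = 8.0  # repeatable per-male median rut date
    male_date_jitter_sd: float = 2.0  # annual jitter on the median date
    male_site_fidelity_sd: float = 100.0  # annual displacement of rut site
    male_daily_jitter_sd: float = 50.0
    natal_philopatry: float = 0.5  # pi_m
    natal_site_sd: float = 150.0

    # female spatial and oestrus structure
    matriline_dispersion: float = 100.0
    female_annual_jitter_sd: float = 30.0
    oestrus_peak_month: int = 10
    oestrus_peak_day: int = 10
    matriline_oestrus_sd: float = 3.0
    oestrus_sd: float = 5.0
    oestrus_clip_days: tuple[int, int] = (-40, 60)
    female_census_halfwidth: int = 7
    female_census_interval: int = 3

    # mating rule
    gestation_days: int = GESTATION_DAYS
    fidelity_phi: float = 0.2
    kappa: float = 1.0  # harem monopolisation: exponent on the whole sire weight
    sire_distance_scale: float = 60.0  # metres; weight ~ exp(-d / scale)
    harem_attachment: float = 0.5  # P(dam censused inside the sire's harem)
    harem_location_sd: float = 40.0

    def __post_init__(self):
        if self.gestation_days != GESTATION_DAYS:
            raise ValueError("gestation is fixed at 235 days")
        for p in (self.fidelity_phi, self.natal_philopatry):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def extent_m(self) -> tuple[float, float]:
        return (
            self.grid_cells[0] * self.cell_size_m,
            self.grid_cells[1] * self.cell_size_m,
        )

    def abs_curve(self, age) -> np.ndarray:
        """Age-peaked annual breeding success used for male weighting."""
        age = np.asarray(age, dtype=float)
        return np.maximum(self.abs_peak_height - (age - self.abs_peak_age) ** 2, 0.0)

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    @classmethod
    def small(cls, **kw) -> "GeneratorConfig":
        """Reduced population scale for quick, replicate-heavy runs."""
        base = dict(
            n_years=12,
            n_founder_females=18,
            n_founder_males=14,
            founder_male_ages=(4, 7),
            grid_cells=(12, 8),
        )
        base.update(kw)
        return cls(**base)


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    seed: int
    individuals: pd.DataFrame
    census: pd.DataFrame
    calvings: pd.DataFrame
    truth: pd.DataFrame

    @property
    def pedigree(self) -> Pedigree:
        return Pedigree(self.individuals, validate=False)

    @property
    def matrilines(self) -> pd.Series:
        return pd.Series(
            dict(zip(self.individuals["id"], self.individuals["matriline_id"]))
        )

    def write_csvs(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(outdir / "individuals.csv", index=False)
        census = self.census.copy()
        census["date"] = census["date"].dt.strftime("%Y-%m-%d")
        census.to_csv(outdir / "census.csv", index=False)
        calv = self.calvings[["female_id", "calf_id", "calf_birth_date"]].copy()
        calv["calf_birth_date"] = pd.to_datetime(calv["calf_birth_date"]).dt.strftime("%Y-%m-%d")
        calv.to_csv(outdir / "calvings.csv", index=False)
        ped = self.individuals[["id", "mother_id", "father_id"]]
        ped.rename(columns={"id": "calf_id"}).to_csv(outdir / "pedigree.csv", index=False)
        truth = self.truth.copy()
        truth["conception_date"] = pd.to_datetime(truth["conception_date"]).dt.strftime("%Y-%m-%d")
        truth.to_csv(outdir / "truth.csv", index=False)


class _Generator:
    def __init__(self, config: GeneratorConfig, seed: int):
        self.cfg = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        # per-individual state, keyed by id
        self.sex: dict[str, str] = {}
        self.birth_year: dict[str, int] = {}
        self.death_year: dict[str, int | None] = {}
        self.mother: dict[str, str | None] = {}
        self.father: dict[str, str | None] = {}
        self.matriline: dict[str, str | None] = {}
        self.female_home: dict[str, np.ndarray] = {}
        self.male_home: dict[str, np.ndarray] = {}
        self.male_date_offset: dict[str, float] = {}
        self.prev_sire: dict[str, str] = {}
        self.alive: set[str] = set()
        self.order: list[str] = []

        self.census_rows: list[tuple] = []
        self.calving_rows: list[tuple] = []
        self.truth_rows: list[dict] = []
        self._mat_effect: dict[tuple, float] = {}
        self._calf_counter = 0

    # -- helpers -----------------------------------------------------------

    def _add(self, iid, sex, by, mother=None, father=None, matriline=None):
        self.sex[iid] = sex
        self.birth_year[iid] = by
        self.death_year[iid] = None
        self.mother[iid] = mother
        self.father[iid] = father
        self.matriline[iid] = matriline
        self.alive.add(iid)
        self.order.append(iid)

    def _uniform_point(self) -> np.ndarray:
        w, h = self.cfg.extent_m
        return self.rng.uniform([0, 0], [w, h])

    def _clip(self, p: np.ndarray) -> np.ndarray:
        w, h = self.cfg.extent_m
        return np.clip(p, [0.0, 0.0], [w, h])

    def _snap(self, p: np.ndarray) -> tuple[int, int]:
        c = self.cfg.cell_size_m
        q = self._clip(np.round(p / c) * c)
        return int(q[0]), int(q[1])

    def _age(self, iid, year) -> int:
        return year - self.birth_year[iid]

    def _conceives(self, age) -> float:
        cp = self.cfg.conception_prob
        if age in cp:
            return cp[age]
        if age <= 12:
            return cp["prime"]
        if age <= 15:
            return cp["old"]
        return cp["senescent"]

    def _mat_oestrus_effect(self, matriline, year) -> float:
        key = (matriline, year)
        if key not in self._mat_effect:
            self._mat_effect[key] = self.rng.normal(0.0, self.cfg.matriline_oestrus_sd)
        return self._mat_effect[key]

    def _assign_male_home(self, iid):
        cfg = self.cfg
        if self.mother[iid] is not None and self.rng.random() < cfg.natal_philopatry:
            centre = self.female_home[self.mother[iid]]
        else:
            centre = self.matriline_centroids[
                self.rng.integers(len(self.matriline_centroids))
            ]
        self.male_home[iid] = self._clip(
            centre + self.rng.normal(0.0, cfg.natal_site_sd, size=2)
        )
        self.male_date_offset[iid] = self.rng.normal(0.0, cfg.male_date_offset_sd)

    # -- main loop ---------------------------------------------------------

    def run(self) -> SyntheticStudy:
        cfg = self.cfg
        self.matriline_centroids = [self._uniform_point() for _ in range(cfg.n_founder_females)]
        for k in range(cfg.n_founder_females):
            iid = f"F{k:04d}"
            age = int(self.rng.integers(cfg.founder_female_ages[0], cfg.founder_female_ages[1] + 1))
            self._add(iid, FEMALE, cfg.start_year - age, matriline=iid)
            self.female_home[iid] = self._clip(
                self.matriline_centroids[k]
                + self.rng.normal(0.0, cfg.matriline_dispersion, size=2)
            )
        for k in range(cfg.n_founder_males):
            iid = f"M{k:04d}"
            age = int(self.rng.integers(cfg.founder_male_ages[0], cfg.founder_male_ages[1] + 1))
            self._add(iid, MALE, cfg.start_year - age)
            self._assign_male_home(iid)

        for year in range(cfg.start_year, cfg.start_year + cfg.n_years):
            self._run_year(year)
            self._apply_mortality(year)

        individuals = pd.DataFrame(
            {
                "id": self.order,
                "sex": [self.sex[i] for i in self.order],
                "birth_year": [self.birth_year[i] for i in self.order],
                "death_year": [self.death_year[i] for i in self.order],
                "mother_id": [self.mother[i] for i in self.order],
                "father_id": [self.father[i] for i in self.order],
                "matriline_id": [self.matriline[i] for i in self.order],
            }
        )
        census = pd.DataFrame(
            self.census_rows,
            columns=["rut_year", "date", "individual_id", "easting", "northing", "harem_holder"],
        )
        census["date"] = pd.to_datetime(census["date"])
        calvings = pd.DataFrame(
            self.calving_rows, columns=["female_id", "calf_id", "calf_birth_date"]
        )
        calvings["calf_birth_date"] = pd.to_datetime(calvings["calf_birth_date"])
        truth = pd.DataFrame(self.truth_rows)
        return SyntheticStudy(
            config=cfg,
            seed=self.seed,
            individuals=individuals,
            census=census,
            calvings=calvings,
            truth=truth,
        )

    def _run_year(self, year: int) -> None:
        cfg = self.cfg
        peak = pd.Timestamp(year=year, month=cfg.oestrus_peak_month, day=cfg.oestrus_peak_day)

        # --- male tenures and census
        rutting = [
            i
            for i in sorted(self.alive)
            if self.sex[i] == MALE
            and cfg.male_min_rut_age <= self._age(i, year) <= cfg.male_max_rut_age
        ]
        if not rutting:
            raise GenerationError(
                f"no rutting males in {year} (seed {self.seed}); population unviable"
            )
        site: dict[str, np.ndarray] = {}
        tenure: dict[str, tuple[int, int]] = {}  # day-offsets from peak, inclusive
        for m in rutting:
            site[m] = self._clip(
                self.male_home[m] + self.rng.normal(0.0, cfg.male_site_fidelity_sd, size=2)
            )
            median = self.male_date_offset[m] + self.rng.normal(0.0, cfg.male_date_jitter_sd)
            length = max(
                int(round(self.rng.normal(cfg.tenure_mean_days, cfg.tenure_sd_days))),
                cfg.tenure_min_days,
            )
            start = int(round(median - length / 2))
            tenure[m] = (start, start + length - 1)
            for d in range(start, start + length):
                x, y = self._snap(site[m] + self.rng.normal(0.0, cfg.male_daily_jitter_sd, size=2))
                self.census_rows.append(
                    (year, peak + pd.Timedelta(days=d), m, x, y, True)
                )

        def active_on(day: int) -> list[str]:
            return [m for m in rutting if tenure[m][0] <= day <= tenure[m][1]]

        # --- conceptions
        females = [
            i
            for i in sorted(self.alive)
            if self.sex[i] == FEMALE and 2 <= self._age(i, year) <= cfg.max_age
        ]
        for f in females:
            if self.rng.random() >= self._conceives(self._age(f, year)):
                continue
            mat = self.matriline[f]
            offset = self.rng.normal(0.0, cfg.oestrus_sd) + (
                self._mat_oestrus_effect(mat, year) if mat is not None else 0.0
            )
            day = int(round(np.clip(offset, *cfg.oestrus_clip_days)))
            # conception needs a harem-holding male; move to the nearest
            # active day inside the 11-day window, else the nearest active
            # day of the season
            if not active_on(day):
                candidates = [
                    d
                    for d in range(day - 5, day + 6)
                    if active_on(d)
                ]
                if not candidates:
                    candidates = [
                        d
                        for d in range(min(t[0] for t in tenure.values()),
                                       max(t[1] for t in tenure.values()) + 1)
                        if active_on(d)
                    ]
                if not candidates:
                    continue
                day = min(candidates, key=lambda d: abs(d - day))
            self._conceive(f, year, peak, day, site, active_on)

    def _conceive(self, female, year, peak, day, site, active_on) -> None:
        cfg = self.cfg
        loc = self._clip(
            self.female_home[female]
            + self.rng.normal(0.0, cfg.female_annual_jitter_sd, size=2)
        )
        eligible = active_on(day)
        prev = self.prev_sire.get(female)
        fidelity = False
        if prev is not None and prev in eligible and self.rng.random() < cfg.fidelity_phi:
            sire = prev
            fidelity = True
        else:
            ages = np.array([self._age(m, year) for m in eligible], dtype=float)
            d = np.array([np.hypot(*(site[m] - loc)) for m in eligible])
            # kappa concentrates success on the locally dominant male:
            # 0 = uniform among active males, large = winner-take-all
            w = np.maximum(self.cfg.abs_curve(ages), 1e-9) * np.exp(
                -d / cfg.sire_distance_scale
            )
            w = np.maximum(w, 1e-12) ** cfg.kappa
            sire = eligible[self.rng.choice(len(eligible), p=w / w.sum())]

        # where the census finds her: inside the sire's harem (herded) with
        # probability harem_attachment, else on her own range
        if self.rng.random() < cfg.harem_attachment:
            census_loc = self._clip(
                site[sire] + self.rng.normal(0.0, cfg.harem_location_sd, size=2)
            )
        else:
            census_loc = loc

        conception = peak + pd.Timedelta(days=day)
        birth = conception + pd.Timedelta(days=cfg.gestation_days)
        self._calf_counter += 1
        calf = f"C{self._calf_counter:05d}"
        sex = FEMALE if self.rng.random() < 0.5 else MALE
        self._add(
            calf, sex, birth.year, mother=female, father=sire,
            matriline=self.matriline[female],
        )
        if sex == FEMALE:
            self.female_home[calf] = self._clip(
                self.female_home[female]
                + self.rng.normal(0.0, cfg.matriline_dispersion, size=2)
            )
        else:
            self._assign_male_home(calf)
        self.prev_sire[female] = sire
        self.calving_rows.append((female, calf, birth))

        # female census records around her window
        x, y = self._snap(census_loc)
        for d in range(
            -cfg.female_census_halfwidth,
            cfg.female_census_halfwidth + 1,
            cfg.female_census_interval,
        ):
            self.census_rows.append(
                (year, conception + pd.Timedelta(days=d), female, x, y, False)
            )
        self.truth_rows.append(
            {
                "calf_id": calf,
                "dam_id": female,
                "sire_id": sire,
                "rut_year": year,
                "conception_date": conception,
                "n_eligible": len(active_on(day)),
                "fidelity_reuse": fidelity,
                "dam_sire_distance_m": float(np.hypot(*(site[sire] - census_loc))),
            }
        )

    def _apply_mortality(self, year: int) -> None:
        cfg = self.cfg
        for i in sorted(self.alive):
            age = self._age(i, year)
            if age < 0:  # born next spring; alive
                continue
            s = cfg.female_survival if self.sex[i] == FEMALE else cfg.male_survival
            if age >= cfg.old_age:
                s = min(s, cfg.senescent_survival)
            if age >= cfg.max_age or self.rng.random() > s:
                self.death_year[i] = year
                self.alive.discard(i)


def generate_study(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study; deterministic under ``seed``."""
    return _Generator(config or GeneratorConfig(), seed).run()


def generate_viable_study(
    config: GeneratorConfig | None = None, seed: int = 0, max_tries: int = 5
) -> SyntheticStudy:
    """Like ``generate_study`` but demographically unviable seeds (all
    rutting males lost in some year — rare at small scale) deterministically
    fall through to ``seed + k * 1_000_003``.  For replicate-over-seeds
    experiments where a crash on one seed is worse than its exclusion."""
    last = None
    for k in range(max_tries):
        try:
            return generate_study(config, seed + k * 1_000_003)
        except GenerationError as e:
            last = e
    raise last


def demographic_summary(study: SyntheticStudy) -> pd.Series:
    """Calibration summary: breeding-year counts, mate counts, sire proximity."""
    truth = study.truth
    if truth.empty:
        return pd.Series(
            {
                "n_individuals": len(study.individuals),
                "n_conceptions": 0,
                "mean_breeding_years_per_female": float("nan"),
                "mean_distinct_mates_per_female": float("nan"),
                "mean_sire_age": float("nan"),
                "frac_sires_within_500m": float("nan"),
                "frac_sires_within_100m": float("nan"),
            }
        )
    by_female = truth.groupby("dam_id").agg(
        years=("rut_year", "nunique"), mates=("sire_id", "nunique")
    )
    birth = dict(zip(study.individuals["id"], study.individuals["birth_year"]))
    sire_age = truth["rut_year"] - truth["sire_id"].map(birth)
    return pd.Series(
        {
            "n_individuals": float(len(study.individuals)),
            "n_conceptions": float(len(truth)),
            "mean_breeding_years_per_female": float(by_female["years"].mean()),
            "mean_distinct_mates_per_female": float(by_female["mates"].mean()),
            "mean_sire_age": float(sire_age.mean()),
            "frac_sires_within_500m": float((truth["dam_sire_distance_m"] <= 500).mean()),
            "frac_sires_within_100m": float((truth["dam_sire_distance_m"] <= 100).mean()),
        }
    )
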