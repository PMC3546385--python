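"""Rut census and calving records; oestrus windows; mate-eligibility.

The rut census records, day by day, where each animal stood (on a 100 m
grid) and which males held harems.  Conception dates are estimated by
backdating each calf's birth by the 235-day gestation, and the dam is assumed
to have conceived within the 11-day "oestrus window" centred on that date.
Candidate males of a rut year are those censused holding a harem at least
once that year; candidate females are those that calved the following spring.

Eligibility of a male for a given dam-year tightens with the scheme:
every candidate male (RANDOM); holding a harem on at least one day of her
window (TEMPORAL); additionally within 500 m or 100 m of her location on the
conception day (SPATIAL_500 / SPATIAL_100).  The two weighted schemes share
the SPATIAL_100 eligible set — weighting acts at sampling time, not on
eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schemes import RANDOM, Scheme, get_scheme

GESTATION_DAYS = 235
WINDOW_HALF_DAYS = 5  # 11 inclusive days

CENSUS_COLUMNS = ["rut_year", "date", "individual_id", "easting", "northing", "harem_holder"]
CALVING_COLUMNS = ["female_id", "calf_id", "calf_birth_date"]


class CensusValidationError(ValueError):
    pass


@dataclass(frozen=True)
class OestrusWindow:
    """11-day conception window for one female in one rut year."""

    female_id: str
    rut_year: int
    conception_date: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp


def oestrus_window(calf_birth_date, female_id: str | None = None) -> OestrusWindow:
    """Backdate a birth by 235 days and spread the window ±5 days."""
    birth = pd.Timestamp(calf_birth_date)
    conception = birth - pd.Timedelta(days=GESTATION_DAYS)
    half = pd.Timedelta(days=WINDOW_HALF_DAYS)
    return OestrusWindow(
        female_id=female_id,
        rut_year=int(conception.year),
        conception_date=conception,
        start=conception - half,
        end=conception + half,
    )


# ---------------------------------------------------------------------------
# table IO / normalisation


def read_census(path) -> pd.DataFrame:
    return normalise_census(pd.read_csv(path))


def read_calvings(path) -> pd.DataFrame:
    return annotate_calvings(pd.read_csv(path))


def normalise_census(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusValidationError(f"census table missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    df["rut_year"] = df["rut_year"].astype(int)
    df["individual_id"] = df["individual_id"].astype(str)
    for c in ("easting", "northing"):
        df[c] = df[c].astype(float)
        if not np.allclose(np.mod(df[c], 100.0), 0.0):
            raise CensusValidationError(f"{c} not on the 100 m grid")
    df["harem_holder"] = df["harem_holder"].astype(bool)
    return df[CENSUS_COLUMNS]


def annotate_calvings(df: pd.DataFrame) -> pd.DataFrame:
    """Add conception_date and rut_year (year of conception) columns."""
    df = df.copy()
    missing = [c for c in CALVING_COLUMNS if c not in df.columns]
    if missing:
        raise CensusValidationError(f"calving table missing columns {missing}")
    if df["female_id"].isna().any():
        raise CensusValidationError("calving with no matching female record")
    df["female_id"] = df["female_id"].astype(str)
    df["calf_id"] = df["calf_id"].astype(str)
    df["calf_birth_date"] = pd.to_datetime(df["calf_birth_date"])
    df["conception_date"] = df["calf_birth_date"] - pd.Timedelta(days=GESTATION_DAYS)
    df["rut_year"] = df["conception_date"].dt.year.astype(int)
    return df


def build_windows(calvings: pd.DataFrame) -> dict[tuple[str, int], OestrusWindow]:
    """(female_id, rut_year) -> OestrusWindow, from annotated calvings."""
    calvings = annotate_calvings(calvings)
    out = {}
    for row in calvings.itertuples(index=False):
        w = oestrus_window(row.calf_birth_date, female_id=row.female_id)
        out[(row.female_id, w.rut_year)] = w
    return out


# ---------------------------------------------------------------------------
# candidates and eligibility


@dataclass
class CandidateTable:
    """Per-rut-year candidate females (calved next spring) and males (held a harem)."""

    females: dict[int, frozenset]
    males: dict[int, frozenset]

    def candidate_females(self, year: int) -> frozenset:
        return self.females.get(int(year), frozenset())

    def candidate_males(self, year: int) -> frozenset:
        return self.males.get(int(year), frozenset())

    @property
    def years(self) -> list[int]:
        return sorted(set(self.females) | set(self.males))


def build_candidates(census: pd.DataFrame, calvings: pd.DataFrame) -> CandidateTable:
    census = normalise_census(census)
    calvings = annotate_calvings(calvings)
    females: dict[int, set] = {}
    for row in calvings.itertuples(index=False):
        females.setdefault(int(row.rut_year), set()).add(row.female_id)
    males: dict[int, set] = {}
    hh = census[census["harem_holder"]]
    for year, grp in hh.groupby("rut_year"):
        males[int(year)] = set(grp["individual_id"])
    return CandidateTable(
        females={y: frozenset(v) for y, v in females.items()},
        males={y: frozenset(v) for y, v in males.items()},
    )


def female_location(
    census: pd.DataFrame, window: OestrusWindow
) -> tuple[float, float] | None:
    """Dam's grid location during her window: the censused day nearest to the
    estimated conception date, or None if she was never censused in-window."""
    recs = census[
        (census["individual_id"] == window.female_id)
        & (census["date"] >= window.start)
        & (census["date"] <= window.end)
    ]
    if recs.empty:
        return None
    gap = (recs["date"] - window.conception_date).abs()
    best = recs.loc[gap.idxmin()]
    return float(best["easting"]), float(best["northing"])


def eligible_males(
    female_id: str,
    rut_year: int,
    scheme: Scheme | str,
    census: pd.DataFrame,
    windows: dict[tuple[str, int], OestrusWindow],
    candidates: CandidateTable | None = None,
) -> list[str]:
    """Males a dam could have conceived by in a given year under a scheme.

    Returns a sorted id list.  For spatial schemes, a dam with no in-window
    census record yields an empty list (the simulator's fallback policy
    decides what happens next).

    Raises KeyError if the female has no oestrus window for the year and the
    scheme needs one.
    """
    scheme = get_scheme(scheme)
    rut_year = int(rut_year)
    if not pd.api.types.is_datetime64_any_dtype(census["date"]):
        census = normalise_census(census)
    if candidates is None:
        # candidate males only; candidate females are irrelevant here
        hh = census[(census["harem_holder"]) & (census["rut_year"] == rut_year)]
        cand = frozenset(hh["individual_id"])
    else:
        cand = candidates.candidate_males(rut_year)
    if scheme == RANDOM or not scheme.temporal:
        return sorted(cand)

    try:
        window = windows[(str(female_id), rut_year)]
    except KeyError:
        raise KeyError(
            f"female {female_id!r} has no oestrus window for rut year {rut_year}"
        ) from None

    hh = census[
        (census["harem_holder"])
        & (census["date"] >= window.start)
        & (census["date"] <= window.end)
        & (census["individual_id"].isin(cand))
    ]
    if scheme.radius_m is None:
        return sorted(set(hh["individual_id"]))

    loc = female_location(census, window)
    if loc is None:
        return []
    d = np.hypot(hh["easting"] - loc[0], hh["northing"] - loc[1])
    near = hh.loc[d <= scheme.radius_m, "individual_id"]
    return sorted(set(near))
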