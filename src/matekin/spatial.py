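"""Spatial genetic structure of rutting males.

Do related males rut near one another?  Each male's lifetime rutting
location is the mean of his harem-holding census records; for every
unordered pair of located males we take the additive relatedness (2K from
the pedigree) and the Euclidean distance between their mean locations, then
estimate the slope of relatedness on distance.

Pairwise records are non-independent (each male enters n-1 pairs), so the
slope is estimated after removing additive per-male effects from both the
relatedness and distance matrices by iterative double-centering over the two
identity margins, and inference is purely permutational: whole location
assignments are shuffled among males (preserving both the location multiset
and the relatedness matrix) and the slope recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import census as census_mod
from .pedigree import KinshipMatrix, MALE, Pedigree, compute_kinship

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaleRutLocation:
    male_id: str
    mean_easting: float
    mean_northing: float
    n_records: int


@dataclass(frozen=True)
class SpatialModelResult:
    slope: float  # relatedness per metre
    intercept: float
    p_permutation: float
    alternative: str
    n_pairs: int
    n_males: int
    n_permutations: int
    perm_slopes: np.ndarray


def male_mean_locations(census: pd.DataFrame) -> list[MaleRutLocation]:
    """Lifetime mean rutting location per male over harem-holding records."""
    census = census_mod.normalise_census(census)
    hh = census[census["harem_holder"]]
    n_unlocated = census.loc[~census["individual_id"].isin(hh["individual_id"]),
                             "individual_id"].nunique()
    if n_unlocated:
        logger.info("%d censused individuals have no harem record and are omitted",
                    n_unlocated)
    grp = hh.groupby("individual_id").agg(
        mean_easting=("easting", "mean"),
        mean_northing=("northing", "mean"),
        n_records=("easting", "size"),
    )
    return [
        MaleRutLocation(m, float(r.mean_easting), float(r.mean_northing), int(r.n_records))
        for m, r in grp.iterrows()
    ]


def pairwise_table(
    kin: KinshipMatrix, locations: list[MaleRutLocation]
) -> pd.DataFrame:
    """Relatedness (2K) and distance (m) for every unordered pair of males."""
    males = [l.male_id for l in locations]
    pos = np.array([[l.mean_easting, l.mean_northing] for l in locations])
    idx = [kin._pos[m] for m in males]
    R = 2.0 * kin.values[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(males), k=1)
    d = np.hypot(*(pos[iu] - pos[ju]).T)
    return pd.DataFrame(
        {
            "male1": [males[i] for i in iu],
            "male2": [males[j] for j in ju],
            "relatedness": R[iu, ju],
            "distance": d,
        }
    )


def _double_center(M: np.ndarray) -> np.ndarray:
    """Residual of the additive two-margin model m_ij = mu + a_i + a_j.

    Least squares over the off-diagonal entries of a complete symmetric
    matrix has a closed form: with r_i the off-diagonal row sums and T their
    total, mu = T / (n(n-1)) and a_i = (r_i - (n-1) mu) / (n-2).  Subtracting
    mu + a_i + a_j leaves the matrix with (numerically) zero margins, i.e.
    the limit of alternately centering rows and columns.
    """
    A = M.astype(float).copy()
    n = A.shape[0]
    np.fill_diagonal(A, 0.0)
    r = A.sum(axis=1)
    mu = r.sum() / (n * (n - 1))
    a = (r - (n - 1) * mu) / (n - 2)
    A = A - mu - a[:, None] - a[None, :]
    np.fill_diagonal(A, 0.0)
    return A


def fit_relatedness_distance(
    pairs_or_kin,
    locations: list[MaleRutLocation] | None = None,
    n_permutations: int = 999,
    seed: int | None = 0,
    alternative: str = "less",
) -> SpatialModelResult:
    """Slope of male relatedness on rut-site distance with a permutation test.

    Accepts either a square relatedness matrix + locations (preferred: the
    permutation reassigns whole locations among males) or a KinshipMatrix +
    locations.  ``alternative='less'`` tests for a negative slope (related
    males rutting closer together), the directional hypothesis of interest;
    'greater' and 'two-sided' are available for reuse.
    """
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError("alternative must be less/greater/two-sided")
    if isinstance(pairs_or_kin, KinshipMatrix):
        if locations is None:
            raise ValueError("locations required with a KinshipMatrix")
        males = [l.male_id for l in locations]
        idx = [pairs_or_kin._pos[m] for m in males]
        R = 2.0 * pairs_or_kin.values[np.ix_(idx, idx)]
        pos = np.array([[l.mean_easting, l.mean_northing] for l in locations])
    else:
        R = np.asarray(pairs_or_kin, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("expected a square relatedness matrix")
        if locations is None:
            raise ValueError("locations required")
        pos = np.array([[l.mean_easting, l.mean_northing] for l in locations])
    n = R.shape[0]
    if n < 3:
        raise ValueError("need >= 3 located males")

    def distmat(p):
        diff = p[:, None, :] - p[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    D = distmat(pos)
    if np.ptp(D[np.triu_indices(n, k=1)]) == 0:
        raise ValueError("all pairwise distances equal: degenerate design")

    Rc = _double_center(R)
    mask = np.triu_indices(n, k=1)

    def slope_of(Dmat):
        Dc = _double_center(Dmat)
        x, y = Dc[mask], Rc[mask]
        denom = float(x @ x)
        return float(x @ y) / denom if denom > 0 else 0.0

    slope = slope_of(D)
    # intercept of the raw (uncentred) least-squares line, for reporting
    x_raw, y_raw = D[mask], R[mask]
    intercept = float(y_raw.mean() - slope * x_raw.mean())

    rng = np.random.default_rng(seed)
    perm_slopes = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        perm_slopes[b] = slope_of(distmat(pos[perm]))

    if alternative == "less":
        extreme = int((perm_slopes <= slope).sum())
    elif alternative == "greater":
        extreme = int((perm_slopes >= slope).sum())
    else:
        extreme = int((np.abs(perm_slopes) >= abs(slope)).sum())
    p = (1 + extreme) / (1 + n_permutations)

    return SpatialModelResult(
        slope=slope,
        intercept=intercept,
        p_permutation=p,
        alternative=alternative,
        n_pairs=n * (n - 1) // 2,
        n_males=n,
        n_permutations=n_permutations,
        perm_slopes=perm_slopes,
    )


def male_spatial_structure(
    ped: Pedigree,
    census: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = 0,
    alternative: str = "less",
) -> tuple[SpatialModelResult, pd.DataFrame]:
    """End-to-end: locations, pairwise table, slope + permutation p."""
    kin = compute_kinship(ped)
    locs = [
        l for l in male_mean_locations(census)
        if l.male_id in ped and ped.sex_of(l.male_id) == MALE
    ]
    result = fit_relatedness_distance(
        kin, locs, n_permutations=n_permutations, seed=seed, alternative=alternative
    )
    return result, pairwise_table(kin, locs)
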