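"""One-tailed Z tests of an observed statistic against a simulation envelope.

Each null scheme's ensemble supplies a mean and a sample standard deviation
(denominator n-1) for a statistic; z = (observed - mean) / sd and the
one-tailed p is the standard-normal tail in the direction of the hypothesis
(greater for the re-mating, sibship, relatedness and inbreeding statistics;
less for the two diversity ratios).  With several tests per hypothesis
family, significance is judged against a Bonferroni-corrected alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: direction of the one-tailed alternative for each statistic
DEFAULT_DIRECTIONS = {
    "pct_pairs_remating": "greater",
    "pct_females_remating": "greater",
    "pct_males_remating": "greater",
    "mean_full_sibship": "greater",
    "mean_males_per_offspring_ratio": "less",
    "mean_matrilines_per_females_ratio": "less",
    "mean_pairwise_relatedness": "greater",
    "mean_f": "greater",
    "n_nonzero_f": "greater",
    "n_f_ge_0125": "greater",
}

#: hypothesis families sharing one Bonferroni correction: the three re-mating
#: percentages form one 18-test family, the three inbreeding statistics
#: another; each remaining statistic is its own 6-test family.
DEFAULT_FAMILIES = {
    "pct_pairs_remating": "remating",
    "pct_females_remating": "remating",
    "pct_males_remating": "remating",
    "mean_full_sibship": "sibship",
    "mean_males_per_offspring_ratio": "mate_diversity",
    "mean_matrilines_per_females_ratio": "intralineage",
    "mean_pairwise_relatedness": "relatedness",
    "mean_f": "inbreeding",
    "n_nonzero_f": "inbreeding",
    "n_f_ge_0125": "inbreeding",
}


@dataclass(frozen=True)
class ZTestResult:
    statistic_name: str
    scheme: str
    observed: float
    sim_mean: float
    sim_sd: float
    z: float
    p_one_tailed: float
    direction: str
    n_tests: int
    alpha_bonferroni: float
    significant: bool


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def z_test(
    observed: float,
    ensemble_values,
    direction: str = "greater",
    statistic_name: str = "",
    scheme: str = "",
    n_tests: int = 1,
    family_alpha: float = 0.05,
) -> ZTestResult:
    """Z test of an observed value against an ensemble of null values.

    ``ensemble_values`` may also be a (mean, sd) pair, e.g. to reconstruct a
    test from a published envelope.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if isinstance(ensemble_values, tuple) and len(ensemble_values) == 2:
        mean, sd = map(float, ensemble_values)
    else:
        vals = np.asarray(ensemble_values, dtype=float)
        if vals.size < 2:
            raise ValueError("need >= 2 ensemble values")
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    if not sd > 0:
        raise ValueError("ensemble standard deviation is zero: test undefined")
    z = (float(observed) - mean) / sd
    p = float(sps.norm.sf(z) if direction == "greater" else sps.norm.cdf(z))
    p = max(p, np.finfo(float).tiny)
    alpha = bonferroni_alpha(family_alpha, n_tests)
    return ZTestResult(
        statistic_name=statistic_name,
        scheme=scheme,
        observed=float(observed),
        sim_mean=mean,
        sim_sd=sd,
        z=z,
        p_one_tailed=p,
        direction=direction,
        n_tests=n_tests,
        alpha_bonferroni=alpha,
        significant=p < alpha,
    )


def compare_all(
    observed_block,
    ensembles: dict,
    statistics: tuple[str, ...] | None = None,
    directions: dict[str, str] | None = None,
    families: dict[str, str] | None = None,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """One Z test per (statistic, scheme); returns a tidy results table.

    ``ensembles`` maps scheme name -> SimulationEnsemble (or a stats
    DataFrame).  The Bonferroni n for each test is the number of tests in its
    hypothesis family across all schemes.
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    families = {**DEFAULT_FAMILIES, **(families or {})}
    obs = observed_block.to_series() if hasattr(observed_block, "to_series") else pd.Series(observed_block)

    tables = {}
    for name, ens in ensembles.items():
        tables[str(name)] = ens.stats if hasattr(ens, "stats") else pd.DataFrame(ens)

    if statistics is None:
        common = set(obs.index)
        for t in tables.values():
            common &= set(t.columns)
        statistics = tuple(s for s in obs.index if s in common)

    plan = [(s, sch) for s in statistics for sch in tables]
    fam_sizes: dict[str, int] = {}
    for s, _ in plan:
        fam = families.get(s, s)
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1

    rows = []
    for s, sch in plan:
        if s not in tables[sch].columns:
            raise KeyError(f"ensemble {sch!r} lacks statistic {s!r}")
        res = z_test(
            obs[s],
            tables[sch][s].to_numpy(),
            direction=directions.get(s, "greater"),
            statistic_name=s,
            scheme=sch,
            n_tests=fam_sizes[families.get(s, s)],
            family_alpha=family_alpha,
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)


def format_p(p: float, floor: float = 1e-4) -> str:
    """Render p values the way the result tables print them."""
    return f"< {floor:g}" if p < floor else f"{p:.3g}"
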