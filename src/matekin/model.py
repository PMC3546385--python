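"""Model/Results facade over the analysis pipeline.

``MatingSystemModel`` holds one study's data (pedigree, rut census, calving
records); ``fit`` simulates the requested null mating schemes and returns a
``MatingSystemResults`` carrying the observed statistics, the per-scheme
simulation envelopes and the one-tailed Z-test table, with ``summary()`` and
envelope plots.  ``MaleSpatialStructureModel`` does the same for the
relatedness-versus-rut-distance analysis of breeding males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import census as census_mod
from .inference import compare_all, format_p
from .pedigree import Pedigree, compute_kinship, matriline_table
from .schemes import ALL_SCHEMES, Scheme, get_scheme
from .simulate import SimulationEnsemble, build_eligibility, run_ensemble
from .spatial import SpatialModelResult, male_spatial_structure
from .stats import STAT_NAMES, StatBlock, stat_block


class MatingSystemModel:
    """Observed mating outcomes versus constrained random-mating nulls."""

    def __init__(
        self,
        pedigree: Pedigree,
        census: pd.DataFrame,
        calvings: pd.DataFrame,
        matrilines: pd.Series | None = None,
    ):
        self.pedigree = pedigree
        self.census = census_mod.normalise_census(census)
        self.calvings = census_mod.annotate_calvings(calvings)
        self.matrilines = (
            matrilines if matrilines is not None else matriline_table(pedigree)
        )

    @classmethod
    def from_csvs(cls, individuals, census, calvings) -> "MatingSystemModel":
        return cls(
            Pedigree.read_csv(individuals),
            census_mod.read_census(census),
            census_mod.read_calvings(calvings),
        )

    @classmethod
    def from_study(cls, study) -> "MatingSystemModel":
        return cls(study.pedigree, study.census, study.calvings, study.matrilines)

    def observed_stats(self) -> StatBlock:
        return stat_block(self.pedigree, self.calvings, self.census, self.matrilines)

    def fit(
        self,
        schemes=ALL_SCHEMES,
        n_replicates: int = 1000,
        seed: int = 0,
        statistics: tuple[str, ...] | None = None,
    ) -> "MatingSystemResults":
        """Simulate each scheme's ensemble and test the observed statistics.

        ``statistics`` restricts both the per-replicate computation and the
        test table (None = all ten).  Per-scheme master seeds are spawned
        deterministically from ``seed``.
        """
        observed = self.observed_stats()
        ensembles: dict[str, SimulationEnsemble] = {}
        for k, scheme in enumerate([get_scheme(s) for s in schemes]):
            sub = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0]
                % (2**31)
            )
            ensembles[scheme.name] = run_ensemble(
                self.pedigree,
                self.calvings,
                self.census,
                scheme,
                n_replicates=n_replicates,
                master_seed=sub,
                statistics=statistics,
                matrilines=self.matrilines,
            )
        comparisons = compare_all(observed, ensembles, statistics=statistics)
        return MatingSystemResults(
            model=self,
            observed=observed,
            ensembles=ensembles,
            comparisons=comparisons,
            n_replicates=n_replicates,
            seed=seed,
        )


@dataclass
class MatingSystemResults:
    model: MatingSystemModel
    observed: StatBlock
    ensembles: dict[str, SimulationEnsemble]
    comparisons: pd.DataFrame
    n_replicates: int
    seed: int

    def summary(self) -> str:
        """Text tables: observed value vs each scheme's envelope, Z, p."""
        lines = [
            "Nonrandom-mating analysis "
            f"({self.n_replicates} replicates per scheme, seed {self.seed})",
            "=" * 78,
        ]
        for stat in self.comparisons["statistic_name"].unique():
            sub = self.comparisons[self.comparisons["statistic_name"] == stat]
            obs = self.observed[stat]
            lines.append(f"\n{stat}  (observed = {obs:.5g}; "
                         f"one-tailed {sub['direction'].iat[0]}; "
                         f"Bonferroni alpha = {sub['alpha_bonferroni'].iat[0]:.3f})")
            lines.append(f"{'scheme':>14s} {'sim mean':>10s} {'sim SD':>9s} "
                         f"{'Z':>7s} {'P':>9s}  sig")
            for row in sub.itertuples(index=False):
                lines.append(
                    f"{row.scheme:>14s} {row.sim_mean:>10.5g} {row.sim_sd:>9.3g} "
                    f"{row.z:>7.1f} {format_p(row.p_one_tailed):>9s}  "
                    f"{'*' if row.significant else ''}"
                )
        return "\n".join(lines)

    def plot_envelope(self, statistic: str, ax=None):
        """Histogram of each scheme's null distribution with the observed value."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, ens in self.ensembles.items():
            ax.hist(ens.stats[statistic], bins=30, alpha=0.4, label=name)
        ax.axvline(self.observed[statistic], color="k", lw=2, label="observed")
        ax.set_xlabel(statistic)
        ax.set_ylabel("replicates")
        ax.legend(fontsize="small")
        return ax


class MaleSpatialStructureModel:
    """Relatedness of breeding males against the distance between their
    lifetime mean rutting locations, with a permutation test."""

    def __init__(self, pedigree: Pedigree, census: pd.DataFrame):
        self.pedigree = pedigree
        self.census = census_mod.normalise_census(census)

    @classmethod
    def from_csvs(cls, individuals, census) -> "MaleSpatialStructureModel":
        return cls(Pedigree.read_csv(individuals), census_mod.read_census(census))

    def fit(
        self,
        n_permutations: int = 999,
        seed: int = 0,
        alternative: str = "less",
    ) -> "SpatialStructureResults":
        result, pairs = male_spatial_structure(
            self.pedigree,
            self.census,
            n_permutations=n_permutations,
            seed=seed,
            alternative=alternative,
        )
        return SpatialStructureResults(model=self, result=result, pairs=pairs)


@dataclass
class SpatialStructureResults:
    model: MaleSpatialStructureModel
    result: SpatialModelResult
    pairs: pd.DataFrame

    @property
    def slope(self) -> float:
        return self.result.slope

    @property
    def p_permutation(self) -> float:
        return self.result.p_permutation

    def summary(self) -> str:
        r = self.result
        return "\n".join(
            [
                "Male spatial genetic structure (relatedness ~ rut-site distance)",
                "-" * 64,
                f"males: {r.n_males}   pairs: {r.n_pairs}",
                f"slope: {r.slope:.3e} relatedness per metre "
                f"(intercept {r.intercept:.4g})",
                f"permutation test ({r.n_permutations} permutations, "
                f"alternative={r.alternative!r}): p = {r.p_permutation:.4f}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.pairs["distance"], self.pairs["relatedness"], s=4, alpha=0.3)
        xs = np.linspace(0, self.pairs["distance"].max(), 50)
        ax.plot(xs, self.result.intercept + self.result.slope * xs, "r-")
        ax.set_xlabel("pairwise rut-site distance (m)")
        ax.set_ylabel("pairwise relatedness (2K)")
        return ax
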