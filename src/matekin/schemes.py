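"""The six null mating schemes.

Each scheme resamples a sire for every focal calf under progressively
stronger constraints: none (RANDOM), the dam's 11-day oestrus window
(TEMPORAL), additionally a 500 m or 100 m radius around the dam on the
conception day (SPATIAL_500, SPATIAL_100), and the 100 m scheme with draws
weighted by age-predicted (AGE_CORRECTED) or identity-predicted
(BS_CORRECTED) annual breeding success.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Scheme:
    name: str
    temporal: bool = False
    radius_m: float | None = None  # eligibility radius; None = no spatial constraint
    weighting: str = "uniform"  # uniform | age | lbs

    def __post_init__(self):
        if self.radius_m is not None and not self.temporal:
            raise ValueError("spatial constraint requires the temporal constraint")
        if self.weighting not in ("uniform", "age", "lbs"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


RANDOM = Scheme("RANDOM")
TEMPORAL = Scheme("TEMPORAL", temporal=True)
SPATIAL_500 = Scheme("SPATIAL_500", temporal=True, radius_m=500.0)
SPATIAL_100 = Scheme("SPATIAL_100", temporal=True, radius_m=100.0)
AGE_CORRECTED = Scheme("AGE_CORRECTED", temporal=True, radius_m=100.0, weighting="age")
BS_CORRECTED = Scheme("BS_CORRECTED", temporal=True, radius_m=100.0, weighting="lbs")

ALL_SCHEMES = (RANDOM, TEMPORAL, SPATIAL_500, SPATIAL_100, AGE_CORRECTED, BS_CORRECTED)
SCHEMES = {s.name: s for s in ALL_SCHEMES}
# CLI aliases
SCHEMES.update(
    random=RANDOM,
    temporal=TEMPORAL,
    spatial500=SPATIAL_500,
    spatial100=SPATIAL_100,
    age=AGE_CORRECTED,
    bs=BS_CORRECTED,
)


def get_scheme(name) -> Scheme:
    if isinstance(name, Scheme):
        return name
    try:
        return SCHEMES[str(name)]
    except KeyError:
        raise KeyError(f"unknown scheme {name!r}; one of {sorted(set(s.name for s in ALL_SCHEMES))}")
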