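# Methods

## Pedigree kinship and inbreeding

Kinship is computed by the tabular method: individuals are processed
parents-first (generation depth, ties broken by birth year then id, so the
order is deterministic), with

    K(i, i) = 0.5 (1 + K(father_i, mother_i))
    K(i, j) = 0.5 (K(father_i, j) + K(mother_i, j))

and an unknown parent contributing zero.  Founders — and, conservatively,
every individual with an unknown parent — are treated as unrelated and
non-inbred; this mirrors the convention of tracing matrilines back to the
females alive when a study began and understates true co-ancestry.
"Relatedness" throughout is the additive (numerator) relationship r = 2K:
under this convention an aunt–half-niece pair scores 0.125 and adding a
shared father makes 0.375, and Wright's f of an individual equals the
kinship of its parents (0 when either parent is unknown).  The test suite
pins the tabular engine against an independent Wright path-counting oracle
(sum over common ancestors A and non-overlapping path pairs of
(1/2)^(n1+n2+1)(1+f_A)) on hundreds of random pedigrees, to 1e-12.

Matrilines are traced mother-to-mother regardless of the focal individual's
sex; a male with an unknown mother has no matriline, and in the intralineage
statistic a mate without a matriline counts as her own singleton lineage
(collapsing unknowns into one lineage would manufacture intralineage
polygyny).

## Null mating schemes

The six schemes resample one sire per focal calf (calves with an assigned
sire; mothers fixed), with replacement, independently across calves and
replicates.  Eligibility tightens cumulatively: candidate males of the year
(≥ 1 harem-holding census record); holding a harem on ≥ 1 day of the dam's
11-day window (conception = birth − 235 d, ± 5 d; the split around the
conception date is symmetric since only the 11-day total is given);
additionally within 500 m / 100 m (inclusive, Euclidean on the 100 m grid)
of the dam's location on the conception day, taking her censused record
nearest in date within the window.  The two weighted schemes share the
100 m eligible set; weights act at sampling time.  Age weights come from an
OLS fit of annual breeding success (ABS) on age + age²; identity ("breeding
success") weights are each male's mean ABS.  Both are floored at
ε = 1e-6 so every eligible male stays drawable.

When a constrained scheme leaves a dam-year empty, the constraint is
widened for that dam-year only (100 m → 500 m → temporal → random, stopping
at the first non-empty set) and logged; dropping such calves would change
the denominators between schemes.

Replicate r of an ensemble uses `SeedSequence(entropy=master_seed,
spawn_key=(r,))`; sires are drawn by inverse-CDF with one uniform per calf
consumed in a fixed calf order, so a master seed reproduces an ensemble
bit for bit.  Ensembles of kinship-free statistics run through a vectorised
engine that is pinned, replicate by replicate, to the pedigree-rebuilding
path in the tests.

## Inference

Each statistic is compared to a scheme's ensemble with
z = (observed − mean)/sd (sample SD, n−1) and an exact one-tailed
standard-normal p — greater for the re-mating percentages, sibship,
relatedness and inbreeding statistics; less for the two diversity ratios.
Bonferroni families follow the hypothesis structure: the three re-mating
percentages form one family across the six schemes (18 tests, α = 0.003),
the three inbreeding statistics another (18 tests), and each remaining
statistic its own six-test family (α = 0.008).  p values are floored at
machine precision and rendered "< 0.0001" below 1e-4.

## Male spatial structure

Each male's lifetime rutting location is the arithmetic mean of his
harem-holding census records.  Pairwise records (r = 2K, Euclidean distance
in metres) are non-independent, so instead of a mixed model the slope of
relatedness on distance is estimated after removing additive per-male
effects from both matrices: the least-squares residual of
m_ij = μ + a_i + a_j over the off-diagonal of a complete symmetric matrix
has the closed form μ = T/(n(n−1)), a_i = (r_i − (n−1)μ)/(n−2) (the limit of
iterated row/column centering), and the slope is ⟨R̃, D̃⟩/⟨D̃, D̃⟩ over
unordered pairs.  Inference is purely permutational: whole location
assignments are shuffled among males (preserving the location multiset and
the relatedness matrix) and the slope recomputed; with the directional
alternative "less" (related males rut closer), p = (1 + #{slope_perm ≤
slope_obs})/(1 + n_perm).  The direction is specified by the caller, not
read off the observed sign — a sign-conditional tail would double the null
rejection rate, and the test suite verifies the chosen form is uniform
under shuffled locations (rejection at 0.05 in ~5% of 200 runs).
Cross-generational pairs are included.  All distances are
translation-invariant; a degenerate design (all distances equal) is an
error.

## The synthetic-study generator

The generator emulates the structure the analysis assumes, year by year:
philopatric females at matriline home ranges (founder matrilines at uniform
centroids, daughters dispersed ~100 m); males entering the rut pool at age
5 with a repeatable home rut site and median rut date, annual site
displacement (SD 100 m) and a contiguous harem tenure (~14 ± 4 d) generating
daily harem-holder census records; an October oestrus peak with
matriline-level (SD 3 d) and individual (SD 5 d) date effects so most
conceptions fall inside a two-week peak; exact 235-day gestation; and age-
peaked male success (quadratic, peak 8–10 y).  Each conception re-uses the
dam's previous sire with probability `fidelity_phi` (default 0.2, matching
roughly a fifth of females re-mating) when he is active that day; otherwise
a sire is drawn from the males holding harems that day with weight
(ABS(age) · exp(−d/60 m))^κ — κ (default 1) is the harem-monopolisation
dial, 0 giving uniform mating.  With probability `harem_attachment`
(default 0.5) the dam's censused conception-day location is placed inside
the chosen sire's harem rather than on her own range; this reproduces the
empirical motivation for the spatial schemes (~75–85% of sires within
500 m of the dam, ~50% within 100 m, at the defaults).  Sons' home rut
sites fall near their mothers' ranges with probability `natal_philopatry`
(default 0.5), which is what creates male spatial genetic structure.  A
truth log records each conception's eligible-set size, chosen sire,
fidelity flag and dam–sire distance.

What the generator does **not** emulate: observation error (every
conception date, parentage and census record is exact, whereas real studies
assign paternity with error and miss census days), immigration, landscape
heterogeneity, female oestrus repeatability beyond the matriline effect,
and harem-size dynamics.  Passing tests therefore demonstrate that the
pipeline detects the behaviours it targets when they are present and stays
calibrated when they are absent — not that any particular wild population
behaves this way.

Default scale is 36 years and 85 founder matrilines (~350–450 breeding
females over the study, a full six-scheme × 1000-replicate analysis in
minutes).  `GeneratorConfig.small()` (12 years, 18 matrilines) is the
reduced scale used for replicate-heavy experiments; at that scale a rare
seed (~1/1000) loses all rutting males in some year, which
`generate_study` reports as an error and `generate_viable_study`
deterministically sidesteps for seed-sweep experiments.

## Calibration and power experiments

The suite's statistical checks use fixed seeds and these problem sizes:

* **Null calibration** — 500 small-scale studies whose sires are drawn under
  the RANDOM scheme, each tested against its own 1000-replicate envelope;
  rejection at α = 0.05 must land in 5% ± 2 pp.  The statistic is mean
  full-sibship size, the least discrete of the sire-dependent statistics and
  hence the one for which the normal approximation behind the Z test is
  cleanest at this scale.
* **Power** — 50 small-scale studies with `fidelity_phi = 0.3` tested for
  excess pair re-mating against RANDOM (≥ 80% detection), and 50
  medium-scale studies with `natal_philopatry = 0.8` tested for a negative
  relatedness–distance slope (≥ 80% detection at permutation p < 0.05).
* **Scheme ordering** — one default-scale study, 300 replicates per scheme:
  ensemble-mean % pairs re-mating must be nondecreasing from RANDOM through
  TEMPORAL and SPATIAL_500 to SPATIAL_100.

## Known limitations

* Founder-unrelatedness makes every relatedness and inbreeding figure a
  lower bound.
* The eligibility fallback (widening per dam-year) slightly softens the
  spatial schemes exactly where data are thinnest; the alternative
  (dropping those calves) would bias denominators instead.
* The spatial slope is reported in relatedness per metre from a two-margin
  residual regression; it is not a variance-component estimate, and the
  permutation p, not the slope's magnitude, carries the inference.
* The Z test treats a 1000-replicate envelope's mean and SD as known;
  statistics with strongly discrete distributions (re-mating percentages in
  very small studies) are better judged by their envelope quantiles than by
  z.
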