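# matekin

Pedigree-based analysis of nonrandom mating in polygynous study populations:
re-mating across years (mate fidelity without a pair bond), intralineage
polygyny (male re-use by female relatives of one matriline), and their
consequences for pairwise relatedness, inbreeding and the spatial genetic
structure of breeding males.

It is written for long-term individual-based field studies of harem-breeding
ungulates — the motivating system is a multi-decade red deer (*Cervus
elaphus*) study with philopatric matrilineal females, an autumn rut censused
daily on a 100 m grid, calving records, and a genetic pedigree — but any
study that can supply individuals, rut census and calving tables in CSV form
can use it.

## The method

Whether observed mating outcomes are "nonrandom" depends entirely on the set
of mates actually available to each female.  The package therefore compares
the observed pedigree against ensembles of **simulated pedigrees** in which
every calf with an assigned sire is given a new sire drawn (with
replacement) from the males available to its dam in its conception year,
under six progressively constrained null schemes:

| scheme | constraint on the dam-year's eligible males |
|---|---|
| `RANDOM` | any male censused holding a harem that year |
| `TEMPORAL` | additionally holding a harem during her 11-day oestrus window |
| `SPATIAL_500` / `SPATIAL_100` | additionally within 500 m / 100 m of her location on the conception day |
| `AGE_CORRECTED` | the 100 m set, sampled ∝ quadratic age-predicted breeding success |
| `BS_CORRECTED` | the 100 m set, sampled ∝ each male's mean annual breeding success |

Oestrus windows come from backdating each birth by the 235-day gestation
(conception ± 5 days).  Mothers are never resampled.  For each pedigree —
observed or simulated — the same ten statistics are computed: the
percentages of pairs, females and males re-mating among those with a
multi-year opportunity; mean full-sibship size; the female mate-diversity
ratio (distinct sires / calves); the intralineage ratio (distinct matrilines
of a male's mates / distinct mates, < 1 meaning intralineage polygyny); mean
pairwise relatedness r = 2K; and mean, nonzero count and ≥ 0.125 count of
Wright's inbreeding coefficients.  Kinship K is computed recursively over
the pedigree (founders unrelated and non-inbred), f of an individual is the
kinship of its parents, and each observed statistic is tested against a
scheme's 1000-replicate envelope with a one-tailed Z test,
`z = (obs − mean) / sd`, at a Bonferroni-corrected level within each
hypothesis family.

A separate model asks whether **related males rut near one another**: each
male's lifetime mean harem-holding location is taken from the census,
per-male additive effects are removed from the pairwise relatedness and
distance matrices (the two-margin residual), and the slope of relatedness on
distance is tested by permuting the location assignment among males.

Because the motivating study's raw data are not public, the package includes
a first-class synthetic-study generator (`matekin.synthetic`) with tunable
mate fidelity `fidelity_phi`, harem monopolisation `kappa` and male natal
philopatry `natal_philopatry`, which the test suite uses for calibration and
power checks end to end.

## Worked example

```python
from matekin import (GeneratorConfig, generate_study,
                     MatingSystemModel, MaleSpatialStructureModel)

study = generate_study(GeneratorConfig.small(), seed=7)   # synthetic study
model = MatingSystemModel.from_study(study)
res = model.fit(schemes=("RANDOM", "TEMPORAL", "SPATIAL_500", "SPATIAL_100"),
                n_replicates=500, seed=1,
                statistics=("pct_pairs_remating", "mean_full_sibship"))
print(res.summary())
```

```
pct_pairs_remating  (observed = 28.947; one-tailed greater; Bonferroni alpha = 0.013)
        scheme   sim mean    sim SD       Z         P  sig
        RANDOM     13.447      4.95     3.1  0.000878  *
      TEMPORAL     15.864      5.27     2.5   0.00655  *
   SPATIAL_500     19.945      5.96     1.5    0.0656
   SPATIAL_100     26.758      5.55     0.4     0.347
```

28.9% of this study's pairs with a multi-year opportunity re-mated (its
generator re-uses a female's previous sire with probability 0.2).  Fully
random mating would have produced 13.4 ± 5.0%, so the excess is significant
(Z = 3.1); as the null gains the temporal and spatial structure of the rut
the envelopes climb toward the observed value and the excess stops being
distinguishable — exactly the diagnostic pattern the method is built to
reveal.  The male spatial model on the same study:

```python
print(MaleSpatialStructureModel(study.pedigree, study.census).fit(seed=1).summary())
```

```
males: 25   pairs: 300
slope: -9.810e-05 relatedness per metre (intercept 0.0811)
permutation test (999 permutations, alternative='less'): p = 0.0080
```

Related males rut measurably closer together than unrelated ones (the
generator places half of all sons' rut sites near their mothers' ranges).

A `matekin` command-line tool mirrors the library:
`matekin generate`, `matekin stats`, `matekin simulate`, `matekin compare`,
`matekin spatial`.

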