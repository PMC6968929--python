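# pyrclone

Quantitative clonal analysis of pyramidal-cell (PC) lineages in the
developing neocortex.

Lineage-tracing experiments (retroviral labelling, MADM, genetic
fate-mapping) yield tables of clones: for each labelled progenitor, the
number of neurons it contributed to cortical layers II/III, IV, V and VI.
`pyrclone` implements the statistical machinery needed to turn such tables
into statements about cortical neurogenesis:

* **Classification and filtering** — translaminar vs deep- or
  superficial-restricted clones, laminar configuration codes (the 15
  possible occupancy patterns), clone-size windows separating neurogenic
  lineages from symmetric-division products, MADM sub-clone division rules,
  and Ctip2/Satb2-based projection-subtype calls.
* **A permutation null** — neurons are shuffled among clones while keeping
  each neuron's laminar identity and each clone's size, isolating which
  statistics (e.g. the superficial-deep anti-correlation) reflect genuine
  lineage structure rather than population-level laminar densities.
* **Bayesian inference of progenitor types** — a Dirichlet-process mixture
  of binomial layer-occupancy profiles, sampled by Gibbs, that infers how
  many distinct progenitor behaviours the observed clones require.
* **A sequential stochastic simulator** — in-silico progenitors generate
  neurons inside-out (VI → V → IV → II/III) through layer-specific
  probabilistic "opportunities", with a per-opportunity chance of lineage
  interruption; one- and two-population models are fitted to experimental
  summaries by minimising normalized z-scores.

## The models

**Occupancy mixture.** Clone *i* is assigned a progenitor type
*t<sub>i</sub>* with frequency *f<sub>t</sub>*; its count in layer *j* is
*S<sub>ij</sub>* ~ Binomial(*N*<sub>max</sub>, *p<sub>t<sub>i</sub>j</sub>*)
with *N*<sub>max</sub> = 20.  A censoring mask σ<sub>ij</sub> removes each
clone's most superficial run of empty layers — zeros that may reflect an
externally interrupted lineage rather than its program — giving the joint
likelihood

P(t, S | p, f) = ∏<sub>t</sub> f<sub>t</sub><sup>n<sub>t</sub></sup> ·
∏<sub>ij</sub> [ p<sub>t<sub>i</sub>j</sub><sup>S<sub>ij</sub></sup>
(1 − p<sub>t<sub>i</sub>j</sub>)<sup>N<sub>max</sub> − S<sub>ij</sub></sup> ]<sup>σ<sub>ij</sub></sup>.

Beta priors on *p*, a Dirichlet-process prior over types, and an
auxiliary-component Gibbs sampler yield a posterior over the number of
types *K*.

**Sequential simulator.** For each layer *j* (inside-out order) a
progenitor draws a number of opportunities uniformly on
{1, …, *M<sub>j</sub>*}; at each opportunity the lineage is first
interrupted with probability *q* (terminal division / progenitor death,
ending the whole lineage), otherwise a neuron is added with probability
*P<sub>j</sub>*.  Model-data agreement is scored by
z = |mean(sim) − experimental| / std(sim) across simulation repeats
(by default 100 repeats of 100 progenitors, clone sizes filtered to 3–12).

## Worked example

```python
import numpy as np

from pyrclone import (
    DirichletProcessBinomialMixture,
    generate_lineage_dataset,
    neurogenic_filter,
    run_permutation_analysis,
    summarize,
    two_type_preset,
)
from pyrclone.dp_mixture import lineages_to_occupancy

# 1. synthesise an experiment-like dataset (two progenitor types)
dataset, truth = generate_lineage_dataset(two_type_preset(), seed=7)
clones = neurogenic_filter(dataset)          # keep 3-12 cell clones
stats = summarize(clones)
print(f"{len(clones)} neurogenic clones out of {len(dataset)} progenitors")
print("laminar fractions (II/III, IV, V, VI):",
      np.round(stats.laminar_fractions, 3))
print("class fractions (translaminar, deep, superficial):",
      np.round(stats.class_fractions, 3))
print("superficial-deep Spearman r:", round(stats.spearman_r, 3))

# 2. permutation null: what survives shuffling neurons among clones?
subset = clones[:200]
report = run_permutation_analysis(subset, n_repeats=1000, seed=7)
entry = report.table["spearman_r"]
print(f"observed r {entry['observed']:.3f} vs null {entry['mean']:.3f} "
      f"+/- {entry['std']:.3f} -> flagged: {entry['flag']}")

# 3. how many progenitor types explain the layer occupancies?
model = DirichletProcessBinomialMixture(
    n_draws=600, burn_in=200, random_state=7
).fit(lineages_to_occupancy(subset))
print("posterior over number of types:",
      {k: round(v, 3) for k, v in sorted(model.k_distribution_.items())})
print("modal number of progenitor types:", model.n_types_)
```

Output:

```
7581 neurogenic clones out of 10000 progenitors
laminar fractions (II/III, IV, V, VI): [0.295 0.257 0.218 0.23 ]
class fractions (translaminar, deep, superficial): [0.672 0.079 0.248]
superficial-deep Spearman r: -0.052
observed r -0.120 vs null -0.039 +/- 0.054 -> flagged: False
posterior over number of types: {2: 0.99, 3: 0.01}
modal number of progenitor types: 2
```

Reading the numbers: the synthetic experiment mixes a majority type making
larger translaminar clones with a minority type making small
superficial-biased clones.  About three-quarters of progenitors yield a
neurogenic-size clone (3–12 cells); clone classes split roughly
67% / 8% / 25%; the slight negative Spearman correlation reflects the
trade-off between superficial and deep output within clones.  On a
200-clone subsample, the permutation null retains a weak anti-correlation
of its own (superficial + deep counts must sum to each clone's size), and
the observed value is within 2 std of the null — detecting the slight
residual structure needs the full dataset.  The Dirichlet-process mixture
concentrates its posterior on two progenitor types, recovering the number
used to generate the data.

Every estimator follows scikit-learn conventions (`fit`, fitted attributes
with trailing underscores, `get_params`/`set_params`), and a `pyrclone`
command-line tool exposes the stages (`synth`, `classify`, `summarize`,
`permute`, `infer`, `simulate`, `fit`, `compare`, `run`) over the standard
CSV/TSV lineage-table schema (`lineage_id, method, area, age, l23, l4, l5,
l6` plus optional MADM sub-clone and subtype columns).

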