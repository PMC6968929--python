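# Methods

This note documents the models implemented in `pyrclone`, the assumptions
behind them, the parameters that matter, and the numerical and design
choices made where the underlying procedures left the design open.

## Data model

A *lineage* (clone) is the set of labelled pyramidal cells descended from
one tagged ventricular-zone progenitor, represented by neuron counts in
layers II/III, IV, V and VI.  Layer I is never represented (it houses no
pyramidal cells).  Internally all per-layer vectors use the *generation*
(inside-out) order VI, V, IV, II/III, because both the censoring rule of
the occupancy model and the sequential simulator operate in the order in
which layers are produced; external tables always use named columns, so
layer order is never positional at the I/O boundary.  Counts must be
explicit integers — a blank cell is an error, never an implicit zero,
because zeros drive the censoring mask.

Classification rules:

* **Laminar class** — translaminar iff both compartments (superficial =
  II/III + IV, deep = V + VI) hold at least one neuron; otherwise deep- or
  superficial-restricted.
* **Configuration code** — the presence/absence pattern over the four
  layers; 15 non-empty codes.
* **Neurogenic window** — by default clones of 3–12 cells.  Clones under
  three cells are ambiguous (labelling of a neuron or an intermediate
  progenitor rather than a self-renewing progenitor); clones above twelve
  cells overwhelmingly trace symmetrically dividing progenitors.  One- and
  two-cell clones are retained in datasets and excluded only where the
  window is applied, so analyses that treat them separately remain
  possible.
* **MADM divisions** — a clone with ≥ 3 cells in *each* reporter colour is
  a symmetric division (excluded from neurogenic analyses); clones of ≤ 2
  cells in total are excluded; the rest are asymmetric neurogenic
  divisions, and the two colours give the two sub-clones.
* **Projection subtypes** — per-cell categorical Ctip2/Satb2 calls map to
  CCPN/SCPN/HPN in layer V and CCPN/CThPN in layer VI (layer VI high/high
  cells are unclassifiable with this marker pair).  In layers II/III and IV
  only the canonical Ctip2^low/Satb2^high cortico-cortical signature is
  classified; other combinations return "unclassified" rather than a
  guess, and clones containing unclassified cells are excluded from
  subtype-diversity summaries.

## Permutation null

Null hypothesis: clone composition carries no information beyond the
population's laminar densities and the clone-size distribution.  All
neurons are pooled as layer labels, shuffled uniformly, and dealt back into
clones of the original sizes in the original order (any exchangeable refill
is equivalent; the sequential refill is documented for reproducibility).
Per construction every repeat preserves the size multiset and per-layer
totals exactly, and the test suite asserts this.  The default ensemble is
1000 repeats, reporting mean ± (sample) standard deviation per statistic
and flagging observed values outside mean ± 2 std (the 2-std flag is this
package's choice of a conventional threshold).

A subtlety worth knowing: because each permuted clone's superficial and
deep counts must sum to its fixed size, the null ensemble itself shows a
mild superficial-deep anti-correlation whenever clone sizes are mixed.  The
meaningful comparison is therefore observed vs null *gap*, not observed vs
zero.

## Dirichlet-process binomial mixture

Generative process: clone *i* draws a type *t_i* from frequencies *f*; its
count in layer *j* is Binomial(*N*max, *p*{t_i,j}) with *N*max = 20 (counts
above the cap are a validation error, never silently clamped).  The
likelihood omits the binomial coefficient exactly as written in the model's
defining formula; it is constant in (t, p, f, K) and leaves the posterior
unchanged.

**Censoring.** For each clone, scanning from the most superficial layer
toward deep, empty layers are censored (σ = 0) until the first occupied
layer is reached; interior zeros are kept.  The rationale: a terminal
superficial run of zeros may reflect an external interruption of the
lineage (premature terminal division, progenitor death) rather than the
layer-occupancy program, so those zeros are uninformative about *p*.
Deep-restricted-style configurations are handled by this mask, not by row
deletion; a fully empty row is fully masked (contributing only prior terms)
and triggers a warning.

**Priors and sampler.** Beta(1, 1) priors on every occupancy probability
and DP concentration α = 1 by default (both configurable) — uninformative
choices.  The sampler is an auxiliary-component Chinese-restaurant-process
Gibbs sampler with `n_aux` = 3 fresh prior-drawn candidate types per
assignment update (a vacated singleton's parameter is recycled as the first
auxiliary), followed by conjugate updates
p_{tj} ~ Beta(a + Σ σS, b + Σ σ(Nmax − S)) for each occupied type.  Type
frequencies are represented implicitly by the CRP weights; retained draws
record the occupied-type fractions n_t/N.  Defaults: 4000 retained draws
after 1000 burn-in sweeps, no thinning.  Initialisation is a single type
with prior-drawn probabilities.  All randomness flows from one
`random_state`.

Validation built into the test suite: exact agreement of the log-likelihood
with term-by-term evaluation; label exchangeability; conjugate posterior
means under a forced single type; recovery of the CRP closed form
E[K] = Σ α/(α+i) when the whole matrix is censored; and modal K = 2 plus
±0.05 recovery of *p* on two-type synthetic data (N = 200, well-separated
types, 20 seeded runs).  On that recovery design, note that the censoring
rule makes the most superficial layer's zeros always unobserved, so very
small occupancy probabilities there are recovered with a small upward bias
(≈ +0.03 at p = 0.05); this is inherent to fitting a censored likelihood
and stays within the ±0.05 recovery band.

**Posterior predictive.** Each simulated clone draws a retained posterior
sample, a type by its fractions, binomial counts per layer, and then passes
through the same 3–12 size filter used for experimental data (configurable,
including no filter), so predictive and experimental summaries are
comparable.

## Sequential stochastic simulator

Per progenitor and layer (inside-out): draw the number of opportunities
uniformly on {1, …, M_j} (once per progenitor, inclusive bounds); at each
opportunity, first test interruption with probability *q* — which
terminates the entire remaining lineage, matching the terminal-division /
cell-death interpretation — then generate a neuron with probability *P_j*.
One progenitor type = one (M, P, q) triple; a model is a mixture of one or
two types with population fractions.  Defaults: 100 progenitors per repeat,
100 repeats, sizes filtered to 3–12.  When fitting real data, the caps M
are taken as the maximum count observed for that layer in any single clone
across the pooled experiments (`opportunity_caps_from_data`); for synthetic
work they are explicit.

The package keeps two implementations of the same law: a literal
opportunity-by-opportunity scalar path and a vectorised batch path that
exploits the geometric distribution of the number of opportunities survived
before interruption.  The scalar path is the reference; the suite checks
the two agree in distribution.

**Fitting.** The objective is the sum of squared z-scores over the four
laminar fractions and the normalised clone-size bins (optionally the three
class fractions), with z = |mean(sim) − target| / std(sim) across repeats
(sample standard deviation).  The search is coordinate descent over the
generation probabilities, interruption probabilities and population
fractions (caps and the number of types are fixed by the template), with
candidate steps shrinking geometrically over passes (0.2, 0.1, 0.05 by
default) and every evaluation reusing one seeded random stream (common
random numbers), so the whole fit is deterministic given `random_state`.
Statistics with zero spread score 0 on exact agreement and infinity on
disagreement, which steers the search away from degenerate corners.
Fitted parameter values shipped anywhere in this repository are derived
artifacts of this procedure, with their fit reports, never external facts.

## Synthetic data

`generate_occupancy_dataset` draws directly from the binomial mixture (the
matched input for sampler-recovery tests); `generate_lineage_dataset` runs
the sequential simulator and records every progenitor's true type before
any size filtering, so the filter itself is testable.  Each lineage uses
its own random substream spawned from the master seed: enlarging a dataset
never perturbs earlier lineages.

The shipped `two_type` preset (values versioned in `presets.yaml`, chosen
by this package) mimics the experiment-like regime: 70% of progenitors with
caps (3, 3, 3, 4), generation probability 0.95 and q = 0.06 produce larger
translaminar clones (size mode near eight); 30% with caps (1, 1, 2, 3),
deep probabilities 0 and superficial probabilities 0.95 produce small
superficial-biased clones (mode near four).  The pooled size histogram is
bimodal with a dip near six, and interruption plus the mixture yield a
slight superficial-deep anti-correlation.

What the generators deliberately do *not* emulate: spatial organisation,
cell-cycle timing, the intermediate-progenitor vs direct-neurogenesis
distinction, area-dependent parameter variation, reporter silencing or
other labelling artifacts, and postnatal cell death.  Tests passing on
synthetic data therefore validate the statistical machinery under the
stated generative assumptions, not the biological completeness of those
assumptions.

## Problem sizes and numerical choices

The test-suite and acceptance-script runs use: 10⁵ draws for simulator
closed forms; 100 × 100 forced runs; 1000 permutation repeats; 10⁴
post-burn-in sweeps for CRP prior recovery (N = 10 clones), with
batch-means standard errors to absorb sweep-to-sweep autocorrelation;
600 retained draws after 200 burn-in for the two-type recovery runs
(N = 200 clones); and three coordinate-descent passes for fits.  These
sizes make every Monte-Carlo comparison pass at 3 standard errors with
comfortable margins while keeping a full run in minutes on one CPU.

Other numerical conventions: sample (n−1) standard deviations throughout;
Spearman correlations use average ranks for ties and raw counts by default
(a fractions variant is available, as both conventions appear in the
field); chi-square tests switch to Fisher's exact test for 2×2 tables or
when any expected cell is below five; near-zero spread (≤ 10⁻⁹ relative)
is treated as zero spread when computing z-scores, so exactly conserved
statistics accumulated in different floating-point orders score zero.

## Known limitations

* The DP sampler is a single-site Gibbs sampler; heavily overlapping types
  mix slowly, and no split-merge moves are implemented.
* The fitting loop is a local search; with two types the parameterisation
  is only weakly identified by laminar fractions and size bins (different
  (P, q, fraction) combinations reproduce the same summaries), so fitted
  parameters should be read as *a* sufficient configuration, not *the*
  generative truth.
* `compare_datasets` applies Fisher's exact test only to 2×2 tables; larger
  sparse tables fall back to chi-square with a caveat in the test name.
* The censoring rule biases upward the recovery of very small occupancy
  probabilities in the most superficial layer (see above).
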