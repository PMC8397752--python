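# Methods

## Model and assumptions

A service is a Boolean function over species presence/absence
configurations, factorised as `E = E* ∘ OR^N` through a bipartite
species-to-trait network (rows species, columns traits, fixed
orientation; the I/O layer transposes as needed).  The default
auxiliary function `E*` is AND over the `N` traits — the least
redundant choice — so the service is lost exactly when the first trait
loses its last provider.  The model is purely qualitative: species and
the service are present or absent, traits are binary capabilities,
there are no abundances, no intraspecific variation, and no
co-extinction dynamics (extinction orders are exogenous
permutations).

Robustness of one extinction sequence is `m/S` with `m` the 1-based
position of the removal that first makes the service evaluate to 0;
the causal removal is counted, so values live on `{1/S, …, 1}`.  For
AND the loss step is `min` over traits of the latest removal position
among that trait's providers, which vectorises over whole permutation
batches; arbitrary truth-table services are re-evaluated after every
removal and the *first* zero counts (such services need not be
monotone).

## Percentile convention

`R_c` is the lower empirical quantile: the smallest value `v` with at
least a fraction `c` of sequences at or below `v`.  This keeps `R_c`
on the discrete support and makes the exhaustive median of the
worked example exactly 0.8.  Exhaustive enumeration iterates all `S!`
permutations and is bounded at `S ≤ 9` by default.

## Analytic fragility

`f_c = log(1 − (1 − q^S) e^(−c/N)) / (S log q)` is evaluated with
`log1p`/`expm1` forms so small `p` and large `S` do not lose
precision.  Degenerate connectance is rejected by default; a
`boundary="limit"` flag returns the analytic limits (`f_c → 0` as
`p → 1`, `f_c → e^(−c/N)` as `p → 0`).  Natural logs are used in the
ratio (any base cancels); dispersion uses base 10, as is conventional
for the deviation-from-randomness scale.

## Dispersion and its correction

Variance of providers-per-trait uses the *population* convention
(divide by `N`): the null `S·p·q` is an exact binomial variance, and
mixing conventions would bias `d` at small `N`.  Zero or undefined
null variance (`p ∈ {0,1}`) yields a NaN sentinel, never a silent 0
or ∞.  The correction is `f*_c = f_c + λ_c f_c(1−f_c) log10(d)` with
`λ_c > 0`; the calibration regression
`(R_c − 1 + f_c)/(f_c(1−f_c)) = λ log10(d)` is fitted through the
origin (the model has no intercept term) and its slope is *negative* —
overdispersion lowers robustness.  `calibrate_lambda` returns the
signed slope; `corrected_fragility` consumes the magnitude, so both
conventions stay visible.  A simplified variant without the
`f(1−f)` factor is available behind a flag but is not the default.

## Species contributions

The connectance and variance updates under removal of species `i` are
first-order approximations; the exact-removal recomputation is the
reference path and both are stored.  The exact variance change equals
the prediction plus `(L_i/N)(1 − L_i/N)` — the dropped second-order
term — which is what the tests bound.  `S̄_{n_i}` (mean providers over
species `i`'s traits) *includes* species `i` in the counts, the
natural reading of "species that have the same traits".  When
dispersion is zero or undefined on either side of a removal (e.g. an
identity network), the correction is inapplicable and plain `f_c` is
used on both sides so deltas stay comparable; the record flags this.
Ranking is by decreasing fragility increase with deterministic
tie-break on species label.

## Synthetic generators

`random_bipartite` places each of the `S·N` links i.i.d. Bernoulli(p)
— the null the fragility formula assumes — optionally
rejection-sampled until no trait is empty (cap, then error).
`dispersion_controlled` draws trait degrees from a gamma distribution
with mean `S·p` and coefficient of variation equal to the
heterogeneity dial, rounded and clipped to `[1, S]`, links placed
uniformly within columns: heterogeneity 0 gives near-regular columns
(underdispersed), large values heavy tails (overdispersed).  These
emulate the *dispersion* axis of real networks only; they do not
reproduce nestedness, modularity or degree-degree correlations, so
passing tests demonstrate the dispersion mechanism, not full realism
of empirical webs.  Degree-sequence-exact null models are out of
scope.

The parameter sweep draws services with `S ∈ [10, 200]`,
`N ∈ [10, 100]`, `p ∈ (0, 0.5]` (125 draws × 600 sequences by
default, the full study design; a 5×20×10 grid mode exists).
Simulation conditions on networks with no empty trait — a service
with an unprovided trait is already lost — and redraws the parameter
triple when that is infeasible at tiny `p`.  Tests and examples use
reduced designs (20 services × 200–300 sequences; ensembles of a few
dozen networks at `S ≤ 100`), which are ample for the properties they
check since every comparison is between quantities computed under the
same design.

## The worked example

The documented 5×2 network has providers A={1,2,3}, B={3,4,5}
(species 3 the shared generalist).  This adjacency is locked by its
enumerated statistics: 120 orders, loss histogram 24/72/24 at
R = 0.6/0.8/1.0, median 0.8, and simultaneous loss of both traits
exactly when species 3 is removed last.

## Randomness and reproducibility

All randomness flows through `numpy.random.Generator`; every sampling
function takes a seed or generator and is reproducible bit-for-bit
under a fixed seed.  Monte-Carlo permutations are uniform
(generator-native per-row shuffles).

## Random E* experiment

When comparing AND against a random auxiliary function, truth tables
are drawn uniformly over all `2^(2^N)` functions and rejection-sampled
to be 1 on the full-community trait configuration and 0 on the empty
one, so robustness is defined along every extinction path; the
accepted fraction is roughly a quarter.  This conditioning is this
package's choice and is the minimal one that makes the comparison
well-posed.

## Known limitations

- Fragility assumes an Erdős–Rényi network; the dispersion correction
  absorbs the first moment of structure only.  Strongly modular or
  nested webs may deviate beyond what `log10(d)` captures.
- `f*_c` is not clamped to `[0, 1]`; extreme dispersion with
  mid-range `f_c` can push predictions outside the feasible range.
- Non-uniform (trait- or degree-biased) extinction scenarios are not
  modelled beyond user-supplied explicit sequences.
- Empirical validation against the public Web of Life database
  requires downloading those matrices; the package ships no data and
  performs no network access.
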