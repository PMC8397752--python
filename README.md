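# fragnet

Robustness of ecosystem-service supply to species loss, modelled on
bipartite species-to-trait networks.

## The problem

Ecosystem services — pollination, seed dispersal, pest control — depend
on species that carry the functional traits underpinning the service.
As species go extinct, a trait survives while at least one of its
provider species survives, and the service survives while every
required trait does.  `fragnet` is for ecologists and theoreticians who
want to quantify *how much species loss a service can tolerate*, which
network features control that tolerance, and which individual species
matter most.

## The model

A service over `S` species with `N` required traits is the Boolean
composition `E = AND ∘ OR^N`: trait `n` is present while any of its
`S_n` provider species is present (OR), and the service is supplied
while all `N` traits are (AND; arbitrary truth tables are also
supported).  For one extinction sequence — a permutation of the
species — robustness is `R = m/S`, the fraction of removals up to and
including the one that first loses the service.  Over all sequences
this gives a distribution `R(E)` on `{1/S, …, 1}` whose percentiles
`R_c` the package simulates, enumerates exactly (small `S`), and
predicts analytically: for a random network with connectance
`p = L/(S·N)` and `q = 1 − p`,

```
R_c = 1 − f_c,     f_c = log(1 − (1 − q^S) e^(−c/N)) / (S log q)
```

where `f_c` is the **network fragility**.  Non-random structure is
captured by the **dispersion** `d = V(S_n) / (S p q)` — observed over
binomial-null variance of providers-per-trait — and corrected as

```
f*_c = f_c + λ_c f_c (1 − f_c) log10(d),   λ_c > 0
```

with `λ_c` calibrated by regressing scaled residuals on `log10(d)`
through the origin.  Because fragility is a local statistic, the
effect of losing species `i` (with `L_i` links) is predictable in
closed form: `p → p − p(L_i/L − 1/S)` and
`V(S_n) → V(S_n) + 2 S̄_n (S̄_n − S̄_{n_i}) L_i / L`, which chains into
a per-species contribution ranking.

## Worked example

Five species share two traits (species 1–3 provide trait A, species
3–5 provide trait B); the service needs both traits.

```
$ python examples/worked_example.py
network: S = 5 species, N = 2 traits
 robustness  count
        0.6     24
        0.8     72
        1.0     24
median robustness R_0.5 = 0.8
```

Of the 120 extinction orders, 24 lose the service at the 3rd removal,
72 at the 4th and 24 only when the last species goes: in half of all
orders, losing 4/5 of the species or fewer suffices, so the median
robustness is 0.8.

The other example scripts show the scaling law
(`examples/fragility_scaling.py`: simulated median robustness tracks
`1 − f_0.5` with mean absolute deviation ≈ 0.03 over random services),
the dispersion correction (`examples/dispersion_correction.py`: fitted
slope ≈ −1.5 on a synthetic ensemble, Spearman ρ improving from −0.59
to −0.87), and species ranking (`examples/species_ranking.py`: a
generalist provider of uncommon traits tops the ranking).

## Command line

A thin CLI wraps the library:

```
fragnet fragility -S 50 -N 20 -p 0.2 --percentiles 0.1,0.5,0.9
fragnet simulate --input net.csv --reps 1000 --seed 1 --out run
fragnet contributions --input net.csv --mode exact --out ranking.csv
fragnet sweep --services 20 --scenarios 200 --seed 1 --out sweep.csv
fragnet validate --input-dir networks/ --reps 1000 --seed 1
```

Empirical matrices are labeled count CSVs (Web of Life export
dialect); counts are binarized on read and oriented so provider
species are rows (for pollination webs the pollinators are the
species and each plant a web-level trait).  The package performs no
downloads.

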