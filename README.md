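# tbplattice

Statistical-mechanical and kinetic modelling of TATA-binding protein (TBP)
recognition of promoter DNA, with the FRET observables used to measure it.

TBP nucleates assembly of the RNA polymerase II preinitiation complex by
binding the TATA box and bending the DNA by ~105°. On DNA longer than the
minimal TATA element, TBP also binds non-specifically — and cooperatively —
at every register along the duplex, competing with its own specific complex.
This package implements that competition as a branched, cooperative
one-dimensional lattice model and simulates all four experimental readouts
built on it:

* **bulk FRET titrations** — ensemble proximity ratio of a donor/acceptor
  labelled construct versus TBP concentration, including the biphasic
  (rise-then-fall) isotherms caused by cooperative non-specific coating;
* **competitor-chase kinetics** — two-phase dissociation after flooding the
  reaction with unlabelled DNA, and its biexponential analysis;
* **single-pair FRET (spFRET) bursts** — shot-noise-limited photon bursts
  of freely diffusing molecules, histogrammed as proximity ratios with a
  donor-only population and a Gaussian width analysis;
* **nucleosome site-exposure competition** — a TATA box buried at the
  entry–exit site of a positioned nucleosome, with salt, histone
  acetylation and TFIIA as accessibility modifiers.

A seeded synthetic-data catalog (`tbplattice.datasets`) regenerates every
input the analysis consumes, so parameter-recovery studies are fully
reproducible.

## The model

A construct of `ℓ` base pairs offers one binding register per bp. A
configuration is a set of bound registers with pairwise center separation
at least the footprint `n` (default 8 bp, the TATAWAWR length); its
statistical weight at free TBP concentration `c` is

```
w(config) = Π_i (c / Kd_i) · ω^(# pairs at separation exactly n)
```

with `Kd_i` the specific (TATA) or non-specific dissociation constant and
`ω` the nearest-neighbour cooperativity. With `ω = 1` on a homogeneous
lattice this is the classical McGhee–von Hippel hard-rod isotherm, which the
transfer recursion reproduces to <1%. Salt enters through a log-log law
`Kd(salt) = Kd_ref · (salt/50 mM)^z`, steeper for non-specific sites; TFIIA
boosts specific and suppresses non-specific affinity.

Observables: each bound register inserts a planar kink (105° specific, 45°
non-specific by default) into a polyline DNA model; the dye–dye distance
gives `E = 1/(1+(r/R0)^6)` with `R0 = 51 Å`, and a correction layer maps
efficiency to the measured proximity ratio (background, crosstalk, direct
excitation, γ).

Kinetics: a master equation over {unbound} ∪ {registers} with uniform
association `k_on[TBP]` (`k_on = 2×10⁶ M⁻¹s⁻¹`), class-specific
dissociation, and optional detailed-balance-consistent sliding. Fitting
follows the statsmodels pattern: `Model(...).fit()` returns a results
object with estimates, standard errors, AIC and `summary()`.

## Worked example

```python
import tbplattice as tl
from tbplattice import datasets, isotherm

# regenerate a noisy titration of the minimal TATA construct and fit it
df = datasets.generate_titration("fig1_tata14E_50mM", seed=3)
fit = isotherm.fit_single_site(df)
print(fit.summary())
```

```
Single-site binding fit (12 points)
param              value        stderr
p_min           0.302604      0.009943
p_max            0.70951       0.01025
kd_nM            5.85477        0.8254
RSS = 23.42, AIC = 14.02
```

The fitted `kd_nM` recovers the fixture's 5 nM dissociation constant within
its standard error; `p_min`/`p_max` are the unbound and saturated proximity
ratios (the amplitude reports the TBP-induced bend). Chase kinetics work the
same way:

```python
scheme = tl.KineticScheme(lattice=datasets.get_construct("tata14E"))
trace = tl.simulate_chase(scheme)           # 30 nM TBP, chase after 60 s
print(tl.fit_exponential(trace, phases=2).summary())
```

```
Exponential decay fit (2 phase(s), 1801 points)
param                value        stderr
offset            0.702369     2.353e-16
k_fast [1/s]          0.02     4.303e-16
a_fast           0.0444625     4.749e-16
k_slow [1/s]        0.0014     2.991e-17
a_slow           0.0374164     2.185e-16
RSS = 4.346e-27, AIC = -122812.09
fast fraction = 0.5430
```

The two recovered rates are exactly the configured non-specific
(0.02 s⁻¹) and specific (0.0014 s⁻¹) off-rates; the fast fraction is the
share of TBP still parked at non-specific registers when the chase starts,
and it shrinks with longer incubation as TBP funnels to the TATA box.

The same pipelines are available from the shell:

```bash
tbplattice fixtures list
tbplattice fixtures make fig4_1min --seed 1 --out chase.csv
tbplattice fit-chase chase.csv --phases 2 --out chase_fit.json
tbplattice nucleosome-predict --state hela --salt-mM 150 --out nuc.csv
# -> p_exposure=0.545 apparent_Kd=3.46 nM amplitude_fraction=0.545
```

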