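# Methods

This note documents the models implemented in `tbplattice`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the package's numerical conventions and limitations.

## Lattice equilibrium

**Model.** DNA of `ℓ` bp is a 1-D lattice with one candidate register per
base pair (the footprint center; the footprint may overhang the ends with
unchanged affinity — this convention makes a 14-bp construct offer exactly
14 candidate sites). One register may be the specific TATA site. Bound
proteins exclude each other within a center separation `n` (footprint,
default 8 bp = the TATAWAWR length); a pair at separation exactly `n` is a
contact and multiplies the configuration weight by the cooperativity `ω`.
The contact span `m` is stored on `LatticeSpec` for reporting only; no
quantitative role for it is defined by the data the model emulates.

**Computation.** Two independent routes: brute-force enumeration (≤30
registers; the oracle) and a forward/backward transfer recursion

```
a(i) = w_i · (z(i−n) + ω·a(i−n)),   z(i+1) = z(i) + a(i)
```

run in `numpy.longdouble` because weights span hundreds of decades on long
lattices (ℓ = 2000 at c/Kd = 10 reaches ~10^390). A count-resolved variant
of the same recursion yields the multi-occupancy distribution. The two
routes agree to ~1e-12; the ω = 1 homogeneous limit agrees with the
McGhee–von Hippel closed form to <1% at ℓ = 2000 (the residual difference
is the finite-lattice edge effect).

**Defaults.** `Kd_specific = 2 nM` at the 50 mM KCl reference (the
consensus-TATA affinity scale), `Kd_nonspecific = 30 nM`, `ω = 20`,
salt exponents `z_spec = 0.5`, `z_ns = 2.5` (log-log Record-style law;
the steeper non-specific exponent means non-specific binding is
essentially abolished at 150 mM while specific binding weakens mildly).
TFIIA divides the specific Kd by 10 and multiplies the non-specific Kd by
10. The non-specific affinity, cooperativity and salt exponents are
calibration constants, not measured values: they were fixed once so that
the flanked 25-bp construct shows the documented low-salt phenotype — a
hyperbolic rise followed by a fall of ≥10% below its peak inside a
0.1–300 nM titration — while the same construct at 150 mM KCl and the
TFIIA and equimolar-competitor scenarios are monophasic. With the
spec-suggested ω = 5 the drop on this geometry is only ~5% and would not
stand out of realistic noise.

**Mass balance.** Free-vs-total TBP corrections (labelled-DNA depletion,
competitor co-titration) solve `free + Σ DNA_j·⟨n_bound⟩_j(free) = total`.
The excess function is strictly increasing, so the root is found by
bracketed bisection on [0, total] to 1e-9 nM; a damped fixed point is
unstable here because `d⟨bound⟩/d(free)` exceeds 1 by orders of magnitude
on cooperative lattices.

**Model facts worth knowing.** (i) Per-register occupancy is *not*
monotone in free ligand: exclusion competition and packing commensuration
make individual registers fill and empty as concentration rises (only the
mean occupancy, a variance, is monotone). (ii) An equimolar competitor
lowers free TBP and mean occupancy but *raises* specific-register
occupancy on the cooperative lattice — the competitor-rescue effect: it
soaks up the excess TBP that would otherwise coat the flank and displace
the TATA complex. (iii) At saturation the cooperative lattice collapses
onto its unique maximal packing, so ensemble heterogeneity peaks at
intermediate concentration and re-homogenises at the very top — see the
spFRET section.

## FRET observables

The duplex is a planar polyline of 3.4 Å bp steps. Every bound register
whose center lies strictly between the dye anchors turns the direction by
its bend angle, coplanar and same-sense (multi-kink geometry is otherwise
underdetermined). Kinks outside the dye span leave the distance unchanged.
An optional dye/linker offset is added in quadrature (default 0 Å).

Bend angles: 105° for the specific complex (human TBP). The non-specific
default is 45°, a partial "loose" bend. This is a deliberate design
choice: whether non-specifically bound TBP bends DNA like the TATA complex
is not established, and a fully bent (105°) non-specific complex is
actually inconsistent with the biphasic bulk observable this model must
produce — dense packings then always carry a kink inside the dye span and
the ensemble proximity ratio can only rise with coating, never fall. A
smaller non-specific bend lets flank-bound proteins displace the bent TATA
complex without replacing its FRET signal, which is what the falling
branch of the biphasic isotherm is.

Efficiency is the Förster law with `R0 = 51 Å`. The proximity ratio layer
synthesises donor/acceptor signals with γ, donor→acceptor crosstalk,
acceptor direct excitation and channel backgrounds; the corrected ratio
inverts those terms and equals E exactly when γ = 1. The printed
correction equations for the original plate-reader pipeline are not
available, so this layer is standard correction algebra constrained by
that identity (documented stand-in). Single-molecule ratios are left
γ-uncorrected by convention.

## Kinetics and the competitor chase

State space: {unbound} ∪ {bound at register i} (single occupancy — the
chase construct is the minimal fragment). Uniform association
`k_on·[TBP]` with `k_on = 2×10⁶ M⁻¹s⁻¹` to every register; dissociation
0.0014 s⁻¹ (specific) and 0.02 s⁻¹ (non-specific) by default. Sliding at
`k_slide` hops between bp-adjacent registers with rates biased as
`k_slide·sqrt(k_off_i/k_off_j)`: plain symmetric hopping would violate
detailed balance against the heterogeneous well depths and drain the
specific register; the biased rates leave the equilibrium distribution
unchanged while adding a dissociation-free route into the stable site
(relaxation to the TATA register accelerates, as a sliding mechanism
should).

Propagation is by matrix exponential (one `expm` per uniform time bin,
default 1 s). The chase is modelled as instantaneous, irreversible removal
of re-association to the labelled DNA (a 2 μM competitor against 1 nM
probe is a ~2000-fold sink). With `k_slide = 0` the post-chase trace is an
exact biexponential whose rates are the two off-rates — this analytic
eigenstructure is used as a test oracle.

Decay fitting (`ExponentialDecayModel`) is nonlinear least squares with a
deterministic, documented initialisation: rate guesses `3·10^j / span`
(a log-spaced decade split of the observation window), amplitudes an even
split of the endpoint difference, offset the final value; amplitudes and
rates are bounded below by 0 and phases are reported fast-first. The
fast-phase mole fraction is `a_fast/(a_fast+a_slow)`.

A note on the branched scheme's own amplitudes: at these defaults the
scheme is still close to its initial (register-uniform) distribution 60 s
after mixing, so the mechanistic 1-min fast fraction (~54%) is larger than
the 38% the parametric fixture encodes; the 20-min value (~16%) matches
the 15% class. The fixtures therefore carry the fractions as explicit
amplitude parameters, while the mechanistic simulation is the source of
the rates and of the qualitative incubation dependence (fractions fall
with incubation, rates do not move).

## spFRET burst pipeline

Per burst: a species is drawn from the mixture (including a donor-only
fraction, default 0.2 in fixtures), a total photon count from a lognormal
(mean 60, σ_log = 0.5 — burst-size statistics are a calibration choice),
and the acceptor count from a binomial whose success probability is the
apparent (γ/crosstalk/direct-excitation-distorted) acceptor fraction of
that species; Poisson backgrounds are optional. Per-burst ratios use the
γ-uncorrected convention. Burst selection is a total-photon threshold
(default 30 in analyses) standing in for the original multi-parameter
burst search. Histograms use 40 bins on [−0.1, 1.1]; the single-Gaussian
width fit excludes bins below the donor-only bound (default P = 0.05).
The exact shot-noise oracle used in tests is
`Var(A/N) = P(1−P)·E[1/N]` (note `E[1/N] ≠ 1/E[N]` for lognormal sizes).

Two diagnostic signatures: a two-state system's width rises to a maximum
at ~50% bound and falls back to the shot-noise width at saturation; a
cooperative many-state system stays broad past half-saturation. Because
the finite lattice re-homogenises at its maximal packing (see above), the
cooperative demonstration runs in the 0.3–20 nM window (the flanked
construct is >90% bound from ~5 nM); the measured system stays broad to
higher concentrations than the model, which is a known limitation of the
hard-footprint lattice.

## Nucleosome site exposure

A TATA box ~5 bp inside the last histone–DNA contacts of a 147-bp wrap on
a 159-bp construct is bindable only while the entry–exit site is
transiently unwrapped: `p_exp = K_unwrap/(1+K_unwrap)`. Two competition
regimes are encoded as modes rather than asserted mechanisms: TBP alone is
*slow exchange* (a fraction `p_exp` titrates with the naked-DNA Kd at full
amplitude; apparent Kd unshifted, amplitude suppressed to `p_exp`);
TBP+TFIIA is *fast exchange* (single population, `Kd_app = Kd_naked/p_exp`,
full amplitude — a conventional competitive shift). An optional
off-consensus residual models TBP on the 12-bp free linker of blocked
nucleosomes through the lattice module; it is off by default because it
contaminates the single-site description's apparent Kd.

`K_unwrap(salt, histone_state)` is a lookup table with log-log salt
interpolation. The shipped defaults are synthetic calibration values
reproducing the qualitative pattern only: near-full access at 5–50 mM KCl
for every histone state; strong occlusion of unmodified recombinant
octamers at 150 mM; partial relief by H3/H4/bulk acetylation (all three
approximately equal); strongest relief for native HeLa octamers with
hyperacetylation adding a little more. They are not measured unwrapping
constants.

## Isotherm fitting

`SingleSiteBindingModel` fits `P = P_min + (P_max−P_min)·[T]/([T]+K_D)`
in total TBP (probe DNA ≪ K_D, so free ≈ total; a depletion-corrected
mode exists through the lattice module's mass balance). Initialisation is
deterministic — `P_min` from the first point, `P_max` from the last, `K_D`
from the concentration nearest half-amplitude — which also makes the fit
exactly scale-equivariant in concentration. Weighted residuals are used
when a `sigma` column is present.

`detect_biphasic` compares that fit against a rise-minus-Hill-decline
composite and calls a curve biphasic when ΔAIC > 10 *and* the decline
amplitude exceeds 3× the residual noise; it requires ≥8 points spanning
≥2 decades. The composite form and the decision rule are diagnostics of
this package, not a mechanistic model. AIC uses a residual floor
equivalent to 1e-8 per-point noise so exactly noiseless data cannot win
through log(RSS→0); the decline amplitude is bounded by 1.5× the data
range so monotone data cannot report a spurious large decline.

## Synthetic-data catalog

`data/fixtures.yaml` defines every fixture as generator kind + parameters
+ per-parameter provenance (`paper` = a printed experimental value the
fixture emulates, `calibration` = a package choice). Defaults that are
calibration: Gaussian noise σ_P = 0.01 on titrations and chase traces,
12-point log grid 0.1–300 nM, 1 Hz × 1800 s chase sampling, burst counts
and sizes, amplitude/offset scales. The chase fixtures use
`k_slow = 0.0014 s⁻¹` for both incubation times although the 20-min fit
report prints 0.007 s⁻¹ — the two rates are described as virtually
identical and the discrepancy is flagged in the fixture notes rather than
resolved. The minimal 14-mer's burst fixtures use a single-active-register
scenario (`tata14E_minimal`): the minimal construct behaves as one strong
site in the single-molecule data, whereas the full 14-register lattice at
the calibrated cooperative energetics would deviate at elevated TBP.

What the generator does **not** emulate: plate images or photon
arrival-time streams, dye photophysics beyond the correction fractions
(no κ², no blinking/bleaching), sequence-dependent non-specific affinity,
nucleosome-internal FRET architecture, or temperature dependence. Passing
recovery tests therefore demonstrate that the analysis pipeline is
self-consistent at realistic noise, not that real data are free of these
effects.

## Conventions

Concentrations in nM, time in s, distances in Å, angles in degrees,
0-based bp indices. CSV is comma-separated, '.' decimal, UTF-8, header
mandatory, column order free. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; JSON reports carry units in the
field names. Problem sizes used by the shipped analyses (200 fit
replicates, 1801-point traces, thousands of bursts, ℓ ≤ 2000 lattices)
run in seconds on one CPU.
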