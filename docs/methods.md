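# Methods

## Two-state unfolding model (nanodsf)

The model treats each thermal transition as an equilibrium between a folded
and an unfolded state with temperature-independent ΔH (cal/mol) and ΔS
(cal/(K·mol)); the unfolded fraction is the logistic

    fU(T) = exp(−ΔH/RT + ΔS/R) / (1 + exp(−ΔH/RT + ΔS/R)),   R = 1.987 cal/(K·mol)

and the observable interpolates between linear baselines,
`E(T) = EF + (EU − EF)·fU`. Melting and onset temperatures are closed forms:
`Tm = ΔH/ΔS` and `Tonset = ΔH/(ΔS + R·ln((1−f)/f))` at f = 0.05, so
`fU(Tm) = 0.5` and `fU(Tonset) = f` hold to numerical precision on every fit
by construction. Temperatures cross the interface in °C and are converted to
K (offset 273.15) for all thermodynamic evaluation. The equilibrium
assumption means no scan-rate dependence and no unfolding kinetics; curves
from aggregating or kinetically controlled samples will fit but the
parameters lose their thermodynamic meaning.

Sequential transitions in a capsid thermogram are fitted window by window:

- first (minor) transition, default window 45–70 °C, with the shared-slope
  constraint a = c (the VP1/VP2 N-termini unfolding barely changes the
  baseline slope);
- second (major, capsid-disassembly) transition, default window 65–85 °C,
  with its folded baseline (a, b) frozen to the first fit's unfolded
  baseline (c, d); samples without a first transition are fitted with free
  baselines.

The windows are user parameters; the defaults bracket onset temperatures of
roughly 55 °C and 71–72 °C for the two transitions. Fits are
Levenberg–Marquardt least squares (lmfit) parametrized by (ΔH, Tm) rather
than (ΔH, ΔS) — better conditioned because Tm is pinned inside the window —
with xtol = ftol = 1e−10. Initialization: Tm at the steepest point of the
curve after smoothing with a ~1 °C boxcar (with point noise of ~1e−3 the raw
derivative of a shallow transition is noise-dominated, and a bad Tm seed is
the main failure mode); ΔH at 1×10⁵ cal/mol (3×10⁵ for the second window);
baselines from linear fits to the outer 20% of the window. A fit is rejected
(FitError) when the fitted amplitude is below 5× the residual RMS or the
fitted Tm sits within 0.5 °C of a window edge — both indicate there is no
transition in the window, the expected outcome for empty or VP3-only
particles in the first window.

Per-gram normalization divides ΔH and ΔS by a candidate domain mass; the
globular classification uses the calorimetric ranges 5.7–8.7 cal/g and
1.7–2.7 × 10⁻² cal/(K·g) at ~62 °C (configurable bounds). The comparison is
a screening heuristic, not a proof of domain assignment.

## Thermogram generator

The generator composes transitions additively on a single global linear
baseline, `E(T) = qT + p + Δ₁·fU₁ + Δ₂·fU₂`, with i.i.d. Gaussian noise on
the signal. Under this model each windowed fit is exactly specified: the
first transition's true parameters satisfy a = c, and the second window's
folded baseline is the first's unfolded baseline, so windowed refitting is
an unbiased round trip up to window-leakage effects. Defaults emulate a
full-particle curve: baseline (0.002 /°C, 0.75), amplitudes 0.03 (minor) and
0.25 (major), noise SD 1e−3 signal units — the instrument noise magnitude is
not a published quantity, so it is an explicit, documented parameter chosen
to give a realistic ~30:1 amplitude-to-noise ratio for the minor transition.
Transitions closer than 2 °C are rejected as unfittable by a windowed
scheme. Not emulated: temperature-correlated drift, scan-rate effects,
aggregation-induced baseline curvature; recovery tests therefore validate
the estimator, not instrument artifacts.

## Mass-photometry decomposition (mp)

Landing events are binned into half-open [lo, hi) bins — default 50 kDa over
2–7 MDa — and the histogram is fitted with a sum of Gaussians by bounded
least squares, one component per expected population (EP/FP/OP), which
mirrors how such histograms are analysed in practice; event-level maximum
likelihood would be statistically tidier but fits a different method than
the one being reproduced. Component means are bounded to ±20% of their
initial guesses so neighbouring populations keep their identity; areas are
analytic Gaussian integrals in event counts. Components whose fitted means
end up within one SD of each other are unresolvable and are merged with a
warning. Unbinding (negative-mass) events are excluded from species
quantification; events at exactly 0 Da count as binding (arbitrary, fixed).

The EP ratio is EP/(EP+FP+OP) by fitted area. The default significance
threshold 0.148 is the noise-derived constant (noise fraction mean + 3 SD in
a control full-particle sample); `noise_threshold(0.077, 0.023)` recomputes
0.146 from the rounded summary statistics — the printed 14.8% presumably
used unrounded inputs, and the package keeps the printed constant as the
default. Antibody binding is declared when the FP mean shifts by more than
3× the pooled standard error of the two fitted means (configurable).

The event generator draws from the same mixture with a Bernoulli unbinding
sign; the mass-photometry noise population near zero can be included as an
explicit low-mass component. Contrast physics, spot detection and binding
kinetics are not modelled.

## Hydrodynamics (hydro)

All relations are algebraic consequences of the Svedberg equation
`s = M(1 − v̄ρ)/(N_A·f)` in CGS units (s expressed in svedbergs, 1 S =
1e−13 s). The frictional ratio uses the anhydrous equivalent sphere,
`f0 = 6πη·(3Mv̄/4πN_A)^{1/3}` — no hydration shell, the standard convention
for reporting f/f0. Defaults: PBS at 20 °C (ρ = 1.005 g/mL, η = 1.002 cP),
v̄ = 0.730 mL/g for protein and 0.550 mL/g for ssDNA, combined as the
mass-weighted mean for DNA-containing particles (0.698 mL/g for a 3.73 MDa
capsid with a 0.8 MDa genome). With these defaults the 4.55 MDa / 91.3 S
control particle gives f/f0 = 1.21; the heated-sample peaks (54.6 S and
84.7 S at 4.45 MDa) give ≈1.99 and ≈1.29, within 5% of the reported 2.07
and 1.33 — the residual spread reflects that the exact v̄, ρ, η behind those
published values are unstated, so the package treats them as approximate
shape indicators, not exact targets. Ratios below 1 raise instead of being
returned. Expected-s under mass change scales s by M_new/M_ref, i.e. assumes
f and the buoyancy factor are unchanged — valid for small mass losses such
as shedding a VP subunit, not for shape changes.

Peak classification is nearest-neighbour on A260/A230 against reference
ratios (defaults: EP 0.10, FP 0.47; ties break toward the lower, more
protein-like reference). c(s) fitting itself is upstream of this package.

## Mass model and cargo enumeration (massmodel)

Particle mass is the 60-mer stoichiometric sum plus genome bases × per-base
mass. VP monomer masses are serotype-specific inputs (the tests use AAV8-like
values of 81.6/66.6/59.8 kDa, which give 3.73 MDa for a 5:5:50 empty capsid).
The per-base ssDNA mass defaults to 330 Da/nt and is deliberately exposed:
published figures for the same constructs imply 317–339 Da/nt depending on
rounding.

Cargo enumeration is an exhaustive search over non-negative integer count
vectors of the candidate species, keeping those whose total mass lies within
the tolerance of the target, whose base total respects the packaging
capacity (default 5.2 knt: wild-type ~4.7 knt plus margin), and whose
molecule count is at most `max_molecules` (default 5). The molecule cap is
the package's resolution choice: compositions of many short fragments grade
into a continuum that a single mass measurement cannot distinguish, so by
default the enumeration reports the few-molecule explanations (for a 1.6 MDa
cargo over {1.6, 0.8, 0.2} MDa candidates at ±0.05 MDa: one oversized
genome, two full genomes, or one genome plus four fragments). Raising the
cap adds the fragments-only fill (8 × 0.2 MDa), which is the physically
dominant packing mode for fragment-rich preparations; the default keeps the
output interpretable rather than exhaustive. Results are sorted by absolute
residual, then fewest molecules.

## HDX differential uptake (hdx)

Per peptide — identified by (start, end, modification) on 1-based VP1
coordinates, so acetylated duplicates stay distinct — the per-time
difference of replicate means (treated − control) is summed over the
labeling series (default 15–3600 s) to the accumulated difference; the
pooled SD is the root-sum-of-squares over times of the per-time variance of
the difference of means. Significance is a strict `>` comparison of the
accumulated difference against a global threshold, default 3.281 Da. The
statistical construction behind that constant (α, number of comparisons) is
not derivable from available information, so the package treats it as a
configurable constant rather than guessing a derivation; a recomputation
mode (k × pooled SE) can be built on the reported pooled SDs but is not the
default. Back-exchange correction and spectral processing are out of scope.

The generator uses single-exponential uptake curves `plateau·(1 − e^{−kt})`
per state — adequate for testing the accumulation/flagging arithmetic, but
not a model of multi-amide exchange kinetics (real uptake curves are sums of
exponentials with EX1/EX2 regimes).

## Pipeline

`run_pipeline` executes simulate → fit-dsf → mp-fit → hydro → mass → hdx
from a single YAML config; every output table carries the package version
and seed in a header comment, and identical config + seed reproduces
byte-identical outputs. Stage failures write a FAILED marker and preserve
earlier outputs.

## Problem sizes and numerics

Recovery checks use 20 independent seeds with 701-point thermograms
(30–100 °C at 0.1 °C) and 5,000-event mass-photometry streams — sizes chosen
to put Monte-Carlo error well below the tolerances being asserted (binomial
SE of an unbinding fraction at n = 5000 is ~0.7%; the SD of a recovered Tm
at noise 1e−3 is ~0.05 °C). All randomness flows through
`numpy.random.default_rng` seeded explicitly; the acceptance script derives
per-run seeds from its `--seed` argument via `SeedSequence`.

Known limitations: windowed sequential fitting leaks a small bias into the
first-transition parameters when the second transition's onset intrudes into
the first window (~0.06 °C on Tm₁ under the default geometry — well inside
the stated tolerances but not zero); the histogram-based mixture fit
underweights populations smaller than a few bins; and all recovery results
certify estimator correctness under the generators' assumptions, not
robustness to instrument artifacts absent from those generators.
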