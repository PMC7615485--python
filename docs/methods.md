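# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic generators do and do not emulate.

## Copolymer formulation

Copolymers are symmetric ABA triblocks named by block degrees of
polymerization ("6-65-6"). The hydrophilic weight fraction is

f = 100 · (2·DP_A·m_MOXA + m_end) / (2·DP_A·m_MOXA + DP_B·m_DMS + m_end)

with repeat-unit masses m_MOXA = 85.10 g/mol and m_DMS = 74.15 g/mol and
end-group mass zero by default. This reproduces the published 43 % for
21-65-21 exactly. Tabulated fractions for very short chains (e.g. a
1-7-1 at 37 %) are *not* reproduced by any end-group-free repeat-mass
formula — end groups contribute a non-negligible share of the molar mass
at those lengths — so the end-group mass is an explicit parameter rather
than a guessed constant, and no short-chain value is asserted. Blends are
molar mixtures; the mean PMOXA DP per arm, Σ xᵢ·DP_A,i, summarises the
average brush length of a blended membrane. The vesicle-forming window
f ≈ 35 ± 10 % is reported as an annotation only, never enforced.

## FCS model and fitting

The correlation model is the standard single-focus confocal form: 3D
Gaussian detection volume (lateral 1/e² radius w_xy, structure parameter
S = w_z/w_xy), one or two freely diffusing species, optional triplet
factor. S is a calibration constant (default 5) and is never fitted.
Defaults w_xy = 0.25 µm, T = 298.15 K, η = 8.9·10⁻⁴ Pa·s are ordinary
room-temperature aqueous values; all are configurable.

The fouling fit holds both diffusion times fixed and varies N and a
single f_slow ∈ [0, 1] (so the fractions sum to 1 by construction),
optionally the triplet pair, and optionally an additive baseline G_∞.
Optimisation is bounded trust-region least squares (lmfit/`least_squares`),
weighted by 1/σ_G when per-point uncertainties exist. Non-convergence is
flagged, not raised.

**F2 is the fitted slow amplitude fraction × 100, with no brightness²
de-weighting.** Amplitude fractions weight each species by N·B², so F2
overstates the *number* fraction of bound label whenever the bound state
is brighter — which is precisely what makes the assay sensitive. F2 is
an operational fouling readout, not a binding stoichiometry.

CPP = mean count rate / fitted N uses the total N of the analysed curve.
Aggregation takes the median over technical repeats within an experiment,
then mean ± s.e.m. across experiments. Repeats whose F2 exceeds a
threshold (default 50 %, configurable; optionally a CPP cut) are excluded
as aggregate-dominated before aggregation; the count of exclusions is
reported alongside.

Calibration fits (one component, free τ_D, baseline enabled by default)
convert τ_D = w_xy²/4D to hydrodynamic diameter via Stokes–Einstein,
d = k_BT/(3πηD), reporting mean ± sd over curves.

## Brownian-dynamics FCS simulator

Point emitters take Gaussian steps of per-axis variance 2DΔt in a
periodic box; positions at the sampling times are exact increments of the
continuous process, so there is no time-discretisation error in the
correlation. The instantaneous rate is B·exp(−2(x²+y²)/w_xy² − 2z²/w_z²)
summed over particles, plus background. Expected-value photon sampling
(the default) records the rate integral per bin — fitting consumes
correlation curves, not photons, so shot noise is opt-in via Poisson
sampling. The box must be ≥ 8 w_xy laterally and ≥ 4 w_z axially.

Finite closed boxes have two knowable artefacts, both scaling with
p = V_eff/V_box: the fixed particle number suppresses the zero-lag
amplitude by (1 − p)-ish, and the discrete diffusion-mode spectrum makes
the measured curve sit below the infinite-volume model by roughly p/N_eff
until box mixing. For fraction fits (both τ_D fixed) the effect largely
cancels between components; for free-τ_D calibration the baseline
parameter absorbs most of it and the calibration conditions use a larger
box (4 × 4 × 6 µm, p ≈ 0.005), which brings the recovered τ_D within a
few percent. The default mixture conditions — free protein D = 4·10⁻¹⁰
m²/s at 10 kHz (d ≈ 1.2 nm) versus 100-nm particles at D = 4.4·10⁻¹²
m²/s and 50 kHz, τ_D ratio ≈ 91, in a 2 × 2 × 5 µm box at Δt = 4 µs —
mirror the assay's fast-dim/slow-bright contrast. The inner loop is a
numba kernel with the RNG inside (one derived stream per species);
traces are bit-reproducible per seed.

Correlators: `autocorrelate_direct` is the literal O(N·L) estimator with
symmetric normalisation (segment means of the overlapping parts only).
`autocorrelate_multitau` evaluates the *same* estimator — FFT cross-sums
plus cumulative-sum means — on a quasi-logarithmic multi-tau grid (m
linear lags, then spacing doubling per stage), so the two agree to
round-off at shared lags while covering decades of lag in O(N log N).
This deliberately avoids the classic coarsen-and-rebin multi-tau, whose
triangular lag-smearing would bias the shared-lag comparison; with
megasample traces the variance advantage of rebinned estimators is not
needed.

## Membrane slab generator

Pseudo-atoms realise a parametric cross-section: a uniform PDMS core of
half-width c (default 2 nm at 965 kg/m³), PMOXA brush layers with a
plateau (default 300 kg/m³) over the brush extent plus an exponential
(or linear) tail, and water at 997 kg/m³ filling the rest. One bead per
heavy atom (m_DMS/4, m_MOXA/6, one molecule per water) keeps number
densities high enough for smooth 0.1-nm-bin profiles. Layer z
coordinates use stratified inverse-CDF sampling: base-position shot noise
does not average out across frames (frames share the base structure), so
stratification is what makes realised plateaus match the parametric
target within a few percent per bin.

Water generated inside the interfacial band (brush region +
`interfacial_band_nm`, default 0.6 nm) is pulled, direction-preserving,
to within 0.28 nm of its nearest PMOXA bead so that the analyser's
default 0.4 nm distance criterion labels it interfacial; bulk water fills
the remainder. Per-frame displacements are i.i.d. Gaussian per component
(defaults 0.05–0.06 nm) or Ornstein–Uhlenbeck with the same stationary
sd. The generator emits the analytic truth (thickness, plateau densities
and the z-ranges where they hold) alongside the trajectory.

What the generator does *not* emulate: chain connectivity and
conformational statistics (no U/I-shapes, no polymer dispersity),
force-field energetics, water orientation or hydrogen bonding, and
density cross-correlations between layers. Passing tests therefore
demonstrate that the *analysis* recovers known structure and trends; they
are not evidence about real membrane physics.

## Membrane analysis conventions

- Profiles are binned along z (bin 0.1 nm; the actual width is the box
  length divided by the rounded bin count), centred per frame on the PDMS
  centre of mass computed circularly to respect periodicity. Uncertainty
  bands are across-frame standard deviations.
- Interfacial water: within 0.4 nm (default) of any PMOXA atom, per
  frame, using a periodic k-d tree. This distance cutoff is the main
  methodological free parameter and is exposed in the API and CLI.
- Membrane thickness: distance between the two z where the mean PDMS
  density crosses 50 % of its plateau, with the plateau taken as the
  median of near-maximal bins (robust to single-bin noise) and linear
  interpolation between bins.
- Water-layer thickness: FWHM of the interfacial-water peak per leaflet;
  cross-over height: innermost PMOXA/bulk-water intersection walking
  outward from the core; AUC: trapezoidal integral of the interfacial
  density. Leaflet values are averaged; sds come from frame-wise metrics.
  A missing intersection is flagged rather than fabricated; a slab with
  no interfacial water reports zero thickness and AUC with a warning.
- RMSF: per-atom deviation from its time-average after removing per-frame
  membrane (PDMS+PMOXA) centre-of-mass translation; coordinates are
  first unwrapped frame-to-frame by minimum image so boundary-crossing
  fluctuations do not register box-sized jumps. For i.i.d. fluctuations
  of per-axis sd σ over F frames the expectation is σ√3·√((F−1)/F).

## Problem sizes and determinism

Test and acceptance runs use 2¹⁸–2²⁰-step traces with ~50–70 particles,
6–10 seeds per statistic, and membrane slabs of ~3–15 k pseudo-atoms ×
25 frames (2000 frames for the RMSF closed-form check) — sizes chosen so
the statistical tolerances above (±5 pp on F2 medians, 10 % on τ_D, 3 %
on RMSF) have comfortable margins while a full run stays in the minutes
range on one CPU. Every stochastic element takes an explicit seed;
identical seeds give bit-identical traces, trajectories and outputs.

## Known limitations

- Amplitude fractions are reported as fitted; converting to number
  fractions requires per-species brightnesses the assay does not measure.
- The correlator pair shares the symmetric-normalisation estimator;
  residual finite-trace bias (≈ −2∫G dτ/T) is absorbed by the optional
  baseline, not modelled.
- GRO output truncates atom numbering fields at 99 999 (format limit);
  trajectories here are far smaller.
- The membrane reader supports orthorhombic boxes and constant atom
  counts only; the RMSF unwrap assumes no atom drifts more than half a
  box between consecutive frames.
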