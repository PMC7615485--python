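# oxafoul

Quantitative analysis of protein fouling on PMOXA-*b*-PDMS-*b*-PMOXA
polymersomes, for researchers studying antifouling nanoparticle surfaces.
The package implements two measurement pipelines end to end, each paired
with a synthetic-data generator carrying exact ground truth so every stage
can be verified without instrument data or trajectory downloads:

1. **In-situ FCS fouling assay.** Serum proteins are fluorescently
   labelled; unlabelled polymersomes are mixed in. Because a correlation
   curve is dominated by bright, slow species, even modest protein binding
   shifts amplitude into the slow component. The autocorrelation is fitted
   with the standard 3D-Gaussian two-component model

   G(τ) = (1/N) · [1 + T e^(−τ/τ_T)/(1−T)] · Σᵢ fᵢ (1+τ/τ_D,i)⁻¹ (1+τ/(S²τ_D,i))⁻¹ᐟ²

   with both diffusion times **fixed** (fast = free protein, slow =
   polymersome) and the fractions free. The readouts are the particle
   fraction **F2 = 100·f_slow**, counts per particle **CPP = ⟨count
   rate⟩/N**, and hydrodynamic diameters d = k_BT/(3πηD) from
   one-component calibration fits (τ_D = w_xy²/4D). Repeats are
   aggregated as per-experiment medians, then mean ± s.e.m. across
   experiments, with an F2-threshold exclusion for aggregate-contaminated
   curves.

2. **Membrane-hydration analysis.** From labelled slab trajectories
   (PDMS core / PMOXA brush / water), it computes membrane-normal mass
   density profiles with water split into *interfacial* (within a cutoff
   of any PMOXA atom, per frame) and *bulk*; the core thickness (50 % of
   the PDMS plateau); the interfacial water-layer thickness (FWHM of the
   interfacial peak); the cross-over height where the PMOXA density meets
   bulk water; the interfacial density AUC; and the PMOXA RMSF after
   removing membrane drift.

The synthetic side provides Brownian-dynamics photon traces in a periodic
box through a 3D-Gaussian detection volume, exact (FFT-based) multi-tau
and brute-force correlators, closed-form noisy curves, and parametric
layered membrane slabs — all bit-reproducible per seed.

## Worked example

```python
import numpy as np
from oxafoul import formulation as fo, fcs_model as fm, fcs_fit as ff
from oxafoul import synthetic_data as sd, membrane_analysis as ma

# hydrophilic weight fraction of the long blend copolymer
long_c = fo.parse_copolymer_name("21-65-21")
print(f"f_hydrophilic(21-65-21) = {fo.hydrophilic_fraction(long_c):.1f}%")

# closed-loop fouling assay on a simulated protein/polymersome mixture
vol = fm.DetectionVolume(w_xy_um=0.25, structure_parameter=5.0)
cfg = sd.FcsSimConfig(
    species=(sd.SpeciesConfig(46, 4.0e-10, 10.0),   # free labelled protein
             sd.SpeciesConfig(8, 4.4e-12, 50.0)),   # polymersome-bound label
    box_um=(2.0, 2.0, 5.0), dt_s=4e-6, n_steps=1 << 19, volume=vol, seed=7)
trace = sd.simulate_fcs_trace(cfg)
curve = sd.autocorrelate_multitau(trace, max_lag=1 << 16)
spec = fm.FcsModelSpec(
    n=1.0,
    components=(fm.FcsComponent(fm.tau_d_from_diffusion(4.0e-10, vol), 0.5),
                fm.FcsComponent(fm.tau_d_from_diffusion(4.4e-12, vol), 0.5)),
    volume=vol)
res = ff.fit_curve(curve, spec)
print(f"true amplitude fraction = {100 * sd.amplitude_fractions(cfg)[1]:.1f}%")
print(f"fitted particle fraction F2 = {res.f2:.1f}%  (N = {res.n:.2f}, CPP = {res.cpp_khz:.1f} kHz)")

# membrane-hydration metrics on a synthetic slab
traj, gt = sd.generate_membrane_trajectory(sd.MembraneSimConfig(seed=1))
profile = ma.density_profile(traj, bin_width_nm=0.1, interfacial_cutoff_nm=0.4)
metrics = ma.interface_metrics(profile)
print(f"membrane thickness = {metrics.membrane_thickness_nm:.2f} nm (truth {gt.membrane_thickness_nm:.1f})")
print(f"interfacial water layer FWHM = {metrics.water_layer_thickness_nm:.2f} nm")
print(f"cross-over height = {metrics.crossover_height_nm:.2f} nm")
print(f"PMOXA RMSF = {ma.rmsf(traj, 'PMOXA').mean_over_selection_nm:.3f} nm")
```

Output:

```
f_hydrophilic(21-65-21) = 42.6%
true amplitude fraction = 81.3%
fitted particle fraction F2 = 84.5%  (N = 0.71, CPP = 10.2 kHz)
membrane thickness = 4.00 nm (truth 4.0)
interfacial water layer FWHM = 1.95 nm
cross-over height = 3.99 nm
PMOXA RMSF = 0.085 nm
```

The 42.6 % hydrophilic weight fraction places 21-65-21 at the upper edge
of the vesicle-forming window (≈35 ± 10 %). The single-seed fitted F2
(84.5 %) scatters around the true amplitude fraction (81.3 %); medians
over seeds recover it to within a couple of percentage points. The
membrane analyser recovers the generator's 4 nm core exactly, and the
PMOXA RMSF of 0.085 nm ≈ σ√3 for the generator's 0.05 nm per-axis
fluctuations.

## Command line

`oxafoul` exposes the same workflows as subcommands, each writing a
`manifest.json` with the package version, seed, parameters and SHA-256
input hashes:

```sh
oxafoul synth membrane --seed 3 --out slab/          # slab.gro + truth.json
oxafoul mem metrics --traj slab/slab.gro --out met/  # metrics.json
oxafoul synth fcs --seed 5 --out fcs/                # curve.csv + truth.json
oxafoul fcs fit --curves fcs/ --out fits/            # results.json
oxafoul formulation report --config blends.yaml --out form/
```

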