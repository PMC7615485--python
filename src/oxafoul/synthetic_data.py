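"""Synthetic inputs with known ground truth for the FCS and membrane pipelines.

Two generators are provided:

* Brownian-dynamics fluorescence traces: point emitters diffuse in a
  periodic box through a 3D-Gaussian detection volume; the binned
  intensity trace is correlated (multi-tau or direct) and fitted, closing
  the loop on the fouling assay with exactly known species parameters.
* Layered membrane slabs: pseudo-atoms realise parametric PDMS-core /
  PMOXA-brush / water density profiles with Gaussian positional
  fluctuations, so every density-profile and interface metric has an
  analytic target.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.fft import irfft, next_fast_len, rfft
from scipy.spatial import cKDTree

from .fcs_fit import CorrelationCurve
from .fcs_model import DetectionVolume, FcsModelSpec, g_model
from .membrane_analysis import DEFAULT_COMPONENT_MASSES, Trajectory


# ---------------------------------------------------------------------------
# FCS Brownian-dynamics simulation

@dataclass(frozen=True)
class SpeciesConfig:
    """One diffusing species: copy number in the box, D, and brightness.

    ``start_um`` pins all particles of the species to a common initial
    position (box coordinates); by default starts are uniform in the box.
    """

    count: int
    diffusion_m2_s: float
    brightness_khz: float
    start_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("species count must be >= 1")
        if self.diffusion_m2_s < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.brightness_khz < 0:
            raise ValueError("brightness must be non-negative")


@dataclass(frozen=True)
class FcsSimConfig:
    """Brownian-dynamics configuration for a confocal FCS simulation.

    The box (micrometres, periodic) must be at least 8 beam waists wide in
    every axis and at least 4 axial waists along z so that the detection
    volume never wraps onto itself.
    """

    species: tuple[SpeciesConfig, ...]
    box_um: tuple[float, float, float] = (2.0, 2.0, 6.0)
    dt_s: float = 2e-6
    n_steps: int = 1 << 18
    volume: DetectionVolume = field(default_factory=DetectionVolume)
    background_khz: float = 0.0
    photon_sampling: str = "expected"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if self.dt_s <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.photon_sampling not in ("expected", "poisson"):
            raise ValueError("photon_sampling must be 'expected' or 'poisson'")
        box = np.asarray(self.box_um, dtype=float)
        if np.any(box < 8.0 * self.volume.w_xy_um):
            raise ValueError("box must be >= 8 x w_xy in every axis")
        if box[2] < 4.0 * self.volume.w_z_um:
            raise ValueError("box z-extent too small versus w_z (need >= 4 x w_z)")
        for sp in self.species:
            step = math.sqrt(2.0 * sp.diffusion_m2_s * 1e12 * self.dt_s)
            if step > self.volume.w_xy_um / 4.0:
                warnings.warn(
                    f"RMS step {step:.3g} um exceeds w_xy/4; trace may under-resolve "
                    "the focal transit",
                    stacklevel=2,
                )

    @property
    def box_volume_um3(self) -> float:
        return float(np.prod(self.box_um))

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_s


@dataclass(frozen=True)
class IntensityTrace:
    """Binned fluorescence intensity (expected or Poisson-sampled counts)."""

    values: np.ndarray
    bin_width_s: float
    truth: FcsSimConfig | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace must be a 1-D array of >= 2 bins")
        if self.bin_width_s <= 0:
            raise ValueError("bin width must be positive")
        if np.any(v < 0):
            raise ValueError("intensity values must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.values.size * self.bin_width_s

    @property
    def mean_rate_khz(self) -> float:
        return float(self.values.mean() / self.bin_width_s / 1e3)


def species_n_effective(cfg: FcsSimConfig) -> np.ndarray:
    """Analytic mean occupancy of the effective volume per species."""
    v_eff = cfg.volume.effective_volume_um3
    return np.array([sp.count * v_eff / cfg.box_volume_um3 for sp in cfg.species])


def amplitude_fractions(cfg: FcsSimConfig) -> np.ndarray:
    """True amplitude fractions f_i = N_i B_i^2 / sum_j N_j B_j^2.

    This is the quantity a two-component amplitude fit estimates: bright
    species contribute with the square of their brightness, which is why
    a few bright slow particles dominate the correlation curve.
    """
    n_eff = species_n_effective(cfg)
    w = n_eff * np.array([sp.brightness_khz for sp in cfg.species]) ** 2
    return w / w.sum()


def expected_mean_rate_khz(cfg: FcsSimConfig) -> float:
    """Analytic mean count rate: background + sum_p B_p <MDF> over the box."""
    vol = cfg.volume
    gauss_integral = (np.pi / 2.0) ** 1.5 * vol.w_xy_um**2 * vol.w_z_um
    rate = cfg.background_khz
    for sp in cfg.species:
        rate += sp.count * sp.brightness_khz * gauss_integral / cfg.box_volume_um3
    return float(rate)


@njit(cache=False, fastmath=True)
def _bd_kernel(count, n_steps, start, random_start, box, sigma, w2, wz2, out, seed):  # pragma: no cover
    np.random.seed(seed)
    hx, hy, hz = box[0] * 0.5, box[1] * 0.5, box[2] * 0.5
    for _ in range(count):
        if random_start:
            x = np.random.uniform(0.0, box[0])
            y = np.random.uniform(0.0, box[1])
            z = np.random.uniform(0.0, box[2])
        else:
            x, y, z = start[0], start[1], start[2]
        for t in range(n_steps):
            x = (x + sigma * np.random.normal()) % box[0]
            y = (y + sigma * np.random.normal()) % box[1]
            z = (z + sigma * np.random.normal()) % box[2]
            dx, dy, dz = x - hx, y - hy, z - hz
            out[t] += math.exp(-2.0 * (dx * dx + dy * dy) / w2 - 2.0 * dz * dz / wz2)


def simulate_fcs_trace(cfg: FcsSimConfig) -> IntensityTrace:
    """Simulate a binned intensity trace by Brownian dynamics.

    Particles take independent Gaussian steps of per-axis variance
    2 D dt with periodic wrapping; the instantaneous rate is the sum of
    per-particle brightnesses weighted by the 3D-Gaussian detection
    profile centred in the box.  Expected-value sampling returns the rate
    integral per bin; Poisson sampling draws shot noise on top.  Bit-for-
    bit reproducible per seed (one derived stream per species).
    """
    box = np.asarray(cfg.box_um, dtype=float)
    w2 = cfg.volume.w_xy_um**2
    wz2 = cfg.volume.w_z_um**2
    n = cfg.n_steps
    rate_khz = np.full(n, float(cfg.background_khz))

    for i, sp in enumerate(cfg.species):
        sigma = math.sqrt(2.0 * sp.diffusion_m2_s * 1e12 * cfg.dt_s)  # um
        sub_seed = int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0])
        if sp.start_um is None:
            start = np.zeros(3)
            random_start = True
        else:
            start = np.mod(np.asarray(sp.start_um, dtype=float), box)
            random_start = False
        mdf = np.zeros(n)
        _bd_kernel(sp.count, n, start, random_start, box, sigma, w2, wz2, mdf, sub_seed)
        rate_khz += sp.brightness_khz * mdf

    rng = np.random.default_rng(cfg.seed)
    expected_counts = rate_khz * 1e3 * cfg.dt_s
    if cfg.photon_sampling == "poisson":
        values = rng.poisson(expected_counts).astype(float)
    else:
        values = expected_counts
    return IntensityTrace(values=values, bin_width_s=cfg.dt_s, truth=cfg)


# ---------------------------------------------------------------------------
# Correlators

def _normalized_correlation(values: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Symmetrically normalised fluctuation autocorrelation at given lags.

    G(k) = [<I_t I_{t+k}> - <I>_L <I>_R] / (<I>_L <I>_R), where the left
    and right means run over the overlapping segments only — the standard
    symmetric normalisation that suppresses finite-trace bias.  Cross sums
    for all lags come from one FFT; the result is identical (to round-off)
    to the literal direct estimator at every lag.
    """
    n = values.size
    csum = np.concatenate(([0.0], np.cumsum(values)))
    total = csum[-1]
    nfft = next_fast_len(2 * n)
    f = rfft(values, nfft)
    cross = irfft(f * np.conj(f), nfft)[:n]  # cross[k] = sum_t I_t I_{t+k}

    g = np.empty(lags.size)
    for i, k in enumerate(lags):
        m = n - k
        mean_l = csum[m] / m
        mean_r = (total - csum[k]) / m
        denom = mean_l * mean_r
        if denom == 0:
            raise ZeroDivisionError("zero-mean trace segment: cannot normalise")
        g[i] = (cross[k] / m - denom) / denom
    return g


def multitau_lag_grid(n: int, m: int = 16, max_lag: int | None = None) -> np.ndarray:
    """Quasi-logarithmic multi-tau lag grid: m linear lags, then doubling
    spacing per stage (m/2 points per stage)."""
    if max_lag is None:
        max_lag = n // 4
    lags = list(range(1, m + 1))
    spacing = 2
    while lags[-1] < max_lag:
        start = lags[-1] + spacing
        stop = min(lags[-1] * 2, max_lag)
        stage = list(range(start, stop + 1, spacing))
        if not stage:
            break
        lags.extend(stage)
        spacing *= 2
    return np.array([k for k in lags if k < n], dtype=int)


def autocorrelate_direct(trace: IntensityTrace, lags) -> CorrelationCurve:
    """Literal O(N x L) reference correlator at explicitly requested lags."""
    lags = np.asarray(lags, dtype=int)
    v = trace.values
    n = v.size
    if np.max(lags) >= n:
        raise ValueError("max lag must be smaller than the trace length")
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    if v.mean() == 0:
        raise ZeroDivisionError("zero-mean trace: cannot normalise")
    g = np.empty(lags.size)
    for i, k in enumerate(lags):
        x = v[: n - k] if k else v
        y = v[k:] if k else v
        ml, mr = x.mean(), y.mean()
        g[i] = (np.dot(x, y) / x.size - ml * mr) / (ml * mr)
    tau = np.where(lags == 0, trace.bin_width_s * 0.5, lags * trace.bin_width_s)
    # lag 0 is reported at half a bin so the tau grid stays strictly positive
    return CorrelationCurve(
        tau_s=tau.astype(float),
        g=g,
        mean_count_rate_khz=trace.mean_rate_khz,
        duration_s=trace.duration_s,
        label="direct",
    )


def autocorrelate_multitau(
    trace: IntensityTrace, m: int = 16, max_lag: int | None = None
) -> CorrelationCurve:
    """Autocorrelation on a multi-tau (quasi-logarithmic) lag grid.

    The grid uses m linear lags then doubles the spacing per stage; at
    every retained lag the estimator is the exact symmetrically-normalised
    correlation (FFT cross-sums), so it agrees with the direct correlator
    to round-off while covering decades of lag time at O(N log N) cost.
    """
    v = trace.values
    if v.size < 2 * m:
        raise ValueError(f"trace length {v.size} < 2m = {2 * m}")
    if v.mean() == 0:
        raise ZeroDivisionError("zero-mean trace: cannot normalise")
    lags = multitau_lag_grid(v.size, m=m, max_lag=max_lag)
    g = _normalized_correlation(v, lags)
    return CorrelationCurve(
        tau_s=lags * trace.bin_width_s,
        g=g,
        mean_count_rate_khz=trace.mean_rate_khz,
        duration_s=trace.duration_s,
        label="multitau",
    )


def generate_fcs_curve(
    spec: FcsModelSpec,
    lag_grid,
    noise_sd: float = 0.0,
    relative_noise: bool = False,
    seed: int | None = None,
    mean_count_rate_khz: float = 0.0,
    label: str = "model",
) -> CorrelationCurve:
    """Evaluate the closed-form model on a lag grid with seeded Gaussian noise.

    A fast fixture path that bypasses Brownian dynamics: useful for fit
    round-trips and noise-robustness checks where the exact correlation
    shape is the ground truth.
    """
    tau = np.asarray(lag_grid, dtype=float)
    g = g_model(tau, spec)
    sigma = None
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd * (np.abs(g) if relative_noise else np.ones_like(g))
        g = g + rng.standard_normal(tau.size) * sigma
    return CorrelationCurve(
        tau_s=tau,
        g=g,
        sigma_g=sigma,
        mean_count_rate_khz=mean_count_rate_khz,
        duration_s=0.0,
        label=label,
    )


# ---------------------------------------------------------------------------
# Membrane slab generator

@dataclass(frozen=True)
class MembraneSimConfig:
    """Parametric layered membrane slab: PDMS core, PMOXA brush, water.

    Lengths in nm, densities in kg/m^3.  The PMOXA brush density is a
    plateau over ``brush_extent_nm`` followed by an exponential (or
    linear) tail of scale ``brush_decay_length_nm``.  Water fills the
    region beyond the core: atoms whose z falls inside the interfacial
    band (brush region plus ``interfacial_band_nm``) are placed within
    ``interfacial_snap_nm`` of a PMOXA atom so the distance criterion of
    the analyser labels them interfacial; the remainder is bulk.
    Per-frame displacements are Gaussian, i.i.d. or Ornstein-Uhlenbeck.
    """

    core_half_width_nm: float = 2.0
    core_density_kg_m3: float = 965.0
    brush_anchor_offset_nm: float = 0.0
    brush_extent_nm: float = 1.5
    brush_plateau_density_kg_m3: float = 300.0
    brush_decay_length_nm: float = 0.3
    brush_profile: str = "exponential"  # or "linear"
    water_density_kg_m3: float = 997.0
    interfacial_band_nm: float = 0.6
    interfacial_snap_nm: float = 0.28
    fluct_sigma_nm: dict = field(
        default_factory=lambda: {"PDMS": 0.05, "PMOXA": 0.05, "WATER": 0.06}
    )
    temporal_correlation: str = "iid"  # or "ou"
    ou_tau_frames: float = 5.0
    box_nm: tuple[float, float, float] = (5.0, 5.0, 16.0)
    n_frames: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.core_half_width_nm, self.brush_extent_nm) <= 0:
            raise ValueError("core half-width and brush extent must be positive")
        if min(
            self.core_density_kg_m3,
            self.brush_plateau_density_kg_m3,
            self.water_density_kg_m3,
        ) < 0:
            raise ValueError("densities must be non-negative")
        if self.brush_profile not in ("exponential", "linear"):
            raise ValueError("brush_profile must be 'exponential' or 'linear'")
        if self.temporal_correlation not in ("iid", "ou"):
            raise ValueError("temporal_correlation must be 'iid' or 'ou'")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        reach = (
            self.core_half_width_nm
            + self.brush_anchor_offset_nm
            + self.brush_extent_nm
            + self.interfacial_band_nm
        )
        if self.box_nm[2] < 2.0 * (reach + 1.0):
            raise ValueError("box z-extent must cover core + brush + water margin twice")
        for comp, dens, mass in (
            ("PDMS", self.core_density_kg_m3, DEFAULT_COMPONENT_MASSES["PDMS"]),
            ("PMOXA", self.brush_plateau_density_kg_m3, DEFAULT_COMPONENT_MASSES["PMOXA"]),
            ("WATER", self.water_density_kg_m3, DEFAULT_COMPONENT_MASSES["WATER"]),
        ):
            if dens / (mass * 1.66053906660) > 60.0:
                raise ValueError(f"{comp} density implies unphysical pseudo-atom packing")


@dataclass(frozen=True)
class MembraneTruth:
    """Analytic ground truth emitted alongside a generated slab."""

    membrane_thickness_nm: float
    core_density_kg_m3: float
    brush_plateau_density_kg_m3: float
    water_density_kg_m3: float
    interfacial_band_z_nm: tuple[float, float]  # |z| range holding interfacial water
    bulk_water_z_nm: tuple[float, float]
    brush_plateau_z_nm: tuple[float, float]
    core_plateau_z_nm: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "membrane_thickness_nm": self.membrane_thickness_nm,
            "core_density_kg_m3": self.core_density_kg_m3,
            "brush_plateau_density_kg_m3": self.brush_plateau_density_kg_m3,
            "water_density_kg_m3": self.water_density_kg_m3,
            "interfacial_band_z_nm": list(self.interfacial_band_z_nm),
            "bulk_water_z_nm": list(self.bulk_water_z_nm),
            "brush_plateau_z_nm": list(self.brush_plateau_z_nm),
            "core_plateau_z_nm": list(self.core_plateau_z_nm),
        }


def _number_density_per_nm3(density_kg_m3: float, mass_amu: float) -> float:
    return density_kg_m3 / (mass_amu * 1.66053906660)


def _stratified_uniform(rng, count: int) -> np.ndarray:
    """Stratified uniforms on [0, 1): one draw per equal stratum.

    Used for layer z-coordinates so the realised profile matches the
    parametric target without persistent Poisson roughness (which frame
    averaging cannot remove, since base positions are shared by frames).
    """
    return (np.arange(count) + rng.uniform(size=count)) / count


def _sample_brush_z(rng, cfg: MembraneSimConfig, count: int) -> np.ndarray:
    """Sample |z| offsets from the brush profile (plateau + tail), one leaflet."""
    ext, lam = cfg.brush_extent_nm, cfg.brush_decay_length_nm
    if cfg.brush_profile == "exponential":
        tail_mass = lam * (1.0 - math.exp(-3.0))
    else:
        tail_mass = lam / 2.0  # linear ramp down over lam
    p_plateau = ext / (ext + tail_mass)
    u = _stratified_uniform(rng, count)
    z = np.empty(count)
    in_plateau = u < p_plateau
    z[in_plateau] = u[in_plateau] / p_plateau * ext
    n_tail = count - int(in_plateau.sum())
    if n_tail:
        v = (u[~in_plateau] - p_plateau) / (1.0 - p_plateau)
        if cfg.brush_profile == "exponential":
            # truncated exponential on [0, 3 lam]
            z_tail = -lam * np.log(1.0 - v * (1.0 - math.exp(-3.0)))
        else:
            z_tail = lam * (1.0 - np.sqrt(1.0 - v))
        z[~in_plateau] = ext + z_tail
    start = cfg.core_half_width_nm + cfg.brush_anchor_offset_nm
    return start + z


def generate_membrane_trajectory(
    cfg: MembraneSimConfig,
) -> tuple[Trajectory, MembraneTruth]:
    """Build a labelled slab trajectory realising the parametric layer profile.

    Returns the trajectory (coordinates in [0, box), membrane centred at
    box_z/2) together with the analytic ground truth the analyser should
    recover.
    """
    rng = np.random.default_rng(cfg.seed)
    lx, ly, lz = cfg.box_nm
    area = lx * ly
    c = cfg.core_half_width_nm
    brush_start = c + cfg.brush_anchor_offset_nm
    brush_end = brush_start + cfg.brush_extent_nm
    band_end = brush_end + cfg.interfacial_band_nm

    masses = DEFAULT_COMPONENT_MASSES
    positions: list[np.ndarray] = []
    labels: list[str] = []

    def _add(comp: str, pos: np.ndarray) -> None:
        positions.append(pos)
        labels.extend([comp] * pos.shape[0])

    # PDMS core: uniform slab |z| < c (z stratified for a flat realised profile)
    n_core = int(round(_number_density_per_nm3(cfg.core_density_kg_m3, masses["PDMS"]) * area * 2 * c))
    core = np.column_stack(
        [
            rng.uniform(0, lx, n_core),
            rng.uniform(0, ly, n_core),
            -c + 2 * c * _stratified_uniform(rng, n_core),
        ]
    )
    _add("PDMS", core)

    # PMOXA brush, per leaflet
    if cfg.brush_profile == "exponential":
        tail_mass = cfg.brush_decay_length_nm * (1.0 - math.exp(-3.0))
    else:
        tail_mass = cfg.brush_decay_length_nm / 2.0
    nu_brush = _number_density_per_nm3(cfg.brush_plateau_density_kg_m3, masses["PMOXA"])
    n_brush = int(round(nu_brush * area * (cfg.brush_extent_nm + tail_mass)))
    pmoxa_list = []
    for sign in (+1.0, -1.0):
        zb = sign * _sample_brush_z(rng, cfg, n_brush)
        leaf = np.column_stack(
            [rng.uniform(0, lx, n_brush), rng.uniform(0, ly, n_brush), zb]
        )
        pmoxa_list.append(leaf)
    pmoxa = np.vstack(pmoxa_list)
    _add("PMOXA", pmoxa)

    # interfacial water: stratified over the band, pulled to within snapping
    # distance of the nearest PMOXA atom (direction-preserving) so the
    # analyser's distance criterion labels it interfacial
    nu_w = _number_density_per_nm3(cfg.water_density_kg_m3, masses["WATER"])
    band_width = band_end - brush_start
    n_int = int(round(nu_w * area * band_width))
    tree = cKDTree(pmoxa)
    int_list = []
    for sign in (+1.0, -1.0):
        w = np.column_stack(
            [
                rng.uniform(0, lx, n_int),
                rng.uniform(0, ly, n_int),
                sign * (brush_start + band_width * _stratified_uniform(rng, n_int)),
            ]
        )
        dist, idx = tree.query(w, k=1)
        far = dist > cfg.interfacial_snap_nm
        if np.any(far):
            n_far = int(far.sum())
            anchor = pmoxa[idx[far]]
            direction = (w[far] - anchor) / dist[far][:, None]
            r = rng.uniform(0.5 * cfg.interfacial_snap_nm, cfg.interfacial_snap_nm, n_far)
            w[far] = anchor + direction * r[:, None]
        int_list.append(w)
    _add("WATER", np.vstack(int_list))

    # bulk water: uniform beyond the band up to the box edge
    bulk_span = lz / 2.0 - band_end
    if bulk_span <= 0:
        raise ValueError("no room for bulk water; enlarge the box")
    n_bulk = int(round(nu_w * area * bulk_span))
    bulk_list = []
    for sign in (+1.0, -1.0):
        w = np.column_stack(
            [
                rng.uniform(0, lx, n_bulk),
                rng.uniform(0, ly, n_bulk),
                sign * (band_end + bulk_span * _stratified_uniform(rng, n_bulk)),
            ]
        )
        bulk_list.append(w)
    _add("WATER", np.vstack(bulk_list))

    base = np.vstack(positions)
    base[:, 2] += lz / 2.0  # membrane centre at box mid-plane
    labels_arr = np.array(labels)
    atom_masses = np.array([masses[lab] for lab in labels_arr])
    sigma = np.array([cfg.fluct_sigma_nm.get(lab, 0.0) for lab in labels_arr])

    n_atoms = base.shape[0]
    frames = np.empty((cfg.n_frames, n_atoms, 3))
    if cfg.temporal_correlation == "iid" or cfg.n_frames == 1:
        noise = rng.standard_normal((cfg.n_frames, n_atoms, 3)) * sigma[None, :, None]
    else:
        theta = math.exp(-1.0 / cfg.ou_tau_frames)
        noise = np.empty((cfg.n_frames, n_atoms, 3))
        noise[0] = rng.standard_normal((n_atoms, 3)) * sigma[:, None]
        scale = math.sqrt(1.0 - theta * theta)
        for f in range(1, cfg.n_frames):
            noise[f] = theta * noise[f - 1] + scale * rng.standard_normal(
                (n_atoms, 3)
            ) * sigma[:, None]
    frames[:] = base[None, :, :] + noise

    traj = Trajectory(
        frames=frames,
        labels=labels_arr,
        masses=atom_masses,
        box=np.array(cfg.box_nm, dtype=float),
    )
    truth = MembraneTruth(
        membrane_thickness_nm=2.0 * c,
        core_density_kg_m3=cfg.core_density_kg_m3,
        brush_plateau_density_kg_m3=cfg.brush_plateau_density_kg_m3,
        water_density_kg_m3=cfg.water_density_kg_m3,
        interfacial_band_z_nm=(brush_start, band_end),
        bulk_water_z_nm=(band_end, lz / 2.0),
        brush_plateau_z_nm=(brush_start, brush_end),
        core_plateau_z_nm=(0.0, c),
    )
    return traj, truth
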