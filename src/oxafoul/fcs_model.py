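"""Closed-form confocal FCS correlation models and diffusion/size conversions.

The canonical model is the 3D-Gaussian detection volume with translational
diffusion of one or two species and an optional triplet (dark-state) term:

    G(tau) = (1/N) * [1 + T e^(-tau/tau_T) / (1 - T)]
             * sum_i f_i * (1 + tau/tau_D,i)^-1 * (1 + tau/(S^2 tau_D,i))^-1/2

with mean occupancy N, amplitude fractions f_i summing to 1, diffusion
times tau_D,i = w_xy^2 / (4 D_i) and structure parameter S = w_z / w_xy.
Hydrodynamic diameters follow from Stokes-Einstein, d = k_B T / (3 pi eta D).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BOLTZMANN = 1.380649e-23  # J/K

#: Default sizing conditions: water at 25 degC.
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_VISCOSITY_PA_S = 8.9e-4


@dataclass(frozen=True)
class DetectionVolume:
    """Confocal 3D-Gaussian detection volume.

    ``w_xy_um`` is the lateral 1/e^2 radius in micrometres and
    ``structure_parameter`` the axial elongation S = w_z / w_xy.  These are
    instrument calibration constants, never fitted.
    """

    w_xy_um: float = 0.25
    structure_parameter: float = 5.0

    def __post_init__(self) -> None:
        if self.w_xy_um <= 0:
            raise ValueError("w_xy must be positive")
        if self.structure_parameter < 1:
            raise ValueError("structure parameter S must be >= 1")

    @property
    def w_z_um(self) -> float:
        return self.w_xy_um * self.structure_parameter

    @property
    def effective_volume_um3(self) -> float:
        """V_eff = pi^(3/2) w_xy^2 w_z, the FCS occupancy normalisation volume."""
        return float(np.pi ** 1.5 * self.w_xy_um**2 * self.w_z_um)


@dataclass(frozen=True)
class FcsComponent:
    """One diffusing species in the correlation model.

    ``fixed`` marks tau_D as held constant during fitting — the defining
    constraint of the fouling assay, where the fast time is pinned to the
    free labelled protein and the slow time to the polymersome.
    """

    tau_d_s: float
    fraction: float = 1.0
    fixed: bool = True

    def __post_init__(self) -> None:
        if self.tau_d_s <= 0:
            raise ValueError("tau_D must be positive")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FcsModelSpec:
    """Full parameter set of the one- or two-component triplet FCS model."""

    n: float
    components: tuple[FcsComponent, ...]
    volume: DetectionVolume = field(default_factory=DetectionVolume)
    triplet_fraction: float = 0.0
    triplet_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("occupancy N must be positive")
        if not 1 <= len(self.components) <= 2:
            raise ValueError("model supports 1 or 2 components")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1 (got {total})")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet fraction must lie in [0, 1)")
        if self.triplet_fraction > 0:
            if self.triplet_time_s <= 0:
                raise ValueError("triplet time must be positive when triplet enabled")
            if self.triplet_time_s >= min(c.tau_d_s for c in self.components):
                raise ValueError("triplet time must be shorter than all diffusion times")

    @property
    def triplet_enabled(self) -> bool:
        return self.triplet_fraction > 0.0

    def with_updates(self, **kwargs) -> "FcsModelSpec":
        return replace(self, **kwargs)


def g_model(tau, spec: FcsModelSpec):
    """Evaluate G(tau) for a model spec on scalar or array lag times (s)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag times must be non-negative")
    s2 = spec.volume.structure_parameter**2
    g = np.zeros_like(tau)
    for c in spec.components:
        g = g + c.fraction / ((1.0 + tau / c.tau_d_s) * np.sqrt(1.0 + tau / (s2 * c.tau_d_s)))
    if spec.triplet_enabled:
        t = spec.triplet_fraction
        g = g * (1.0 + t * np.exp(-tau / spec.triplet_time_s) / (1.0 - t))
    return g / spec.n


def tau_d_from_diffusion(diffusion_m2_s: float, volume: DetectionVolume) -> float:
    """Diffusion time tau_D = w_xy^2 / (4 D) in seconds."""
    if diffusion_m2_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    w = volume.w_xy_um * 1e-6
    return w * w / (4.0 * diffusion_m2_s)


def diffusion_from_tau_d(tau_d_s: float, volume: DetectionVolume) -> float:
    """Inverse of :func:`tau_d_from_diffusion`: D = w_xy^2 / (4 tau_D), m^2/s."""
    if tau_d_s <= 0:
        raise ValueError("tau_D must be positive")
    w = volume.w_xy_um * 1e-6
    return w * w / (4.0 * tau_d_s)


def stokes_einstein_diameter(
    diffusion_m2_s: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
) -> float:
    """Hydrodynamic diameter d = k_B T / (3 pi eta D), reported in nm."""
    if min(diffusion_m2_s, temperature_k, viscosity_pa_s) <= 0:
        raise ValueError("all inputs must be positive")
    d_m = BOLTZMANN * temperature_k / (3.0 * np.pi * viscosity_pa_s * diffusion_m2_s)
    return d_m * 1e9


def stokes_einstein_diffusion(
    diameter_nm: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
) -> float:
    """Inverse sizing relation: D = k_B T / (3 pi eta d), m^2/s."""
    if min(diameter_nm, temperature_k, viscosity_pa_s) <= 0:
        raise ValueError("all inputs must be positive")
    return BOLTZMANN * temperature_k / (3.0 * np.pi * viscosity_pa_s * diameter_nm * 1e-9)
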