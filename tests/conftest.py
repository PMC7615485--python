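"""Shared fixtures: detection geometry and small synthetic datasets."""

import numpy as np
import pytest

from oxafoul import fcs_model as fm
from oxafoul import synthetic_data as sd


@pytest.fixture(scope="session")
def volume() -> fm.DetectionVolume:
    return fm.DetectionVolume(w_xy_um=0.25, structure_parameter=5.0)


@pytest.fixture(scope="session")
def lag_grid() -> np.ndarray:
    return np.geomspace(1e-6, 1.0, 120)


def mixture_sim_config(
    volume: fm.DetectionVolume,
    n_slow: int,
    seed: int,
    n_steps: int = 1 << 18,
    n_fast: int = 46,
) -> sd.FcsSimConfig:
    """Standard fouling-assay study conditions: fast dim free protein
    (D = 4e-10 m^2/s, 10 kHz) plus slow bright 100-nm particles
    (D = 4.4e-12 m^2/s, 50 kHz) in a 2 x 2 x 5 um periodic box."""
    species = [sd.SpeciesConfig(n_fast, 4.0e-10, 10.0)]
    if n_slow > 0:
        species.append(sd.SpeciesConfig(n_slow, 4.4e-12, 50.0))
    return sd.FcsSimConfig(
        species=tuple(species),
        box_um=(2.0, 2.0, 5.0),
        dt_s=4e-6,
        n_steps=n_steps,
        volume=volume,
        seed=seed,
    )


def two_component_assay_spec(volume: fm.DetectionVolume) -> fm.FcsModelSpec:
    """Fit model with both diffusion times fixed to the mixture truth."""
    tau_fast = fm.tau_d_from_diffusion(4.0e-10, volume)
    tau_slow = fm.tau_d_from_diffusion(4.4e-12, volume)
    return fm.FcsModelSpec(
        n=1.0,
        components=(
            fm.FcsComponent(tau_fast, 0.5, fixed=True),
            fm.FcsComponent(tau_slow, 0.5, fixed=True),
        ),
        volume=volume,
    )


@pytest.fixture(scope="session")
def small_mixture_curve(volume):
    """One fast BD mixture realisation, correlated; reused across tests."""
    cfg = mixture_sim_config(volume, n_slow=8, seed=11, n_steps=1 << 16)
    trace = sd.simulate_fcs_trace(cfg)
    curve = sd.autocorrelate_multitau(trace, max_lag=1 << 14)
    return cfg, trace, curve
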