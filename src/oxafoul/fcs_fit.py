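"""Constrained fitting of FCS correlation curves and fouling statistics.

The in-situ fouling assay measures a mixture of fast, dim free labelled
serum protein and slow, bright polymersome-bound label.  Curves are fitted
with a two-component model whose diffusion times are both held fixed (fast
pinned to the free protein, slow to the particle); the free parameters are
the occupancy N and the slow amplitude fraction.  The headline statistics
are the particle fraction F2 = 100 x f_slow, the molecular-brightness
proxy CPP = mean count rate / N, and per-timepoint aggregates that take
the median over technical repeats within each independent experiment and
the mean +/- s.e.m. across experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np

from .fcs_model import (
    DEFAULT_TEMPERATURE_K,
    DEFAULT_VISCOSITY_PA_S,
    DetectionVolume,
    FcsComponent,
    FcsModelSpec,
    diffusion_from_tau_d,
    g_model,
    stokes_einstein_diameter,
)

logger = logging.getLogger(__name__)

#: Default cut used to drop technical repeats dominated by aggregates
#: (free-dye / calibration controls should show essentially no slow species;
#: an occasional aggregate drives F2 far above it).  Fully configurable:
#: the act of exclusion is part of the assay, the cut-off is a choice.
DEFAULT_AGGREGATE_F2_THRESHOLD = 50.0


@dataclass(frozen=True)
class CorrelationCurve:
    """A measured or simulated autocorrelation curve.

    ``tau_s`` must be strictly increasing and positive (log-spaced grids
    are typical); ``sigma_g`` are optional per-point standard deviations
    used as least-squares weights.
    """

    tau_s: np.ndarray
    g: np.ndarray
    sigma_g: np.ndarray | None = None
    mean_count_rate_khz: float = 0.0
    duration_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_s, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "tau_s", tau)
        object.__setattr__(self, "g", g)
        if tau.ndim != 1 or tau.size == 0:
            raise ValueError("tau must be a non-empty 1-D array")
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau must be strictly increasing and positive")
        if g.shape != tau.shape:
            raise ValueError("tau and G lengths disagree")
        if self.sigma_g is not None:
            sig = np.asarray(self.sigma_g, dtype=float)
            if sig.shape != tau.shape:
                raise ValueError("sigma_G length disagrees with tau")
            object.__setattr__(self, "sigma_g", sig)
        if self.mean_count_rate_khz < 0:
            raise ValueError("mean count rate must be non-negative")

    def __len__(self) -> int:
        return self.tau_s.size


@dataclass(frozen=True)
class FcsFitResult:
    """Outcome of a constrained curve fit plus derived fouling statistics."""

    spec_out: FcsModelSpec
    n: float
    f2: float  # slow-component amplitude fraction, percent
    cpp_khz: float  # mean count rate / N
    chi2_reduced: float
    converged: bool
    curve_label: str = ""


@dataclass(frozen=True)
class RepeatAggregate:
    """Per-timepoint aggregate over technical repeats and experiments."""

    timepoint: object
    median_f2: float  # mean over experiments of per-experiment median F2
    sem_f2: float
    n_used: int
    n_excluded: int
    exclusion_rule: str


@dataclass(frozen=True)
class FreeDyeCalibration:
    """Mean +/- sd diffusion time and Stokes-Einstein diameter over curves."""

    tau_d_mean_s: float
    tau_d_sd_s: float
    diameter_mean_nm: float
    diameter_sd_nm: float
    n_used: int
    n_excluded: int


def _count_free_parameters(spec: FcsModelSpec, fit_triplet: bool) -> int:
    n_free = 1  # occupancy N
    if len(spec.components) == 2:
        n_free += 1  # f_slow
    n_free += sum(0 if c.fixed else 1 for c in spec.components)
    if fit_triplet:
        n_free += 2
    return n_free


def fit_curve(
    curve: CorrelationCurve,
    spec: FcsModelSpec,
    fit_triplet: bool = False,
    init_f_slow: float = 0.5,
    fit_offset: bool = False,
) -> FcsFitResult:
    """Fit a correlation curve with the constrained one/two-component model.

    For the two-component fouling assay both diffusion times must be marked
    ``fixed`` in ``spec``; free parameters are N, the slow amplitude
    fraction (parameterised as a single f_slow in [0, 1] so the fractions
    sum to 1 by construction) and, optionally, the triplet term.
    ``fit_offset`` adds a free additive baseline that absorbs the residual
    normalisation offset of finite-trace correlation estimates (useful for
    free-tau_D calibration fits).  Weighted least squares uses 1/sigma_G
    when the curve carries uncertainties.  Non-convergence is reported
    through the ``converged`` flag, never as an exception.
    """
    if np.all(curve.g <= 0):
        raise ValueError("curve is non-positive everywhere; nothing to fit")
    if len(spec.components) == 2 and not all(c.fixed for c in spec.components):
        raise ValueError("two-component assay fits require both tau_D fixed")
    n_free = _count_free_parameters(spec, fit_triplet) + int(fit_offset)
    if len(curve) < n_free:
        raise ValueError(f"curve has {len(curve)} points < {n_free} free parameters")

    two = len(spec.components) == 2
    # order components fast -> slow for a stable f_slow meaning
    comps = sorted(spec.components, key=lambda c: c.tau_d_s)

    params = lmfit.Parameters()
    g0 = float(np.max(curve.g[: max(3, len(curve) // 20)]))
    n_init = 1.0 / g0 if g0 > 0 else spec.n
    params.add("n", value=max(n_init, 1e-6), min=1e-9, max=1e12)
    params.add("tau_d_fast", value=comps[0].tau_d_s, vary=not comps[0].fixed,
               min=comps[0].tau_d_s / 100, max=comps[0].tau_d_s * 100)
    if two:
        params.add("tau_d_slow", value=comps[1].tau_d_s, vary=not comps[1].fixed,
                   min=comps[1].tau_d_s / 100, max=comps[1].tau_d_s * 100)
        params.add("f_slow", value=init_f_slow, min=0.0, max=1.0)
    if fit_triplet:
        params.add("trip_t", value=max(spec.triplet_fraction, 0.05), min=0.0, max=0.999)
        tau_t0 = spec.triplet_time_s or comps[0].tau_d_s / 20.0
        params.add("trip_tau", value=tau_t0, min=1e-9, max=comps[0].tau_d_s)
    elif spec.triplet_enabled:
        params.add("trip_t", value=spec.triplet_fraction, vary=False)
        params.add("trip_tau", value=spec.triplet_time_s, vary=False)
    if fit_offset:
        params.add("g_inf", value=0.0, min=-0.5, max=0.5)

    s2 = spec.volume.structure_parameter**2
    tau = curve.tau_s
    weights = None
    if curve.sigma_g is not None and np.all(curve.sigma_g > 0):
        weights = 1.0 / curve.sigma_g

    def model(p) -> np.ndarray:
        v = p.valuesdict()
        f_slow = v.get("f_slow", 0.0)
        g = (1.0 - f_slow) / (
            (1.0 + tau / v["tau_d_fast"]) * np.sqrt(1.0 + tau / (s2 * v["tau_d_fast"]))
        )
        if two:
            g = g + f_slow / (
                (1.0 + tau / v["tau_d_slow"]) * np.sqrt(1.0 + tau / (s2 * v["tau_d_slow"]))
            )
        if "trip_t" in v and v["trip_t"] > 0:
            g = g * (1.0 + v["trip_t"] * np.exp(-tau / v["trip_tau"]) / (1.0 - v["trip_t"]))
        return g / v["n"] + v.get("g_inf", 0.0)

    def residual(p) -> np.ndarray:
        r = model(p) - curve.g
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, params, method="least_squares")
    v = result.params.valuesdict()
    f_slow = float(v.get("f_slow", 0.0))

    if two:
        out_components = (
            FcsComponent(v["tau_d_fast"], 1.0 - f_slow, comps[0].fixed),
            FcsComponent(v["tau_d_slow"], f_slow, comps[1].fixed),
        )
    else:
        out_components = (FcsComponent(v["tau_d_fast"], 1.0, comps[0].fixed),)
    spec_out = FcsModelSpec(
        n=float(v["n"]),
        components=out_components,
        volume=spec.volume,
        triplet_fraction=float(v.get("trip_t", 0.0)),
        triplet_time_s=float(v.get("trip_tau", 0.0)),
    )
    n_fit = float(v["n"])
    cpp = curve.mean_count_rate_khz / n_fit if n_fit > 0 else math.nan
    return FcsFitResult(
        spec_out=spec_out,
        n=n_fit,
        f2=100.0 * f_slow,
        cpp_khz=cpp,
        chi2_reduced=float(result.redchi),
        converged=bool(result.success),
        curve_label=curve.label,
    )


def chi2_fixed_model(curve: CorrelationCurve, spec: FcsModelSpec) -> float:
    """Reduced chi^2 of a fully-fixed model against a curve (no fitting)."""
    g = g_model(curve.tau_s, spec)
    r = g - curve.g
    if curve.sigma_g is not None and np.all(curve.sigma_g > 0):
        r = r / curve.sigma_g
    return float(np.sum(r * r) / len(curve))


def calibrate_free_dye(
    curves: list[CorrelationCurve],
    volume: DetectionVolume,
    tau_d_init_s: float = 4e-5,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
    fit_offset: bool = True,
) -> FreeDyeCalibration:
    """One-component calibration of a free-dye (or free-protein) sample.

    Each curve is fitted with a single freely-varying diffusion time (plus
    a baseline offset by default, absorbing finite-trace normalisation
    residue); the mean +/- sd of tau_D and of the Stokes-Einstein
    hydrodynamic diameter over converged curves is returned.
    Non-converged curves are excluded and counted.
    """
    if not curves:
        raise ValueError("calibration requires at least one curve")
    tau_ds = []
    n_excluded = 0
    spec = FcsModelSpec(
        n=1.0,
        components=(FcsComponent(tau_d_init_s, 1.0, fixed=False),),
        volume=volume,
    )
    for curve in curves:
        res = fit_curve(curve, spec, fit_offset=fit_offset)
        if res.converged:
            tau_ds.append(res.spec_out.components[0].tau_d_s)
        else:
            n_excluded += 1
    if not tau_ds:
        raise ValueError("no calibration curve converged")
    tau_arr = np.array(tau_ds)
    diam = np.array(
        [
            stokes_einstein_diameter(
                diffusion_from_tau_d(t, volume), temperature_k, viscosity_pa_s
            )
            for t in tau_ds
        ]
    )
    sd = float(np.std(tau_arr, ddof=1)) if tau_arr.size > 1 else 0.0
    sd_d = float(np.std(diam, ddof=1)) if diam.size > 1 else 0.0
    return FreeDyeCalibration(
        tau_d_mean_s=float(np.mean(tau_arr)),
        tau_d_sd_s=sd,
        diameter_mean_nm=float(np.mean(diam)),
        diameter_sd_nm=sd_d,
        n_used=len(tau_ds),
        n_excluded=n_excluded,
    )


def exclude_aggregates(
    results: list[FcsFitResult],
    f2_threshold: float = DEFAULT_AGGREGATE_F2_THRESHOLD,
    cpp_threshold_khz: float | None = None,
) -> tuple[list[FcsFitResult], list[FcsFitResult]]:
    """Split fit results into (kept, excluded) by an aggregate cut.

    Results with F2 above ``f2_threshold`` (or CPP above the optional CPP
    cut) are moved to the excluded list; input order is preserved in both.
    """
    if not 0.0 < f2_threshold <= 100.0:
        raise ValueError("F2 threshold must lie in (0, 100]")
    kept: list[FcsFitResult] = []
    excluded: list[FcsFitResult] = []
    for r in results:
        over_cpp = cpp_threshold_khz is not None and r.cpp_khz > cpp_threshold_khz
        (excluded if r.f2 > f2_threshold or over_cpp else kept).append(r)
    if results and not kept:
        logger.warning("all %d results excluded as aggregates", len(results))
    return kept, excluded


def aggregate_repeats(
    results: list[FcsFitResult],
    timepoints: list,
    experiments: list | None = None,
    f2_exclusion_threshold: float | None = None,
    cpp_threshold_khz: float | None = None,
) -> list[RepeatAggregate]:
    """Aggregate technical repeats into per-timepoint fouling statistics.

    ``timepoints`` (and optionally ``experiments``) label each result.
    Within each timepoint: optionally exclude aggregate-dominated repeats,
    take the median F2 per independent experiment, then report the mean of
    those medians and their s.e.m. across experiments (s.e.m. = 0 for a
    single experiment).
    """
    if len(timepoints) != len(results):
        raise ValueError("timepoints must label every result")
    if experiments is None:
        experiments = [0] * len(results)
    if len(experiments) != len(results):
        raise ValueError("experiments must label every result")

    rule = "none"
    if f2_exclusion_threshold is not None:
        rule = f"F2 > {f2_exclusion_threshold:g}%"
        if cpp_threshold_khz is not None:
            rule += f" or CPP > {cpp_threshold_khz:g} kHz"

    def _keep(r: FcsFitResult) -> bool:
        if f2_exclusion_threshold is None:
            return True
        over_cpp = cpp_threshold_khz is not None and r.cpp_khz > cpp_threshold_khz
        return r.f2 <= f2_exclusion_threshold and not over_cpp

    out: list[RepeatAggregate] = []
    for tp in dict.fromkeys(timepoints):  # preserve first-seen order
        idx = [i for i, t in enumerate(timepoints) if t == tp]
        n_total = len(idx)
        kept_idx = [i for i in idx if _keep(results[i])]
        if not kept_idx:
            raise ValueError(f"timepoint {tp!r} has no usable repeats after exclusion")
        kept_ids = [experiments[i] for i in kept_idx]
        medians = []
        for exp in dict.fromkeys(kept_ids):
            vals = [results[i].f2 for i in kept_idx if experiments[i] == exp]
            medians.append(float(np.median(vals)))
        med_arr = np.array(medians)
        sem = float(np.std(med_arr, ddof=1) / np.sqrt(med_arr.size)) if med_arr.size > 1 else 0.0
        out.append(
            RepeatAggregate(
                timepoint=tp,
                median_f2=float(np.mean(med_arr)),
                sem_f2=sem,
                n_used=len(kept_idx),
                n_excluded=n_total - len(kept_idx),
                exclusion_rule=rule,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Curve CSV dialect: '#'-prefixed metadata lines then 'tau_s,G[,sigma_G]'.

def write_curve_csv(curve: CorrelationCurve, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# mean_count_rate_khz: {curve.mean_count_rate_khz}\n")
        fh.write(f"# duration_s: {curve.duration_s}\n")
        fh.write(f"# label: {curve.label}\n")
        has_sigma = curve.sigma_g is not None
        fh.write("tau_s,G,sigma_G\n" if has_sigma else "tau_s,G\n")
        for i in range(len(curve)):
            row = f"{curve.tau_s[i]:.9e},{curve.g[i]:.9e}"
            if has_sigma:
                row += f",{curve.sigma_g[i]:.9e}"
            fh.write(row + "\n")


def read_curve_csv(path: str | Path) -> CorrelationCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header: list[str] | None = None
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            elif header is None:
                header = [h.strip() for h in line.split(",")]
            else:
                rows.append([float(x) for x in line.split(",")])
    if header is None or not rows:
        raise ValueError(f"no curve data found in {path}")
    data = np.array(rows)
    sigma = data[:, 2] if len(header) > 2 else None
    return CorrelationCurve(
        tau_s=data[:, 0],
        g=data[:, 1],
        sigma_g=sigma,
        mean_count_rate_khz=float(meta.get("mean_count_rate_khz", 0.0)),
        duration_s=float(meta.get("duration_s", 0.0)),
        label=meta.get("label", path.stem),
    )
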