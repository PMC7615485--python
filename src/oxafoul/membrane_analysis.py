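"""Structural observables of polymer membrane slabs from labelled trajectories.

Works on orthorhombic slab trajectories whose atoms are tagged as PDMS
(hydrophobic core), PMOXA (hydrophilic brush) or WATER.  The analysis
produces the membrane-normal (z) cross-sectional mass-density profile per
component — with water split into interfacial (within a distance cutoff of
any PMOXA atom, evaluated per frame) and bulk — and the derived interface
metrics: membrane core thickness, interfacial water-layer thickness
(FWHM of the interfacial peak), the cross-over height where the PMOXA
density meets the bulk-water density, and the interfacial-water density
area under the curve.  PMOXA root-mean-square fluctuations quantify brush
dynamics after removing whole-membrane drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

AMU_PER_NM3_TO_KG_M3 = 1.66053906660  # 1 amu/nm^3 in kg/m^3

COMPONENTS = ("PDMS", "PMOXA", "WATER")

#: Default mapping of atom/residue names to membrane components.
DEFAULT_COMPONENT_MAP = {
    "PDMS": "PDMS",
    "DMS": "PDMS",
    "PMOXA": "PMOXA",
    "PMOX": "PMOXA",
    "MOXA": "PMOXA",
    "MOX": "PMOXA",
    "WATER": "WATER",
    "SOL": "WATER",
    "WAT": "WATER",
    "HOH": "WATER",
    "OW": "WATER",
    "W": "WATER",
}

#: Default pseudo-atom masses per component, amu: one bead per heavy atom
#: (DMS repeat 74.15/4, MOXA repeat 85.10/6, one water molecule).
DEFAULT_COMPONENT_MASSES = {"PDMS": 18.5375, "PMOXA": 14.1833, "WATER": 18.015}


@dataclass
class Trajectory:
    """Frames of labelled pseudo-atom coordinates in an orthorhombic box.

    ``frames`` has shape (n_frames, n_atoms, 3) in nm; ``box`` is per-frame
    (n_frames, 3) in nm; ``labels`` maps each atom to a component tag.
    Coordinates are wrapped into [0, box) on construction.
    """

    frames: np.ndarray
    labels: np.ndarray
    masses: np.ndarray
    box: np.ndarray
    normal_axis: int = 2

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.labels = np.asarray(self.labels)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        n_frames, n_atoms, _ = self.frames.shape
        if self.labels.shape != (n_atoms,):
            raise ValueError("labels must be one tag per atom")
        if self.masses.shape != (n_atoms,):
            raise ValueError("masses must be one value per atom")
        if self.box.shape == (3,):
            self.box = np.tile(self.box, (n_frames, 1))
        if self.box.shape != (n_frames, 3):
            raise ValueError("box must be per-frame (n_frames, 3) or constant (3,)")
        bad = set(np.unique(self.labels)) - set(COMPONENTS)
        if bad:
            raise ValueError(f"unknown component labels: {sorted(bad)}")
        # wrap into [0, box)
        self.frames = np.mod(self.frames, self.box[:, None, :])

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class DensityProfile:
    """Per-component mass density vs membrane-normal coordinate.

    ``rho`` / ``rho_sd`` map component names (``PDMS``, ``PMOXA``,
    ``WATER_INT``, ``WATER_BULK``) to mean and across-frame standard
    deviation in kg/m^3 on the membrane-centred grid ``z_centers_nm``.
    ``per_frame`` retains the frame-wise profiles for uncertainty
    propagation of derived metrics.
    """

    z_centers_nm: np.ndarray
    rho: dict
    rho_sd: dict
    bin_width_nm: float
    per_frame: dict = field(repr=False, default_factory=dict)

    def total_water(self) -> np.ndarray:
        return self.rho["WATER_INT"] + self.rho["WATER_BULK"]


@dataclass(frozen=True)
class InterfaceMetrics:
    """Interfacial-water observables of a membrane slab (all in nm except AUC)."""

    membrane_thickness_nm: float
    water_layer_thickness_nm: float
    crossover_height_nm: float
    interfacial_auc_kg_m3_nm: float
    per_leaflet: dict = field(default_factory=dict)
    uncertainties: dict = field(default_factory=dict)
    crossover_found: bool = True


@dataclass(frozen=True)
class RmsfResult:
    """Per-atom and selection-mean positional fluctuations, nm."""

    per_atom_nm: np.ndarray
    mean_over_selection_nm: float
    selection: str
    alignment: str = "membrane center-of-mass translation removed"


# ---------------------------------------------------------------------------
# Trajectory input/output (multi-frame XYZ in nm; GRO-style frames)

def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    component_map: dict | None = None,
    component_masses: dict | None = None,
    box_nm: tuple | None = None,
) -> Trajectory:
    """Read a multi-frame XYZ or GRO-style trajectory with component labels.

    XYZ files carry no box: ``box_nm`` must be given (coordinates in nm,
    name + x y z per atom line).  GRO frames carry their own box line.
    Atom/residue names are mapped to components via ``component_map``
    (defaults to :data:`DEFAULT_COMPONENT_MAP`); unmapped names raise with
    the list of offenders.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    cmap = dict(DEFAULT_COMPONENT_MAP)
    if component_map:
        cmap.update({k.upper(): v for k, v in component_map.items()})
    masses_by_comp = dict(DEFAULT_COMPONENT_MASSES)
    if component_masses:
        masses_by_comp.update(component_masses)

    if fmt == "xyz":
        if box_nm is None:
            raise ValueError("XYZ trajectories need an explicit box_nm")
        names, frames = _parse_xyz(path)
        box = np.asarray(box_nm, dtype=float)
    elif fmt == "gro":
        names, frames, box = _parse_gro(path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    unmapped = sorted({n for n in names if n.upper() not in cmap})
    if unmapped:
        raise ValueError(f"atom names not mapped to a component: {unmapped}")
    labels = np.array([cmap[n.upper()] for n in names])
    masses = np.array([masses_by_comp[lab] for lab in labels])
    return Trajectory(frames=np.asarray(frames), labels=labels, masses=masses, box=box)


def _parse_xyz(path: Path):
    names: list[str] | None = None
    frames = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"frame {frame_no}: bad atom-count line {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"frame {frame_no} truncated: {len(block)}/{n_atoms} atoms")
        frame_names, coords = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_no}: malformed atom line {ln!r}")
            frame_names.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise ValueError(f"frame {frame_no}: atom names differ from frame 0")
        frames.append(coords)
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return names, np.array(frames, dtype=float)


def _parse_gro(path: Path):
    names: list[str] | None = None
    frames, boxes = [], []
    with path.open() as fh:
        lines = fh.read().splitlines()
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ValueError(f"frame {frame_no} truncated: missing atom count")
        n_atoms = int(lines[i + 1].split()[0])
        end = i + 2 + n_atoms
        if end >= len(lines) + 1 or len(lines) < end + 1:
            raise ValueError(f"frame {frame_no} truncated")
        frame_names, coords = [], []
        for ln in lines[i + 2 : end]:
            # fixed columns: resid(5) resname(5) atomname(5) atomnum(5) x y z
            resname = ln[5:10].strip()
            frame_names.append(resname)
            coords.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
        box_parts = lines[end].split()
        if len(box_parts) < 3:
            raise ValueError(f"frame {frame_no}: missing box line")
        boxes.append([float(x) for x in box_parts[:3]])
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise ValueError(f"frame {frame_no}: residue names differ from frame 0")
        frames.append(coords)
        i = end + 1
        frame_no += 1
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return names, np.array(frames, dtype=float), np.array(boxes, dtype=float)


def write_xyz(traj: Trajectory, path: str | Path, comment: str = "") -> None:
    """Write a trajectory as multi-frame XYZ (component tag + nm coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment or f'frame {f}'}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.frames[f, a]
                fh.write(f"{traj.labels[a]} {x:.5f} {y:.5f} {z:.5f}\n")


def write_gro(traj: Trajectory, path: str | Path, title: str = "membrane slab") -> None:
    """Write a trajectory as concatenated GRO frames (nm, box line per frame)."""
    path = Path(path)
    resname = {"PDMS": "PDMS", "PMOXA": "PMOX", "WATER": "SOL"}
    atomname = {"PDMS": "C", "PMOXA": "C", "WATER": "OW"}
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{title}, frame {f}\n{traj.n_atoms}\n")
            for a in range(traj.n_atoms):
                lab = traj.labels[a]
                x, y, z = traj.frames[f, a]
                fh.write(
                    f"{(a % 99999) + 1:>5d}{resname[lab]:<5s}{atomname[lab]:>5s}"
                    f"{(a % 99999) + 1:>5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = traj.box[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# Density profiles

def density_profile(
    traj: Trajectory,
    bin_width_nm: float = 0.1,
    interfacial_cutoff_nm: float = 0.4,
    center: str = "pdms",
) -> DensityProfile:
    """Membrane-centred cross-sectional mass-density profile per component.

    Each frame is centred on the PDMS centre of mass along the membrane
    normal (``center="midplane"`` keeps the box mid-plane instead, for
    membrane-free fixtures); component masses are histogrammed into z bins
    and divided by the slab volume of each bin.  Water atoms within
    ``interfacial_cutoff_nm`` of any PMOXA atom (periodic 3D distance,
    per frame) count as interfacial water, the rest as bulk.  Means and
    across-frame standard deviations are returned.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    if center not in ("pdms", "midplane"):
        raise ValueError("center must be 'pdms' or 'midplane'")
    ax = traj.normal_axis
    is_pdms = traj.labels == "PDMS"
    if center == "pdms" and not np.any(is_pdms):
        raise ValueError("no PDMS atoms: cannot centre profile on the core")
    is_pmoxa = traj.labels == "PMOXA"
    is_water = traj.labels == "WATER"

    lz = float(traj.box[0, ax])
    n_bins = max(int(round(lz / bin_width_nm)), 1)
    bin_width_nm = lz / n_bins  # actual uniform width
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    comp_keys = ["PDMS", "PMOXA", "WATER_INT", "WATER_BULK"]
    per_frame = {k: np.zeros((traj.n_frames, n_bins)) for k in comp_keys}

    for f in range(traj.n_frames):
        box = traj.box[f]
        pos = traj.frames[f]
        z = pos[:, ax].copy()
        # centre on PDMS centre of mass (minimum-image along the normal)
        if center == "pdms":
            z_com = _periodic_com(z[is_pdms], traj.masses[is_pdms], box[ax])
        else:
            z_com = box[ax] / 2.0
        z_rel = np.mod(z - z_com + box[ax] / 2.0, box[ax]) - box[ax] / 2.0
        # rescale to the reference grid if the box breathes slightly
        if not math.isclose(box[ax], lz, rel_tol=1e-9):
            z_rel = z_rel * (lz / box[ax])

        lateral = [i for i in range(3) if i != ax]
        slab_volume = bin_width_nm * box[lateral[0]] * box[lateral[1]]

        interfacial = np.zeros(traj.n_atoms, dtype=bool)
        if np.any(is_water) and np.any(is_pmoxa):
            tree = cKDTree(np.mod(pos[is_pmoxa], box), boxsize=box)
            dist, _ = tree.query(np.mod(pos[is_water], box), k=1)
            interfacial[np.flatnonzero(is_water)[dist <= interfacial_cutoff_nm]] = True

        masks = {
            "PDMS": is_pdms,
            "PMOXA": is_pmoxa,
            "WATER_INT": is_water & interfacial,
            "WATER_BULK": is_water & ~interfacial,
        }
        for key, mask in masks.items():
            hist, _ = np.histogram(z_rel[mask], bins=edges, weights=traj.masses[mask])
            per_frame[key][f] = hist * AMU_PER_NM3_TO_KG_M3 / slab_volume

    rho = {k: per_frame[k].mean(axis=0) for k in comp_keys}
    rho_sd = {k: per_frame[k].std(axis=0, ddof=0) for k in comp_keys}
    return DensityProfile(
        z_centers_nm=centers,
        rho=rho,
        rho_sd=rho_sd,
        bin_width_nm=bin_width_nm,
        per_frame=per_frame,
    )


def _periodic_com(z: np.ndarray, masses: np.ndarray, lz: float) -> float:
    """Mass-weighted centre along a periodic coordinate (circular mean)."""
    theta = z * (2.0 * np.pi / lz)
    c = np.average(np.cos(theta), weights=masses)
    s = np.average(np.sin(theta), weights=masses)
    return float(np.arctan2(s, c) * lz / (2.0 * np.pi))


def _interp_crossing(z0, z1, y0, y1, level) -> float:
    if y1 == y0:
        return 0.5 * (z0 + z1)
    return z0 + (level - y0) * (z1 - z0) / (y1 - y0)


def membrane_thickness(profile: DensityProfile, rho_pdms: np.ndarray | None = None) -> float:
    """Core thickness: distance between the two z where the PDMS density
    crosses 50% of its plateau maximum (linear interpolation between bins)."""
    z = profile.z_centers_nm
    rho = profile.rho["PDMS"] if rho_pdms is None else rho_pdms
    peak = float(np.max(rho))
    if peak <= 0:
        raise ValueError("PDMS density is zero everywhere")
    # robust plateau level: median of near-maximal bins, insensitive to bin noise
    plateau = float(np.median(rho[rho >= 0.8 * peak]))
    half = plateau / 2.0
    i0 = int(np.argmax(rho))
    # walk outward from the plateau maximum to the first half-max crossing
    left = right = None
    for i in range(i0, 0, -1):
        if rho[i - 1] < half <= rho[i]:
            left = _interp_crossing(z[i], z[i - 1], rho[i], rho[i - 1], half)
            break
    for i in range(i0, len(z) - 1):
        if rho[i + 1] < half <= rho[i]:
            right = _interp_crossing(z[i], z[i + 1], rho[i], rho[i + 1], half)
            break
    if left is None or right is None:
        raise ValueError("PDMS density never falls below half of its plateau")
    return float(right - left)


def _leaflet_metrics(z, rho_int, rho_pmoxa, rho_bulk, sign: int):
    """FWHM, cross-over height and AUC for one leaflet (sign = +1 or -1)."""
    sel = (z * sign) >= 0
    zl = z[sel] * sign
    order = np.argsort(zl)
    zl = zl[order]
    ri = rho_int[sel][order]
    rp = rho_pmoxa[sel][order]
    rb = rho_bulk[sel][order]

    # FWHM of the interfacial-water peak
    if np.max(ri) <= 0:
        fwhm = 0.0
    else:
        ipk = int(np.argmax(ri))
        half = ri[ipk] / 2.0
        inner = zl[0]
        for i in range(ipk, 0, -1):
            if ri[i - 1] < half <= ri[i]:
                inner = _interp_crossing(zl[i], zl[i - 1], ri[i], ri[i - 1], half)
                break
        outer = zl[-1]
        for i in range(ipk, len(zl) - 1):
            if ri[i + 1] < half <= ri[i]:
                outer = _interp_crossing(zl[i], zl[i + 1], ri[i], ri[i + 1], half)
                break
        fwhm = float(abs(outer - inner))

    # innermost PMOXA / bulk-water intersection walking outward from the core
    crossover = math.nan
    diff = rp - rb
    started = False
    for i in range(len(zl) - 1):
        if diff[i] > 0:
            started = True
        if started and diff[i] > 0 >= diff[i + 1]:
            crossover = _interp_crossing(zl[i], zl[i + 1], diff[i], diff[i + 1], 0.0)
            break

    auc = float(np.trapezoid(ri, zl))
    return fwhm, crossover, auc


def interface_metrics(
    profile: DensityProfile,
    per_frame_uncertainty: bool = True,
) -> InterfaceMetrics:
    """Interfacial-water metrics from a density profile.

    Per leaflet: water-layer thickness = FWHM of the interfacial-water
    peak; cross-over height = |z| of the innermost intersection of the
    PMOXA and bulk-water densities walking outward from the core;
    interfacial AUC = trapezoidal integral of the interfacial-water
    density.  Leaflet values are averaged; across-frame standard
    deviations of the frame-wise metrics are reported as uncertainties.
    """
    z = profile.z_centers_nm
    thickness = membrane_thickness(profile)

    def _both_leaflets(ri, rp, rb):
        vals = [_leaflet_metrics(z, ri, rp, rb, s) for s in (+1, -1)]
        fwhm = float(np.mean([v[0] for v in vals]))
        cross_vals = [v[1] for v in vals if not math.isnan(v[1])]
        crossover = float(np.mean(cross_vals)) if cross_vals else math.nan
        auc = float(np.mean([v[2] for v in vals]))
        return fwhm, crossover, auc, vals

    fwhm, crossover, auc, leaflets = _both_leaflets(
        profile.rho["WATER_INT"], profile.rho["PMOXA"], profile.rho["WATER_BULK"]
    )
    if auc == 0.0:
        import logging

        logging.getLogger(__name__).warning("zero interfacial water: thickness and AUC are 0")

    uncertainties: dict = {}
    if per_frame_uncertainty and profile.per_frame:
        fw, co, au = [], [], []
        n_frames = profile.per_frame["WATER_INT"].shape[0]
        for f in range(n_frames):
            fw_f, co_f, au_f, _ = _both_leaflets(
                profile.per_frame["WATER_INT"][f],
                profile.per_frame["PMOXA"][f],
                profile.per_frame["WATER_BULK"][f],
            )
            fw.append(fw_f)
            co.append(co_f)
            au.append(au_f)
        uncertainties = {
            "water_layer_thickness_nm": float(np.nanstd(fw)),
            "crossover_height_nm": float(np.nanstd(co)),
            "interfacial_auc_kg_m3_nm": float(np.nanstd(au)),
        }

    return InterfaceMetrics(
        membrane_thickness_nm=thickness,
        water_layer_thickness_nm=fwhm,
        crossover_height_nm=crossover,
        interfacial_auc_kg_m3_nm=auc,
        per_leaflet={
            "water_layer_thickness_nm": (leaflets[0][0], leaflets[1][0]),
            "crossover_height_nm": (leaflets[0][1], leaflets[1][1]),
            "interfacial_auc_kg_m3_nm": (leaflets[0][2], leaflets[1][2]),
        },
        uncertainties=uncertainties,
        crossover_found=not math.isnan(crossover),
    )


# ---------------------------------------------------------------------------
# RMSF

def rmsf(traj: Trajectory, selection: str = "PMOXA") -> RmsfResult:
    """Root-mean-square fluctuation of a component about time-averaged positions.

    Whole-membrane (PDMS + PMOXA) centre-of-mass translation is removed
    per frame before computing, for each selected atom, the RMS deviation
    from its own time-averaged position.  Assumes the selection does not
    diffuse across the periodic boundary during the trajectory.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = traj.labels == selection
    if not np.any(sel):
        raise ValueError(f"selection {selection!r} matches no atoms")
    membrane = (traj.labels == "PDMS") | (traj.labels == "PMOXA")
    if not np.any(membrane):
        membrane = np.ones(traj.n_atoms, dtype=bool)

    # unwrap against the first frame (minimum image) so atoms fluctuating
    # across the periodic boundary do not register box-sized jumps
    box = traj.box[:, None, :]
    disp = traj.frames - traj.frames[0][None]
    disp -= box * np.round(disp / box)
    pos = traj.frames[0][None] + disp

    w = traj.masses[membrane]
    com = np.einsum("fam,a->fm", pos[:, membrane, :], w) / w.sum()
    pos = pos - com[:, None, :]

    x = pos[:, sel, :]
    mean_pos = x.mean(axis=0)
    disp2 = ((x - mean_pos[None]) ** 2).sum(axis=2)
    per_atom = np.sqrt(disp2.mean(axis=0))
    return RmsfResult(
        per_atom_nm=per_atom,
        mean_over_selection_nm=float(per_atom.mean()),
        selection=selection,
    )


def profile_to_csv(profile: DensityProfile, path: str | Path) -> None:
    """Write a density profile as CSV (z, per-component mean and sd columns)."""
    import pandas as pd

    cols = {"z_nm": profile.z_centers_nm}
    for key in ("PDMS", "PMOXA", "WATER_INT", "WATER_BULK"):
        cols[f"rho_{key}"] = profile.rho[key]
    for key in ("PDMS", "PMOXA", "WATER_INT", "WATER_BULK"):
        cols[f"rho_{key}_sd"] = profile.rho_sd[key]
    pd.DataFrame(cols).to_csv(path, index=False)
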