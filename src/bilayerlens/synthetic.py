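"""Synthetic data with known ground truth for every analysis stage.

Each generator emulates one experimental or simulation input — FRAP
recovery traces, two-phase microscopy images, single-peak emission spectra,
geometric bilayer snapshots, and 2-D Brownian lateral trajectories — and
records the generating parameters so downstream estimators can be validated
by round trip.  The bilayers are geometric/statistical stand-ins: no
force-field physics is attempted.

Defaults reflect the study conditions: 90 phospholipids + 30 steroids per
leaflet, pure-DOPC thickness 38.3 A and area per lipid 64 A^2, steroid ring
depth 8 A, experimental DOPC diffusion 1.74 um^2/s, FRAP bleach radius 5 um
(10 um diameter spot).

C-H bond orientations are drawn from a two-delta mixture {theta=0 with
weight p, theta=90 deg with weight 1-p}, p = (2*S+1)/3, whose expectation of
(3 cos^2 theta - 1)/2 is exactly the target S for any S in [-0.5, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frap as _frap
from .domains import Domain, DomainSet, MicroscopyImage
from .spectra import EmissionSpectrum
from .trajectory import Trajectory

__all__ = [
    "SyntheticFrapSpec",
    "SyntheticImageSpec",
    "SyntheticBilayerSpec",
    "SyntheticBrownianSpec",
    "make_frap_trace",
    "make_domain_image",
    "make_spectrum",
    "make_bilayer_trajectory",
    "make_brownian",
    "default_sch_targets",
    "write_trace_csv",
    "write_spectrum_csv",
    "write_truth_json",
]


def _default_time_grid() -> np.ndarray:
    return np.logspace(math.log10(0.1), math.log10(60.0), 120)


# ---------------------------------------------------------------------------
# FRAP


@dataclass
class SyntheticFrapSpec:
    amplitude_a: float = 0.9
    baseline_b: float = 0.1
    diffusion_um2_s: float = 1.74
    bleach_radius_um: float = 5.0
    time_grid_s: np.ndarray = field(default_factory=_default_time_grid)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_grid_s = np.asarray(self.time_grid_s, dtype=float)
        if self.amplitude_a < 0 or self.baseline_b < 0:
            raise ValueError("amplitude and baseline must be non-negative")
        if self.amplitude_a + self.baseline_b > 1.05:
            raise ValueError("a + b must not exceed 1.05")
        if self.diffusion_um2_s <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.bleach_radius_um <= 0:
            raise ValueError("bleach radius must be positive")
        if np.any(np.diff(self.time_grid_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.time_grid_s < 0):
            raise ValueError("times must be non-negative")


def make_frap_trace(spec: SyntheticFrapSpec) -> _frap.FrapTrace:
    """Noisy (or noiseless) modified-Soumpasis recovery trace with the
    generating parameters attached as ground truth."""
    tau_d = spec.bleach_radius_um**2 / (4.0 * spec.diffusion_um2_s)
    clean = _frap.recovery_model(spec.time_grid_s, spec.amplitude_a, spec.baseline_b, tau_d)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else clean
    return _frap.FrapTrace(
        spec.time_grid_s.copy(), noisy, spec.bleach_radius_um,
        label=f"synthetic(D={spec.diffusion_um2_s})",
        truth={
            "a": spec.amplitude_a, "b": spec.baseline_b,
            "tau_d_s": tau_d, "D_um2_s": spec.diffusion_um2_s,
            "w_um": spec.bleach_radius_um, "noise_sd": spec.noise_sd, "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# Two-phase domain images


@dataclass
class SyntheticImageSpec:
    width_px: int = 500
    height_px: int = 500
    pixel_size_um: float = 0.1
    domain_radii_um: tuple = ()
    domain_shapes: str = "disk"  # disk | ellipse | blob
    fg_level: float = 300.0
    bg_level: float = 3000.0
    noise_sd: float = 0.0
    seed: int = 0
    max_placement_tries: int = 2000

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if any(r <= 0 for r in self.domain_radii_um):
            raise ValueError("all domain radii must be positive")
        if self.domain_shapes not in ("disk", "ellipse", "blob"):
            raise ValueError(f"unknown shape {self.domain_shapes!r}")


def _shape_radius_fn(shape: str, r0: float, rng) -> tuple:
    """Return (r(phi) callable, bounding radius) for one domain outline."""
    if shape == "disk":
        return (lambda phi: np.full_like(phi, r0)), r0
    if shape == "ellipse":
        # 2:1 aspect, same area as a disk of radius r0, random orientation
        a, b = r0 * math.sqrt(2.0), r0 / math.sqrt(2.0)
        phi0 = rng.uniform(0, math.pi)
        def r(phi, a=a, b=b, phi0=phi0):
            c, s = np.cos(phi - phi0), np.sin(phi - phi0)
            return a * b / np.sqrt((b * c) ** 2 + (a * s) ** 2)
        return r, a
    # blob: low-order harmonic perturbation of a circle
    amps = rng.uniform(0.05, 0.15, size=3)
    phases = rng.uniform(0, 2 * math.pi, size=3)
    def r(phi, amps=amps, phases=phases, r0=r0):
        out = np.ones_like(phi)
        for k, (ak, pk) in enumerate(zip(amps, phases), start=2):
            out = out + ak * np.cos(k * phi + pk)
        return r0 * out
    return r, r0 * (1.0 + float(amps.sum()))


def make_domain_image(spec: SyntheticImageSpec) -> tuple[MicroscopyImage, DomainSet]:
    """Two-level image with non-overlapping dark domains on a bright
    background, plus the analytic ground-truth domain set."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    w_um, h_um = spec.width_px * px, spec.height_px * px
    margin = 2 * px

    placed: list[tuple[float, float, object, float]] = []  # (cx, cy, r_fn, r_bound)
    for i, r0 in enumerate(spec.domain_radii_um):
        r_fn, r_b = _shape_radius_fn(spec.domain_shapes, float(r0), rng)
        ok = False
        for _ in range(spec.max_placement_tries):
            cx = rng.uniform(r_b + margin, w_um - r_b - margin)
            cy = rng.uniform(r_b + margin, h_um - r_b - margin)
            if all(
                math.hypot(cx - qx, cy - qy) > r_b + q_rb + margin
                for qx, qy, _, q_rb in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place domain {i + 1}/{len(spec.domain_radii_um)} "
                f"without overlap ({len(placed)} placed)"
            )
        placed.append((cx, cy, r_fn, r_b))

    img = np.full((spec.height_px, spec.width_px), spec.bg_level, dtype=float)
    xs = (np.arange(spec.width_px) + 0.5) * px
    ys = (np.arange(spec.height_px) + 0.5) * px
    domains: list[Domain] = []
    phi_grid = np.linspace(0, 2 * math.pi, 4097)
    for did, (cx, cy, r_fn, r_b) in enumerate(placed, start=1):
        ix = np.flatnonzero(np.abs(xs - cx) <= r_b + px)
        iy = np.flatnonzero(np.abs(ys - cy) <= r_b + px)
        dx = xs[ix][None, :] - cx
        dy = ys[iy][:, None] - cy
        rho = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        inside = rho <= r_fn(phi)
        sub = img[np.ix_(iy, ix)]
        sub[inside] = spec.fg_level
        img[np.ix_(iy, ix)] = sub
        # analytic outline measures via dense quadrature
        r_phi = r_fn(phi_grid)
        area = 0.5 * float(np.trapezoid(r_phi**2, phi_grid))
        dr = np.gradient(r_phi, phi_grid)
        perim = float(np.trapezoid(np.sqrt(r_phi**2 + dr**2), phi_grid))
        domains.append(
            Domain(
                id=did, area_um2=area, perimeter_um=perim,
                circularity=min(4 * math.pi * area / perim**2, 1.0),
                equivalent_diameter_um=2 * math.sqrt(area / math.pi),
                centroid_um=(cx, cy), touches_border=False,
                area_px=int(np.count_nonzero(inside)),
            )
        )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = MicroscopyImage(img, px, channel="synthetic")
    truth = DomainSet(domains, px, provenance={"generator": "make_domain_image", "seed": spec.seed})
    return image, truth


# ---------------------------------------------------------------------------
# Emission spectra

DETECTOR_RANGE_NM = (300.0, 800.0)


def make_spectrum(
    center_nm: float,
    fwhm_nm: float = 40.0,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
    mol_percent: float | None = None,
    composition: str = "",
) -> EmissionSpectrum:
    """Single Gaussian emission peak plus optional additive noise (clipped
    at zero counts), with the generating centre recorded."""
    if grid is None:
        grid = np.arange(400.0, 550.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("wavelength grid needs at least 3 points")
    if grid.min() < DETECTOR_RANGE_NM[0] or grid.max() > DETECTOR_RANGE_NM[1]:
        raise ValueError("grid outside detector range 300-800 nm")
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    inten = np.exp(-0.5 * ((grid - center_nm) / sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = np.clip(inten + rng.normal(0.0, noise_sd, size=inten.shape), 0.0, None)
    if inten.sum() <= 0:
        raise ValueError("generated spectrum has zero intensity")
    return EmissionSpectrum(
        grid, inten, label=label or f"synthetic({center_nm} nm)",
        mol_percent=mol_percent, composition=composition,
        truth={"center_nm": center_nm, "fwhm_nm": fwhm_nm, "noise_sd": noise_sd, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Bilayer snapshots


def default_sch_targets() -> dict:
    """Realistic per-carbon order-parameter targets for an unsaturated
    (di-oleoyl) chain: moderate order at the top, a dip around the C9=C10
    double bond, decaying order toward the terminal methyl."""
    profile = {
        2: 0.20, 3: 0.21, 4: 0.20, 5: 0.19, 6: 0.18, 7: 0.16, 8: 0.12,
        9: 0.05, 10: 0.05, 11: 0.12, 12: 0.14, 13: 0.13, 14: 0.12,
        15: 0.10, 16: 0.08, 17: 0.04,
    }
    return {"sn1": dict(profile), "sn2": dict(profile)}


def chain_atom_names(chain: str, carbon: int) -> tuple[str, list[str]]:
    """CHARMM-style acyl-chain naming: sn-1 carbons C3n (H nX/Y), sn-2
    carbons C2n (H nR/S)."""
    if chain == "sn1":
        return f"C3{carbon}", [f"H{carbon}X", f"H{carbon}Y"]
    if chain == "sn2":
        return f"C2{carbon}", [f"H{carbon}R", f"H{carbon}S"]
    raise ValueError(f"unknown chain {chain!r}")


STEROID_RING_ATOMS = ("C3", "C8", "C10", "C13", "C16")
#: offsets (A) along the C3->C16 axis; equal-mass COM sits at the centre
_RING_OFFSETS = {"C3": -4.4, "C8": -1.1, "C10": 0.0, "C13": 1.1, "C16": 4.4}
_O3_OFFSET = -5.8  # C3-bound oxygen, 1.4 A beyond C3 toward the interface


@dataclass
class SyntheticBilayerSpec:
    n_phospholipid_per_leaflet: int = 90
    n_steroid_per_leaflet: int = 30
    box_xy_A: float | None = None  # derived from APL when omitted
    thickness_A: float = 38.3
    apl_A2: float = 64.0
    ring_depth_mean_A: float = 8.0
    ring_depth_sd_A: float = 0.5
    tilt_mode: str = "upright"  # upright | broad | fixed_angle
    tilt_angle_deg: float = 30.0
    tilt_broad_sd_deg: float = 25.0
    sch_targets: dict = field(default_factory=default_sch_targets)
    n_frames: int = 100
    frame_dt_ns: float = 1.0
    seed: int = 0
    phosphorus_sd_A: float = 1.0
    lateral_jitter_A: float = 0.5
    steroid_resname: str = "CHL"

    def __post_init__(self) -> None:
        if self.n_phospholipid_per_leaflet <= 0 or self.n_steroid_per_leaflet < 0:
            raise ValueError("molecule counts must be positive")
        if self.thickness_A <= 0 or self.apl_A2 <= 0:
            raise ValueError("thickness and APL must be positive")
        n_mol = self.n_phospholipid_per_leaflet + self.n_steroid_per_leaflet
        if self.box_xy_A is None:
            self.box_xy_A = math.sqrt(n_mol * self.apl_A2)
        if self.box_xy_A**2 < n_mol * self.apl_A2 - 1e-9:
            raise ValueError("box area smaller than n_per_leaflet * APL")
        if self.tilt_mode not in ("upright", "broad", "fixed_angle"):
            raise ValueError(f"unknown tilt mode {self.tilt_mode!r}")
        for chain, targets in self.sch_targets.items():
            for c, s in targets.items():
                if not -0.5 <= s <= 1.0:
                    raise ValueError(f"S_CH target out of [-0.5, 1] at {chain} C{c}: {s}")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _sample_ch_unit_vectors(rng, s_target: float, n: int) -> np.ndarray:
    """Two-delta mixture with exact expectation S of (3 cos^2 - 1)/2."""
    p = (2.0 * s_target + 1.0) / 3.0
    along = rng.random(n) < p
    out = np.zeros((n, 3))
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    out[along, 2] = signs[along]
    phi = rng.uniform(0, 2 * math.pi, size=n)
    out[~along, 0] = np.cos(phi[~along])
    out[~along, 1] = np.sin(phi[~along])
    return out


def make_bilayer_trajectory(spec: SyntheticBilayerSpec) -> Trajectory:
    """Geometric bilayer stand-in with prescribed thickness, APL, steroid
    ring depth/tilt, and per-carbon order-parameter targets.

    Per leaflet and frame: phosphorus z ~ Normal(+-thickness/2, sd);
    steroid ring centres at |z| ~ Normal(ring depth, sd) with the C3->C16
    axis set by the tilt mode (0 deg = outward normal); lateral positions on
    a jittered lattice at the prescribed APL.  Frames are statistically
    independent (no dynamics).
    """
    rng = np.random.default_rng(spec.seed)
    n_pl, n_st = spec.n_phospholipid_per_leaflet, spec.n_steroid_per_leaflet
    n_mol_leaflet = n_pl + n_st
    box_xy = float(spec.box_xy_A)
    half = spec.thickness_A / 2.0
    box_z = spec.thickness_A + 30.0

    # --- topology ------------------------------------------------------
    chains = {
        chain: sorted(targets) for chain, targets in spec.sch_targets.items()
    }
    names: list[str] = []
    resnames: list[str] = []
    mol_ids: list[int] = []
    masses: list[float] = []
    mol_records: list[tuple[str, int]] = []  # (kind, leaflet_sign) per molecule

    mol_id = 0
    for leaflet_sign in (1, -1):
        order = ["PL"] * n_pl + ["ST"] * n_st
        rng.shuffle(order)
        for kind in order:
            if kind == "PL":
                names.append("P")
                resnames.append("DOPC")
                mol_ids.append(mol_id)
                masses.append(30.974)
                for chain, carbons in chains.items():
                    for c in carbons:
                        cname, hnames = chain_atom_names(chain, c)
                        names.append(cname)
                        resnames.append("DOPC")
                        mol_ids.append(mol_id)
                        masses.append(12.011)
                        for h in hnames:
                            names.append(h)
                            resnames.append("DOPC")
                            mol_ids.append(mol_id)
                            masses.append(1.008)
            else:
                for a in STEROID_RING_ATOMS:
                    names.append(a)
                    resnames.append(spec.steroid_resname)
                    mol_ids.append(mol_id)
                    masses.append(12.011)
                names.append("O3")
                resnames.append(spec.steroid_resname)
                mol_ids.append(mol_id)
                masses.append(15.999)
            mol_records.append((kind, leaflet_sign))
            mol_id += 1

    n_atoms = len(names)
    n_mols = mol_id
    atom_mol = np.array(mol_ids)

    # base lattice per leaflet (shared across frames)
    side = math.ceil(math.sqrt(n_mol_leaflet))
    spacing = box_xy / side
    lattice = np.array(
        [[((i % side) + 0.5) * spacing, ((i // side) + 0.5) * spacing] for i in range(n_mol_leaflet)]
    )

    coords = np.zeros((spec.n_frames, n_atoms, 3))
    leaflet_atom = np.zeros(n_atoms, dtype=int)
    truth_depth = np.zeros((spec.n_frames, 2 * n_st))
    truth_tilt = np.zeros((spec.n_frames, 2 * n_st))

    # per-molecule atom index slices, built once
    mol_atom_idx = [np.flatnonzero(atom_mol == m) for m in range(n_mols)]
    for m, (kind, sign) in enumerate(mol_records):
        leaflet_atom[mol_atom_idx[m]] = sign

    ring_s = np.array([_RING_OFFSETS[a] for a in STEROID_RING_ATOMS])

    for f in range(spec.n_frames):
        st_counter = 0
        for leaflet_i, sign in enumerate((1, -1)):
            mols = [m for m in range(n_mols) if mol_records[m][1] == sign]
            lat = lattice + rng.normal(0.0, spec.lateral_jitter_A, size=(n_mol_leaflet, 2))
            lat %= box_xy
            for j, m in enumerate(mols):
                idx = mol_atom_idx[m]
                kind = mol_records[m][0]
                x0, y0 = lat[j]
                if kind == "PL":
                    k = 0
                    pz = sign * (half + rng.normal(0.0, spec.phosphorus_sd_A))
                    coords[f, idx[k]] = (x0, y0, pz)
                    k += 1
                    for ci, (chain, carbons) in enumerate(chains.items()):
                        xo = x0 + (ci - 0.5) * 1.0
                        for c in carbons:
                            cz = sign * max(half - 3.0 - (c - 2) * 0.9, 0.5)
                            cpos = np.array([xo, y0, cz])
                            coords[f, idx[k]] = cpos
                            k += 1
                            u = _sample_ch_unit_vectors(
                                rng, spec.sch_targets[chain][c], 2
                            )
                            coords[f, idx[k]] = cpos + 1.09 * u[0]
                            coords[f, idx[k + 1]] = cpos + 1.09 * u[1]
                            k += 2
                else:
                    depth = rng.normal(spec.ring_depth_mean_A, spec.ring_depth_sd_A)
                    centre = np.array([x0, y0, sign * depth])
                    if spec.tilt_mode == "upright":
                        theta = 0.0
                    elif spec.tilt_mode == "fixed_angle":
                        theta = math.radians(spec.tilt_angle_deg)
                    else:
                        theta = min(
                            abs(rng.normal(0.0, math.radians(spec.tilt_broad_sd_deg))),
                            math.radians(89.0),
                        )
                    phi = rng.uniform(0, 2 * math.pi)
                    # 0 tilt = outward normal (leaflet-corrected convention)
                    axis = np.array(
                        [
                            math.sin(theta) * math.cos(phi),
                            math.sin(theta) * math.sin(phi),
                            sign * math.cos(theta),
                        ]
                    )
                    pos = centre[None, :] + ring_s[:, None] * axis[None, :]
                    coords[f, idx[:5]] = pos
                    coords[f, idx[5]] = centre + _O3_OFFSET * axis
                    truth_depth[f, st_counter] = depth
                    truth_tilt[f, st_counter] = math.degrees(theta)
                    st_counter += 1

    box = np.tile(np.array([box_xy, box_xy, box_z]), (spec.n_frames, 1))
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_dt_ns * 1000.0
    truth = {
        "thickness_A": spec.thickness_A,
        "apl_A2": spec.apl_A2,
        "box_xy_A": box_xy,
        "ring_depth_mean_A": spec.ring_depth_mean_A,
        "ring_depth_sd_A": spec.ring_depth_sd_A,
        "ring_depths_A": truth_depth,
        "tilt_deg": truth_tilt,
        "tilt_mode": spec.tilt_mode,
        "sch_targets": spec.sch_targets,
        "leaflet_by_molecule": {m: s for m, (_, s) in enumerate(mol_records)},
        "seed": spec.seed,
    }
    return Trajectory(
        atom_names=np.array(names), resnames=np.array(resnames),
        molecule_ids=np.array(mol_ids), masses=np.array(masses),
        coords=coords, box=box, times_ps=times,
        leaflet=leaflet_atom, truth=truth,
    )


# ---------------------------------------------------------------------------
# Brownian lateral trajectories


@dataclass
class SyntheticBrownianSpec:
    n_particles: int = 240
    diffusion_um2_s: float = 2.6
    frame_dt_ns: float = 1.0
    n_frames: int = 100
    box_xy_A: float = 89.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_um2_s < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.n_particles < 1 or self.box_xy_A <= 0:
            raise ValueError("invalid particle count or box")


#: 1 um^2/s expressed in A^2/ns
UM2_S_TO_A2_NS = 0.1


def make_brownian(spec: SyntheticBrownianSpec) -> Trajectory:
    """Independent 2-D Brownian walkers in a periodic box.

    Generated in unwrapped space (increments i.i.d. Gaussian with variance
    2*D*dt per axis) and wrapped afterwards, so the unwrapped coordinates
    make the MSD oracle exact: MSD_xy(t) = 4*D*t.
    """
    rng = np.random.default_rng(spec.seed)
    d_a2ns = spec.diffusion_um2_s * UM2_S_TO_A2_NS
    sd = math.sqrt(2.0 * d_a2ns * spec.frame_dt_ns)
    n, t = spec.n_particles, spec.n_frames
    start = rng.uniform(0.0, spec.box_xy_A, size=(1, n, 2))
    steps = rng.normal(0.0, sd, size=(t - 1, n, 2)) if sd > 0 else np.zeros((t - 1, n, 2))
    xy = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    unwrapped = np.zeros((t, n, 3))
    unwrapped[:, :, :2] = xy
    unwrapped[:, :, 2] = 5.0
    wrapped = unwrapped.copy()
    wrapped[:, :, :2] %= spec.box_xy_A
    box = np.tile(np.array([spec.box_xy_A, spec.box_xy_A, 10.0]), (t, 1))
    return Trajectory(
        atom_names=np.array(["P"] * n),
        resnames=np.array(["LIP"] * n),
        molecule_ids=np.arange(n),
        masses=np.full(n, 30.974),
        coords=wrapped, box=box,
        times_ps=np.arange(t, dtype=float) * spec.frame_dt_ns * 1000.0,
        unwrapped=unwrapped,
        truth={"D_um2_s": spec.diffusion_um2_s, "frame_dt_ns": spec.frame_dt_ns, "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# Writers


def write_trace_csv(trace: _frap.FrapTrace, path) -> None:
    """FRAP trace as a raw-style CSV (constant unit reference; first row is
    the pre-bleach level, as read back by :func:`bilayerlens.frap.read_trace_csv`)."""
    time = np.concatenate([[-1.0], trace.time_s])
    bleach = np.concatenate([[1.0], trace.intensity_norm])
    ref = np.ones_like(time)
    pd.DataFrame(
        {"time_s": time, "bleach_intensity": bleach, "reference_intensity": ref}
    ).to_csv(path, index=False)


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelength_nm,
            "intensity": spectrum.intensity,
            "label": spectrum.label,
            "mol_percent": spectrum.mol_percent,
            "composition": spectrum.composition,
        }
    ).to_csv(path, index=False)


def write_truth_json(truth: dict, path) -> None:
    def _clean(o):
        if isinstance(o, dict):
            return {str(k): _clean(v) for k, v in o.items()}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        return o

    Path(path).write_text(json.dumps(_clean(truth), indent=2) + "\n")
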