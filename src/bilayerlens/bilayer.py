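"""Structural analysis of lipid-bilayer trajectories.

Operations, all on the :class:`~bilayerlens.trajectory.Trajectory`
container (coordinates in Angstrom, z along the membrane normal):

- leaflet assignment and midplane centring from the bimodal phosphorus
  z distribution;
- partial density profiles along z (atom selections or steroid ring
  centres, the equal-weight centre of the C3/C8/C10/C13/C16 scaffold);
- membrane thickness as the peak-to-peak distance of the per-leaflet
  phosphorus density maxima, refined by parabolic interpolation;
- steroid tilt: angle between the C3->C16 ring axis and the outward
  leaflet normal, with paired ring-centre depth for joint histograms;
- C-H order parameter S_CH = <(3 cos^2 theta - 1)/2> per carbon with a
  5-block standard error, and per-carbon differences with quadrature
  error propagation;
- area per lipid by periodic 2-D Voronoi tessellation of projected
  reference atoms (phosphorus for phospholipids, the C3-bound oxygen for
  steroids), per leaflet and frame;
- lateral mean-square displacement with a linear fit D = slope/4 on a
  configurable lag window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Voronoi

from .trajectory import Trajectory

__all__ = [
    "DensityProfile",
    "TiltDistribution",
    "OrderProfile",
    "APLResult",
    "MSDSeries",
    "assign_leaflets_and_center",
    "partial_density_profile",
    "ring_center_profile",
    "profile_peak",
    "membrane_thickness",
    "ring_tilt_angles",
    "joint_tilt_depth",
    "order_parameter_profile",
    "delta_order",
    "dopc_chain_definitions",
    "voronoi_apl",
    "periodic_voronoi_areas",
    "msd_diffusion",
    "A2_NS_TO_UM2_S",
]

#: 1 A^2/ns expressed in um^2/s
A2_NS_TO_UM2_S = 10.0


# ---------------------------------------------------------------------------
# Leaflets and centring


def assign_leaflets_and_center(
    traj: Trajectory, phosphorus: tuple[str, str] = ("DOPC", "P")
) -> Trajectory:
    """Centre the midplane at z = 0 and tag every molecule upper/lower.

    The phosphorus z values of each frame are split into two groups by a
    two-means partition; a clearly bimodal split (inter-group gap larger
    than the pooled within-group spread) is required, otherwise the input
    is rejected as not being a bilayer.  Each frame is shifted so the
    midpoint of the two leaflet phosphorus levels sits at z = 0, then all
    molecules are tagged by the z sign of their first atom.
    """
    p_mask = traj.select(*phosphorus)
    if not p_mask.any():
        raise ValueError(f"no phosphorus atoms matching {phosphorus}")
    pz_all = traj.coords[:, p_mask, 2]

    shifts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        pz = np.sort(pz_all[f])
        # two-means split over sorted values: best split minimises within-group SS
        cum = np.cumsum(pz)
        total = cum[-1]
        n = pz.size
        ks = np.arange(1, n)
        m1 = cum[:-1] / ks
        m2 = (total - cum[:-1]) / (n - ks)
        ss = (
            np.array([np.sum((pz[:k] - m1[k - 1]) ** 2) for k in ks])
            + np.array([np.sum((pz[k:] - m2[k - 1]) ** 2) for k in ks])
        )
        k = int(ks[np.argmin(ss)])
        lower, upper = pz[:k], pz[k:]
        if lower.size == 0 or upper.size == 0:
            raise ValueError("phosphorus distribution is unimodal: not a bilayer")
        gap = upper.mean() - lower.mean()
        spread = math.sqrt((np.var(lower) + np.var(upper)) / 2.0) + 1e-12
        if gap < 4.0 * spread:
            raise ValueError(
                "phosphorus distribution is unimodal: not a bilayer "
                f"(gap {gap:.2f} A vs spread {spread:.2f} A)"
            )
        shifts[f] = -(upper.mean() + lower.mean()) / 2.0

    centered = traj.translated_z(shifts)
    # leaflet tag by reference-atom z sign (first atom of each molecule)
    mol_ids = np.asarray(centered.molecule_ids)
    first_idx = np.unique(mol_ids, return_index=True)[1]
    leaflet_mol = np.sign(centered.coords[0, first_idx, 2]).astype(int)
    leaflet_mol[leaflet_mol == 0] = 1
    lookup = dict(zip(np.unique(mol_ids), leaflet_mol))
    centered.leaflet = np.array([lookup[m] for m in mol_ids])
    return centered


# ---------------------------------------------------------------------------
# Density profiles and thickness


@dataclass
class DensityProfile:
    z_centers_A: np.ndarray
    density: np.ndarray  # count (or mass) per A^3, frame-averaged
    counts: np.ndarray  # raw summed histogram counts
    selection: str
    bin_width_A: float
    n_frames: int
    box_area_A2: float


def _histogram_profile(
    z: np.ndarray, weights, bin_width: float, selection: str,
    n_frames: int, box_area: float,
) -> DensityProfile:
    zmax = float(np.max(np.abs(z))) + 3 * bin_width
    n_half = int(math.ceil(zmax / bin_width))
    edges = np.arange(-n_half, n_half + 1) * bin_width
    counts, _ = np.histogram(z, bins=edges, weights=weights)
    centers = (edges[:-1] + edges[1:]) / 2.0
    density = counts / (n_frames * box_area * bin_width)
    return DensityProfile(
        z_centers_A=centers, density=density, counts=counts.astype(float),
        selection=selection, bin_width_A=bin_width, n_frames=n_frames,
        box_area_A2=box_area,
    )


def partial_density_profile(
    traj: Trajectory,
    resname: str | None = None,
    name: str | None = None,
    bin_width_A: float = 0.5,
    mass_weighted: bool = False,
) -> DensityProfile:
    """Frame-averaged z histogram of an atom selection, normalised per bin
    volume.  The trajectory should be centred first."""
    mask = traj.select(resname=resname, name=name)
    if not mask.any():
        raise ValueError(f"empty selection resname={resname} name={name}")
    z = traj.coords[:, mask, 2].ravel()
    weights = None
    if mass_weighted:
        weights = np.tile(np.asarray(traj.masses, dtype=float)[mask], traj.n_frames)
    box_area = float(np.mean(traj.box[:, 0] * traj.box[:, 1]))
    label = f"{resname or '*'}:{name or '*'}"
    return _histogram_profile(z, weights, bin_width_A, label, traj.n_frames, box_area)


def _ring_centers(traj: Trajectory, resname: str) -> np.ndarray:
    """(n_frames, n_steroids, 3) equal-weight centres of the five ring atoms."""
    from .synthetic import STEROID_RING_ATOMS

    res_mask = traj.select(resname=resname)
    if not res_mask.any():
        raise ValueError(f"no molecules with resname {resname!r}")
    mols = np.unique(np.asarray(traj.molecule_ids)[res_mask])
    per_atom = []
    for a in STEROID_RING_ATOMS:
        mask = traj.select(resname=resname, name=a)
        idx_by_mol = {m: i for i, m in zip(np.flatnonzero(mask),
                                           np.asarray(traj.molecule_ids)[mask])}
        missing = [m for m in mols if m not in idx_by_mol]
        if missing:
            raise ValueError(f"molecule {missing[0]} lacks ring atom {a}")
        per_atom.append([idx_by_mol[m] for m in mols])
    idx = np.array(per_atom)  # (5, n_steroids)
    return traj.coords[:, idx, :].mean(axis=1)


def ring_center_profile(
    traj: Trajectory, resname: str, bin_width_A: float = 0.5
) -> DensityProfile:
    """Density profile of steroid ring centres (COM of C3, C8, C10, C13,
    C16) along z."""
    centers = _ring_centers(traj, resname)
    box_area = float(np.mean(traj.box[:, 0] * traj.box[:, 1]))
    return _histogram_profile(
        centers[:, :, 2].ravel(), None, bin_width_A,
        f"{resname}:ring-center", traj.n_frames, box_area,
    )


def profile_peak(profile: DensityProfile, z_range: tuple[float, float]) -> float:
    """Location of the density maximum inside ``z_range``.

    Refined by 3-point parabolic interpolation through the peak bin and its
    neighbours, performed on log counts when all three are positive (exact
    for a Gaussian peak) and on linear counts otherwise.
    """
    mask = (profile.z_centers_A >= z_range[0]) & (profile.z_centers_A <= z_range[1])
    if not mask.any():
        raise ValueError("z_range selects no bins")
    z = profile.z_centers_A[mask]
    c = profile.counts[mask]
    if np.ptp(c) == 0:
        raise ValueError("flat profile: no density maximum")
    i = int(np.argmax(c))
    if i == 0 or i == c.size - 1:
        return float(z[i])
    y = c[i - 1 : i + 2]
    if np.all(y > 0):
        y = np.log(y)
    denom = y[0] - 2 * y[1] + y[2]
    if denom >= 0:
        return float(z[i])
    delta = 0.5 * (y[0] - y[2]) / denom
    return float(z[i] + delta * profile.bin_width_A)


def membrane_thickness(p_profile: DensityProfile) -> float:
    """Peak-to-peak distance (A) between the per-leaflet phosphorus
    density maxima — the headgroup-to-headgroup bilayer thickness."""
    zmax = float(np.max(np.abs(p_profile.z_centers_A)))
    upper = profile_peak(p_profile, (0.0, zmax))
    lower = profile_peak(p_profile, (-zmax, 0.0))
    if upper <= 0 or lower >= 0:
        raise ValueError("could not locate one density maximum per leaflet")
    return float(upper - lower)


# ---------------------------------------------------------------------------
# Steroid tilt


@dataclass
class TiltDistribution:
    theta_deg: np.ndarray  # flat samples over steroids and frames
    ring_z_A: np.ndarray  # paired ring-centre z
    resname: str
    folded: bool = False
    convention: str = "angle to outward leaflet normal, [0, 180) deg"

    def fold(self) -> "TiltDistribution":
        """Fold to [0, 90] deg (axis orientation without direction)."""
        t = np.minimum(self.theta_deg, 180.0 - self.theta_deg)
        return TiltDistribution(
            t, self.ring_z_A.copy(), self.resname, folded=True,
            convention="angle to outward leaflet normal, folded to [0, 90] deg",
        )

    def histogram(self, bin_width_deg: float = 2.0):
        hi = 90.0 if self.folded else 180.0
        edges = np.arange(0.0, hi + bin_width_deg, bin_width_deg)
        counts, edges = np.histogram(self.theta_deg, bins=edges)
        return counts / counts.sum(), edges


def ring_tilt_angles(traj: Trajectory, resname: str) -> TiltDistribution:
    """Tilt angle of every steroid in every frame.

    theta is the angle between the C3->C16 ring axis and the *outward*
    leaflet normal (+z upper, -z lower), so an upright steroid reads ~0 deg
    in both leaflets.  Requires leaflet tags (run
    :func:`assign_leaflets_and_center` first, or generator tags).
    """
    res_mask = traj.select(resname=resname)
    if not res_mask.any():
        raise ValueError(f"no molecules with resname {resname!r}")
    mols = np.unique(np.asarray(traj.molecule_ids)[res_mask])

    def atom_index(atom: str) -> np.ndarray:
        mask = traj.select(resname=resname, name=atom)
        by_mol = {m: i for i, m in zip(np.flatnonzero(mask),
                                       np.asarray(traj.molecule_ids)[mask])}
        missing = [m for m in mols if m not in by_mol]
        if missing:
            raise ValueError(f"steroid molecule {missing[0]} is missing atom {atom}")
        return np.array([by_mol[m] for m in mols])

    i3, i16 = atom_index("C3"), atom_index("C16")
    if traj.leaflet is None:
        raise ValueError("trajectory has no leaflet tags; centre it first")
    signs = traj.leaflet[i3].astype(float)

    vec = traj.coords[:, i16, :] - traj.coords[:, i3, :]  # (F, S, 3)
    norm = np.linalg.norm(vec, axis=2)
    cos = vec[:, :, 2] * signs[None, :] / norm
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    centers = _ring_centers(traj, resname)
    return TiltDistribution(
        theta_deg=theta.ravel(), ring_z_A=centers[:, :, 2].ravel(), resname=resname
    )


def joint_tilt_depth(
    tilts: TiltDistribution,
    theta_bins: int = 36,
    z_bins: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised joint histogram P(theta, ring z); marginalising either
    axis reproduces the corresponding 1-D histogram by construction."""
    if tilts.theta_deg.size == 0:
        raise ValueError("no tilt samples")
    hist, te, ze = np.histogram2d(
        tilts.theta_deg, tilts.ring_z_A, bins=[theta_bins, z_bins]
    )
    return hist / hist.sum(), te, ze


# ---------------------------------------------------------------------------
# Order parameters


@dataclass
class OrderProfile:
    chain: str
    carbons: np.ndarray
    s_ch: np.ndarray
    stderr: np.ndarray
    n_samples: np.ndarray
    n_blocks: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chain": self.chain, "carbon": self.carbons, "S_CH": self.s_ch,
             "stderr": self.stderr, "n": self.n_samples}
        )


def dopc_chain_definitions(carbons=range(2, 18)) -> dict:
    """Default chain/atom-naming map matching the synthetic generator's
    CHARMM-style names: {chain: {carbon: (C name, [H names])}}."""
    from .synthetic import chain_atom_names

    return {
        chain: {c: chain_atom_names(chain, c) for c in carbons}
        for chain in ("sn1", "sn2")
    }


def order_parameter_profile(
    traj: Trajectory,
    chain_definitions: dict | None = None,
    resname: str = "DOPC",
    n_blocks: int = 5,
) -> dict[str, OrderProfile]:
    """S_CH(carbon) = <(3 cos^2 theta - 1)/2> over all equivalent C-H bonds,
    molecules, leaflets and frames; theta measured to the bilayer normal (z).

    The standard error per carbon comes from block averaging over
    ``n_blocks`` consecutive equal frame segments.
    """
    if chain_definitions is None:
        chain_definitions = dopc_chain_definitions()
    mol_of = np.asarray(traj.molecule_ids)
    out: dict[str, OrderProfile] = {}
    n_frames = traj.n_frames
    block_edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)

    for chain, cdef in chain_definitions.items():
        carbons = np.array(sorted(cdef))
        s_vals, errs, ns = [], [], []
        for c in carbons:
            cname, hnames = cdef[c]
            c_mask = traj.select(resname=resname, name=cname)
            if not c_mask.any():
                raise ValueError(f"no atoms named {cname} in {resname}")
            c_by_mol = {m: i for i, m in zip(np.flatnonzero(c_mask), mol_of[c_mask])}
            mols = sorted(c_by_mol)
            c_idx = np.array([c_by_mol[m] for m in mols])
            pair_cos2 = []  # per H: (F, n_mols) cos^2
            for h in hnames:
                h_mask = traj.select(resname=resname, name=h)
                h_by_mol = {m: i for i, m in zip(np.flatnonzero(h_mask), mol_of[h_mask])}
                missing = [m for m in mols if m not in h_by_mol]
                if missing:
                    raise ValueError(
                        f"carbon {cname} of molecule {missing[0]} has no hydrogen {h}"
                    )
                h_idx = np.array([h_by_mol[m] for m in mols])
                v = traj.coords[:, h_idx, :] - traj.coords[:, c_idx, :]
                cos2 = (v[:, :, 2] / np.linalg.norm(v, axis=2)) ** 2
                pair_cos2.append(cos2)
            s_frame = 0.5 * (3.0 * np.stack(pair_cos2).mean(axis=0) - 1.0)  # (F, M)
            s_vals.append(float(s_frame.mean()))
            block_means = [
                float(s_frame[block_edges[b]: block_edges[b + 1]].mean())
                for b in range(n_blocks)
                if block_edges[b + 1] > block_edges[b]
            ]
            if len(block_means) > 1:
                errs.append(float(np.std(block_means, ddof=1) / math.sqrt(len(block_means))))
            else:
                errs.append(float("nan"))
            ns.append(int(s_frame.size * len(hnames)))
        out[chain] = OrderProfile(
            chain=chain, carbons=carbons, s_ch=np.array(s_vals),
            stderr=np.array(errs), n_samples=np.array(ns), n_blocks=n_blocks,
        )
    return out


def delta_order(profile: OrderProfile, reference: OrderProfile) -> OrderProfile:
    """Per-carbon difference profile with errors added in quadrature."""
    if not np.array_equal(profile.carbons, reference.carbons):
        raise ValueError("carbon index sets differ between profiles")
    return OrderProfile(
        chain=profile.chain,
        carbons=profile.carbons.copy(),
        s_ch=profile.s_ch - reference.s_ch,
        stderr=np.sqrt(profile.stderr**2 + reference.stderr**2),
        n_samples=np.minimum(profile.n_samples, reference.n_samples),
        n_blocks=profile.n_blocks,
    )


# ---------------------------------------------------------------------------
# Voronoi area per lipid


@dataclass
class APLResult:
    per_class: dict  # class -> {mean, sd, n}
    per_leaflet_sums: np.ndarray  # (n_frames, 2) total tessellated area
    box_area_A2: np.ndarray  # (n_frames,)
    reference_atoms: dict
    perturbed: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": k, "mean_A2": v["mean"], "sd_A2": v["sd"], "n": v["n"]}
            for k, v in self.per_class.items()
        ]
        return pd.DataFrame(rows)


def periodic_voronoi_areas(points_xy: np.ndarray, box_xy: tuple[float, float]) -> np.ndarray:
    """Cell areas of a periodic 2-D Voronoi tessellation.

    The points are wrapped into the box and tiled 3x3; the central copies'
    cells are then finite and exactly the periodic cells for an
    orthorhombic box.  Areas by the shoelace formula.
    """
    pts = np.asarray(points_xy, dtype=float).copy()
    n = pts.shape[0]
    if n < 1:
        raise ValueError("no points to tessellate")
    lx, ly = box_xy
    pts[:, 0] %= lx
    pts[:, 1] %= ly
    offsets = [(dx * lx, dy * ly) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    tiled = np.concatenate([pts + np.array(o) for o in offsets])
    central_start = offsets.index((0.0, 0.0)) * n
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[central_start + i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded central Voronoi cell (degenerate input)")
        verts = vor.vertices[region]
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


DEFAULT_APL_REFERENCES = {"DOPC": "P", "CHL": "O3", "PRG": "O3"}


def voronoi_apl(
    traj: Trajectory,
    reference_atoms: dict | None = None,
    jitter_A: float = 1e-6,
) -> APLResult:
    """Per-lipid areas from independent per-leaflet periodic Voronoi
    tessellations of the projected reference atoms.

    Phospholipids are represented by their phosphorus, steroids by the
    C3-bound oxygen — both near the lipid-water interface, minimising the
    systematic difference between molecule classes.  Coincident projected
    points are perturbed by ``jitter_A`` and flagged.
    """
    if reference_atoms is None:
        reference_atoms = {
            r: DEFAULT_APL_REFERENCES[r]
            for r in np.unique(np.asarray(traj.resnames))
            if r in DEFAULT_APL_REFERENCES
        }
    if not reference_atoms:
        raise ValueError("no reference atoms for any residue class")
    if traj.leaflet is None:
        raise ValueError("trajectory has no leaflet tags; centre it first")

    idx_list, cls_list = [], []
    for res, atom in reference_atoms.items():
        mask = traj.select(resname=res, name=atom)
        if not mask.any():
            raise ValueError(f"no reference atom {atom} for class {res}")
        idx_list.append(np.flatnonzero(mask))
        cls_list += [res] * int(mask.sum())
    idx = np.concatenate(idx_list)
    classes = np.array(cls_list)
    leaf = traj.leaflet[idx]

    per_class_vals: dict[str, list] = {c: [] for c in reference_atoms}
    sums = np.zeros((traj.n_frames, 2))
    perturbed = False
    rng = np.random.default_rng(0)
    for f in range(traj.n_frames):
        box = (float(traj.box[f, 0]), float(traj.box[f, 1]))
        for li, sign in enumerate((1, -1)):
            sel = leaf == sign
            pts = traj.coords[f, idx[sel], :2]
            # guard against exactly coincident projections
            rounded = np.round(pts / max(jitter_A, 1e-12)).astype(np.int64)
            if len(np.unique(rounded, axis=0)) < len(pts):
                pts = pts + rng.normal(0.0, max(jitter_A, 1e-9), size=pts.shape)
                perturbed = True
            areas = periodic_voronoi_areas(pts, box)
            sums[f, li] = areas.sum()
            for c in reference_atoms:
                per_class_vals[c].append(areas[classes[sel] == c])

    per_class = {}
    all_vals = []
    for c, chunks in per_class_vals.items():
        vals = np.concatenate([v for v in chunks if v.size]) if chunks else np.array([])
        if vals.size:
            per_class[c] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
            }
            all_vals.append(vals)
    allv = np.concatenate(all_vals)
    per_class["all"] = {
        "mean": float(allv.mean()), "sd": float(allv.std(ddof=1)), "n": int(allv.size)
    }
    return APLResult(
        per_class=per_class, per_leaflet_sums=sums,
        box_area_A2=traj.box[:, 0] * traj.box[:, 1],
        reference_atoms=dict(reference_atoms), perturbed=perturbed,
    )


# ---------------------------------------------------------------------------
# MSD diffusion


@dataclass
class MSDSeries:
    lag_ns: np.ndarray
    msd_A2: np.ndarray
    fit_window_ns: tuple[float, float]
    diffusion_um2_s: float
    slope_A2_ns: float
    slope_stderr_A2_ns: float
    intercept_A2: float
    n_particles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ns": self.lag_ns, "msd_A2": self.msd_A2})


def _unwrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Reconstruct continuous trajectories from wrapped coordinates by
    minimum-image unwrapping of successive displacements."""
    disp = np.diff(coords, axis=0)
    L = box[1:, None, :]
    disp -= np.round(disp / L) * L
    out = np.concatenate([coords[:1], coords[:1] + np.cumsum(disp, axis=0)])
    return out


def msd_diffusion(
    traj: Trajectory,
    resname: str | None = None,
    name: str | None = None,
    fit_window_ns: tuple[float, float] = (30.0, 70.0),
    max_lag_frames: int | None = None,
    remove_com_drift: bool = False,
) -> MSDSeries:
    """Lateral MSD averaged over particles and all time origins, with
    D = slope/4 from an unweighted linear fit on ``fit_window_ns``.

    Uses stored unwrapped coordinates when present, otherwise reconstructs
    them from wrapped coordinates and the box (valid when no particle moves
    more than half a box length between frames).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for an MSD")
    mask = traj.select(resname=resname, name=name)
    if not mask.any():
        raise ValueError("empty selection for MSD")
    if traj.unwrapped is not None:
        u = traj.unwrapped[:, mask, :2]
    else:
        u = _unwrap(traj.coords[:, mask, :], traj.box)[:, :, :2]
    if remove_com_drift:
        u = u - u.mean(axis=1, keepdims=True)
    times_ns = traj.times_ps / 1000.0
    dt = float(np.mean(np.diff(times_ns)))
    n_frames = u.shape[0]
    max_lag = max_lag_frames if max_lag_frames is not None else n_frames - 1
    max_lag = min(max_lag, n_frames - 1)

    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    for lag in lags[1:]:
        d = u[lag:] - u[:-lag]
        msd[lag] = float(np.mean(np.sum(d**2, axis=2)))
    lag_ns = lags * dt

    fit = fit_diffusion_from_msd(lag_ns, msd, fit_window_ns)
    return MSDSeries(
        lag_ns=lag_ns, msd_A2=msd, fit_window_ns=fit_window_ns,
        diffusion_um2_s=fit["D_um2_s"], slope_A2_ns=fit["slope_A2_ns"],
        slope_stderr_A2_ns=fit["slope_stderr_A2_ns"],
        intercept_A2=fit["intercept_A2"],
        n_particles=int(mask.sum()),
    )


def fit_diffusion_from_msd(
    lag_ns: np.ndarray, msd_A2: np.ndarray, fit_window_ns: tuple[float, float]
) -> dict:
    """Unweighted linear fit of MSD(lag) on the window; D = slope/4 for
    lateral (2-D) diffusion, reported in um^2/s."""
    lag_ns = np.asarray(lag_ns, dtype=float)
    lo, hi = fit_window_ns
    fit_mask = (lag_ns >= lo) & (lag_ns <= hi)
    if fit_mask.sum() < 2:
        raise ValueError(
            f"fit window {fit_window_ns} ns outside lag range 0-{lag_ns[-1]:.1f} ns"
        )
    res = stats.linregress(lag_ns[fit_mask], np.asarray(msd_A2)[fit_mask])
    slope = float(res.slope)
    if slope < 0:
        warnings.warn("negative MSD slope: reporting D = 0", stacklevel=2)
    return {
        "D_um2_s": max(slope, 0.0) / 4.0 * A2_NS_TO_UM2_S,
        "slope_A2_ns": slope,
        "slope_stderr_A2_ns": float(res.stderr),
        "intercept_A2": float(res.intercept),
    }
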