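"""Configuration-driven orchestration of the analysis modules.

A single YAML file describes a run: a global seed, an output directory and
an ordered task list.  Each task block mirrors one module's options; unknown
keys are rejected up front so a typo cannot silently fall back to a
default.  Every run writes a manifest (config hash, package version,
per-task status, produced files) and, for synthetic tasks, is exactly
reproducible from the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bilayer, domains, frap, spectra, synthetic

__all__ = ["AnalysisConfig", "RunManifest", "load_config", "run_pipeline", "ConfigError"]

log = logging.getLogger("bilayerlens")


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


_TOP_KEYS = {"seed", "out_dir", "log_level", "tasks"}

# allowed option keys per task type ("task" itself excluded)
_TASK_KEYS = {
    "synth_frap": {"n_traces", "diffusion_um2_s", "amplitude_a", "baseline_b",
                   "bleach_radius_um", "noise_sd", "out"},
    "synth_image": {"width_px", "height_px", "pixel_size_um", "n_domains",
                    "radius_um", "shape", "noise_sd", "out"},
    "synth_spectra": {"centers_nm", "mol_percents", "fwhm_nm", "noise_sd",
                      "n_replicates", "out"},
    "synth_bilayer": {"n_phospholipid_per_leaflet", "n_steroid_per_leaflet",
                      "thickness_A", "apl_A2", "ring_depth_mean_A",
                      "ring_depth_sd_A", "tilt_mode", "n_frames",
                      "steroid_resname", "out"},
    "synth_brownian": {"n_particles", "diffusion_um2_s", "n_frames",
                       "frame_dt_ns", "box_xy_A", "out"},
    "frap": {"input", "radius_um", "out"},
    "domains": {"image", "pixel_size_um", "min_diameter_um", "threshold",
                "fixed_threshold", "out"},
    "spectra": {"input", "range_nm", "out"},
    "bilayer": {"traj", "steroid_resname", "analyses", "bin_width_A",
                "fit_window_ns", "out"},
}


@dataclass
class AnalysisConfig:
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    tasks: list = field(default_factory=list)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    tasks: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "tasks": self.tasks,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }


def load_config(path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)


def validate_config(raw: dict) -> AnalysisConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    tasks = raw.get("tasks", [])
    if not isinstance(tasks, list):
        raise ConfigError("tasks must be a list")
    for i, t in enumerate(tasks):
        if not isinstance(t, dict) or "task" not in t:
            raise ConfigError(f"task #{i} must be a mapping with a 'task' key")
        kind = t["task"]
        if kind not in _TASK_KEYS:
            raise ConfigError(f"task #{i}: unknown task type {kind!r}")
        bad = set(t) - _TASK_KEYS[kind] - {"task"}
        if bad:
            raise ConfigError(f"task #{i} ({kind}): unknown keys {sorted(bad)}")
    return AnalysisConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "results")),
        log_level=str(raw.get("log_level", "INFO")),
        tasks=tasks,
    )


# ---------------------------------------------------------------------------
# Task implementations (each returns a list of written files)


def _task_synth_frap(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    n = int(p.get("n_traces", 10))
    written = []
    for i in range(n):
        spec = synthetic.SyntheticFrapSpec(
            amplitude_a=float(p.get("amplitude_a", 0.9)),
            baseline_b=float(p.get("baseline_b", 0.1)),
            diffusion_um2_s=float(p.get("diffusion_um2_s", 1.74)),
            bleach_radius_um=float(p.get("bleach_radius_um", 5.0)),
            noise_sd=float(p.get("noise_sd", 0.02)),
            seed=seed + i,
        )
        trace = synthetic.make_frap_trace(spec)
        path = out / f"trace_{i:03d}.csv"
        synthetic.write_trace_csv(trace, path)
        written.append(path)
    truth_path = out / "truth.json"
    synthetic.write_truth_json(
        {"D_um2_s": float(p.get("diffusion_um2_s", 1.74)), "n_traces": n, "seed": seed},
        truth_path,
    )
    return written + [truth_path]


def _task_synth_image(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    n_dom = int(p.get("n_domains", 12))
    spec = synthetic.SyntheticImageSpec(
        width_px=int(p.get("width_px", 500)),
        height_px=int(p.get("height_px", 500)),
        pixel_size_um=float(p.get("pixel_size_um", 0.1)),
        domain_radii_um=tuple([float(p.get("radius_um", 2.0))] * n_dom),
        domain_shapes=str(p.get("shape", "disk")),
        noise_sd=float(p.get("noise_sd", 0.0)),
        seed=seed,
    )
    image, truth = synthetic.make_domain_image(spec)
    img_path = out / "image.tif"
    domains.write_tiff(image, img_path)
    truth_path = out / "truth.json"
    synthetic.write_truth_json(
        {"n_domains": len(truth), "areas_um2": truth.areas_um2(),
         "pixel_size_um": spec.pixel_size_um, "seed": seed},
        truth_path,
    )
    return [img_path, truth_path]


def _task_synth_spectra(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    centers = p.get("centers_nm", [440.0])
    mols = p.get("mol_percents", [0.0] * len(centers))
    reps = int(p.get("n_replicates", 3))
    written = []
    k = 0
    for center, mol in zip(centers, mols):
        for r in range(reps):
            s = synthetic.make_spectrum(
                float(center), fwhm_nm=float(p.get("fwhm_nm", 40.0)),
                noise_sd=float(p.get("noise_sd", 0.01)), seed=seed + k,
                mol_percent=float(mol), label=f"c{center}_r{r}",
            )
            path = out / f"spectrum_{k:03d}.csv"
            synthetic.write_spectrum_csv(s, path)
            written.append(path)
            k += 1
    return written


def _task_synth_bilayer(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticBilayerSpec(
        n_phospholipid_per_leaflet=int(p.get("n_phospholipid_per_leaflet", 90)),
        n_steroid_per_leaflet=int(p.get("n_steroid_per_leaflet", 30)),
        thickness_A=float(p.get("thickness_A", 38.3)),
        apl_A2=float(p.get("apl_A2", 64.0)),
        ring_depth_mean_A=float(p.get("ring_depth_mean_A", 8.0)),
        ring_depth_sd_A=float(p.get("ring_depth_sd_A", 0.5)),
        tilt_mode=str(p.get("tilt_mode", "upright")),
        n_frames=int(p.get("n_frames", 20)),
        steroid_resname=str(p.get("steroid_resname", "CHL")),
        seed=seed,
    )
    traj = synthetic.make_bilayer_trajectory(spec)
    from .trajectory import write_pdb

    pdb_path = out / "bilayer.pdb"
    write_pdb(traj, pdb_path)
    truth_path = out / "truth.json"
    truth = {k: v for k, v in traj.truth.items()
             if k not in ("ring_depths_A", "tilt_deg", "leaflet_by_molecule")}
    synthetic.write_truth_json(truth, truth_path)
    return [pdb_path, truth_path]


def _task_synth_brownian(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticBrownianSpec(
        n_particles=int(p.get("n_particles", 240)),
        diffusion_um2_s=float(p.get("diffusion_um2_s", 2.6)),
        n_frames=int(p.get("n_frames", 100)),
        frame_dt_ns=float(p.get("frame_dt_ns", 1.0)),
        box_xy_A=float(p.get("box_xy_A", 89.0)),
        seed=seed,
    )
    traj = synthetic.make_brownian(spec)
    from .trajectory import write_pdb

    pdb_path = out / "brownian.pdb"
    write_pdb(traj, pdb_path)
    truth_path = out / "truth.json"
    synthetic.write_truth_json(traj.truth, truth_path)
    return [pdb_path, truth_path]


def _task_frap(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    src = Path(p["input"])
    radius = float(p.get("radius_um", 5.0))
    files = sorted(src.glob("trace_*.csv")) if src.is_dir() else [src]
    if not files:
        raise FileNotFoundError(f"no trace CSVs under {src}")
    fits = [frap.fit_recovery(frap.read_trace_csv(f, radius, label=f.stem)) for f in files]
    cohort = out / "frap_fits.csv"
    frap.write_cohort_csv(fits, cohort)
    summary = out / "frap_summary.json"
    summary.write_text(json.dumps(frap.aggregate_diffusion(fits), indent=2) + "\n")
    return [cohort, summary]


def _task_domains(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    image = domains.read_tiff(Path(p["image"]), float(p["pixel_size_um"]))
    smoothed = domains.smooth_3x3(image)
    method = str(p.get("threshold", "otsu"))
    mask, prov = domains.binarize(
        smoothed, method=method, threshold=p.get("fixed_threshold")
    )
    dset = domains.label_and_measure(mask, image.pixel_size_um)
    kept = domains.filter_min_diameter(dset, float(p.get("min_diameter_um", 3.0)))
    table = out / "domains.csv"
    dset.to_frame().to_csv(table, index=False)
    outputs = [table]
    result = {"binarize": prov, "n_domains": len(dset), "n_after_filter": len(kept)}
    if len(dset):
        dist = domains.size_distribution(dset)
        result["shannon_entropy_bits"] = domains.shannon_entropy(dist)
    if len(kept):
        result["circularity"] = domains.circularity_summary(kept)
    report = out / "domains_summary.json"
    report.write_text(json.dumps(result, indent=2) + "\n")
    outputs.append(report)
    return outputs


def _task_spectra(p: dict, seed: int, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    src = Path(p["input"])
    files = sorted(src.glob("spectrum_*.csv")) if src.is_dir() else [src]
    if not files:
        raise FileNotFoundError(f"no spectrum CSVs under {src}")
    specs = []
    for f in files:
        df = pd.read_csv(f)
        specs.append(
            spectra.EmissionSpectrum(
                df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(),
                label=str(df["label"].iloc[0]),
                mol_percent=float(df["mol_percent"].iloc[0]),
                composition=str(df.get("composition", pd.Series([""])).iloc[0]),
            )
        )
    rng = tuple(p.get("range_nm", spectra.DEFAULT_RANGE_NM))
    series = spectra.com_vs_concentration(specs, range_nm=rng)
    path = out / "spectral_series.csv"
    series.to_frame().to_csv(path, index=False)
    return [path]


def _task_bilayer(p: dict, seed: int, out: Path) -> list[Path]:
    from .trajectory import read_pdb

    out.mkdir(parents=True, exist_ok=True)
    traj = read_pdb(Path(p["traj"]))
    traj = bilayer.assign_leaflets_and_center(traj)
    steroid = str(p.get("steroid_resname", "CHL"))
    analyses = p.get("analyses", ["density", "thickness", "tilt", "apl"])
    bw = float(p.get("bin_width_A", 0.5))
    written: list[Path] = []
    manifest: dict = {"analyses": analyses, "bin_width_A": bw}
    if "density" in analyses or "thickness" in analyses:
        prof = bilayer.partial_density_profile(traj, resname="DOPC", name="P", bin_width_A=bw)
        path = out / "phosphorus_density.csv"
        pd.DataFrame({"z_A": prof.z_centers_A, "density_A3": prof.density}).to_csv(
            path, index=False
        )
        written.append(path)
        if "thickness" in analyses:
            manifest["thickness_A"] = bilayer.membrane_thickness(prof)
    if "ring_density" in analyses:
        prof = bilayer.ring_center_profile(traj, steroid, bin_width_A=bw)
        path = out / "ring_center_density.csv"
        pd.DataFrame({"z_A": prof.z_centers_A, "density_A3": prof.density}).to_csv(
            path, index=False
        )
        written.append(path)
        zmax = float(np.max(np.abs(prof.z_centers_A)))
        manifest["ring_peak_A"] = bilayer.profile_peak(prof, (0.0, zmax))
    if "tilt" in analyses:
        tilts = bilayer.ring_tilt_angles(traj, steroid)
        probs, edges = tilts.histogram()
        path = out / "tilt_histogram.csv"
        pd.DataFrame(
            {"theta_deg": (edges[:-1] + edges[1:]) / 2, "probability": probs}
        ).to_csv(path, index=False)
        written.append(path)
    if "order" in analyses:
        profiles = bilayer.order_parameter_profile(traj)
        path = out / "order_profile.csv"
        pd.concat([pr.to_frame() for pr in profiles.values()]).to_csv(path, index=False)
        written.append(path)
    if "apl" in analyses:
        apl = bilayer.voronoi_apl(traj)
        path = out / "apl.csv"
        apl.to_frame().to_csv(path, index=False)
        written.append(path)
    if "msd" in analyses:
        fw = tuple(p.get("fit_window_ns", (30.0, 70.0)))
        series = bilayer.msd_diffusion(traj, name="P", fit_window_ns=fw)
        path = out / "msd.csv"
        series.to_frame().to_csv(path, index=False)
        written.append(path)
        manifest["D_um2_s"] = series.diffusion_um2_s
        manifest["fit_window_ns"] = list(fw)
    report = out / "bilayer_summary.json"
    report.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(report)
    return written


_TASK_FNS = {
    "synth_frap": _task_synth_frap,
    "synth_image": _task_synth_image,
    "synth_spectra": _task_synth_spectra,
    "synth_bilayer": _task_synth_bilayer,
    "synth_brownian": _task_synth_brownian,
    "frap": _task_frap,
    "domains": _task_domains,
    "spectra": _task_spectra,
    "bilayer": _task_bilayer,
}


def run_pipeline(config: AnalysisConfig, base_dir: Path | str = ".") -> RunManifest:
    """Execute the configured tasks in order and write the run manifest.

    Raises on the first failing task after recording its status; relative
    paths resolve against ``base_dir``.
    """
    base = Path(base_dir)
    out_root = base / config.out_dir
    out_root.mkdir(parents=True, exist_ok=True)
    cfg_blob = json.dumps(
        {"seed": config.seed, "tasks": config.tasks}, sort_keys=True
    ).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_blob).hexdigest()[:16],
        package_version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    failure: Exception | None = None
    for i, t in enumerate(config.tasks):
        kind = t["task"]
        params = {
            k: v for k, v in t.items() if k != "task"
        }
        # resolve input paths relative to base_dir
        for key in ("input", "image", "traj"):
            if key in params:
                params[key] = str(base / params[key])
        out = out_root / str(params.pop("out", kind))
        t0 = time.perf_counter()
        log.info("task %d/%d %s -> %s", i + 1, len(config.tasks), kind, out)
        try:
            files = _TASK_FNS[kind](params, config.seed + i, out)
            status = "ok"
        except Exception as exc:  # recorded, then re-raised after manifest write
            files, status, failure = [], f"failed: {exc}", exc
        manifest.tasks.append(
            {"task": kind, "status": status,
             "wall_s": round(time.perf_counter() - t0, 3)}
        )
        manifest.outputs.extend(str(f.relative_to(base)) for f in files)
        if failure is not None:
            break
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_root / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2) + "\n"
    )
    if failure is not None:
        raise RuntimeError(f"task {kind!r} failed") from failure
    return manifest
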