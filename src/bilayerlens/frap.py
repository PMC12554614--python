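"""Fluorescence recovery after photobleaching (FRAP) analysis.

Recovery of fluorescence into a uniformly bleached disk of radius ``w`` by
pure lateral diffusion follows the closed-form Soumpasis solution, here used
in its modified form with a free amplitude ``a`` and post-bleach baseline
``b``::

    f(t) = a * exp(-2*tau_d/t) * [I0(2*tau_d/t) + I1(2*tau_d/t)] + b

where ``I0`` and ``I1`` are modified Bessel functions of the first kind and
``tau_d = w**2 / (4*D)`` is the characteristic diffusion time.  The mobile
fraction is ``R_mobile = a / (1 - b)``.

Traces are normalised against a reference region so that slow acquisition
photobleaching divides out before fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "FrapTrace",
    "FrapFit",
    "recovery_model",
    "normalize_trace",
    "fit_recovery",
    "mobile_fraction",
    "aggregate_diffusion",
    "read_trace_csv",
    "write_fit_json",
    "write_cohort_csv",
]


@dataclass
class FrapTrace:
    """A normalised post-bleach recovery curve.

    Attributes
    ----------
    time_s : array
        Strictly increasing times after the bleach, in seconds (all > 0
        except an optional leading 0).
    intensity_norm : array
        Double-normalised fluorescence (bleach ROI over reference, relative
        to pre-bleach), dimensionless.
    bleach_radius_um : float
        Radius ``w`` of the bleached disk in micrometres.
    label : str
        Free-text identifier (composition, region, ...).
    truth : dict
        Optional generator ground truth (synthetic traces only).
    """

    time_s: np.ndarray
    intensity_norm: np.ndarray
    bleach_radius_um: float
    label: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity_norm = np.asarray(self.intensity_norm, dtype=float)
        if self.time_s.shape != self.intensity_norm.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time_s.size < 8:
            raise ValueError("a FRAP trace needs at least 8 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.time_s < 0):
            raise ValueError("post-bleach times must be non-negative")
        if self.bleach_radius_um <= 0:
            raise ValueError("bleach radius must be positive")


@dataclass
class FrapFit:
    """Fitted modified-Soumpasis parameters for one trace.

    ``diffusion_um2_s`` always satisfies ``D = w**2 / (4 * tau_d_s)``; the
    mobile fraction is reported raw and, when outside [0, 1], also clipped
    with a flag rather than silently truncated.
    """

    amplitude_a: float
    baseline_b: float
    tau_d_s: float
    bleach_radius_um: float
    diffusion_um2_s: float
    mobile_fraction: float
    mobile_fraction_clipped: float
    mobile_fraction_out_of_range: bool
    rss: float
    converged: bool
    n_points: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "a": self.amplitude_a,
            "b": self.baseline_b,
            "tau_d_s": self.tau_d_s,
            "w_um": self.bleach_radius_um,
            "D_um2_s": self.diffusion_um2_s,
            "R_mobile": self.mobile_fraction,
            "R_mobile_clipped": self.mobile_fraction_clipped,
            "R_mobile_out_of_range": self.mobile_fraction_out_of_range,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }


def recovery_model(t, a: float, b: float, tau_d: float):
    """Evaluate the modified Soumpasis recovery curve.

    Uses the exponentially scaled Bessel forms ``i0e``/``i1e`` so that the
    product ``exp(-x) * (I0(x) + I1(x))`` stays finite as ``t -> 0`` (where
    ``x = 2*tau_d/t`` diverges).  At ``t == 0`` the limiting value ``b`` is
    returned.

    Parameters
    ----------
    t : float or array
        Time(s) after the bleach, seconds; must be >= 0.
    a, b : float
        Recovery amplitude and post-bleach baseline.
    tau_d : float
        Characteristic diffusion time, seconds; must be > 0.
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    out = np.full(t_arr.shape, float(b))
    pos = t_arr > 0
    x = 2.0 * tau_d / t_arr[pos]
    out[pos] = a * (special.i0e(x) + special.i1e(x)) + b
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def normalize_trace(
    time_s,
    bleach_series,
    reference_series,
    prebleach_bleach: float,
    prebleach_reference: float,
    bleach_radius_um: float,
    label: str = "",
) -> FrapTrace:
    """Double-normalise a raw FRAP recording into a :class:`FrapTrace`.

    ``corrected(t) = (bleach(t) / reference(t)) /
    (prebleach_bleach / prebleach_reference)`` — the reference region (the
    whole image excluding the bleached spot) divides out acquisition
    photobleaching and lamp drift.
    """
    time_s = np.asarray(time_s, dtype=float)
    bleach = np.asarray(bleach_series, dtype=float)
    ref = np.asarray(reference_series, dtype=float)
    if not (time_s.shape == bleach.shape == ref.shape):
        raise ValueError("time, bleach and reference series must share a grid")
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(f"reference intensity non-positive at index {bad[0]}")
    if prebleach_reference <= 0 or prebleach_bleach <= 0:
        raise ValueError("pre-bleach intensities must be positive")
    corrected = (bleach / ref) / (prebleach_bleach / prebleach_reference)
    return FrapTrace(time_s, corrected, bleach_radius_um, label=label)


def mobile_fraction(a: float, b: float) -> tuple[float, float, bool]:
    """Mobile fraction ``R = a / (1 - b)``.

    Returns ``(raw, clipped, out_of_range)``; ``b >= 1`` is a domain error
    (the baseline would imply complete recovery before any diffusion).
    """
    if b >= 1.0:
        raise ValueError("baseline b must be < 1")
    if b < 0:
        raise ValueError("baseline b must be >= 0")
    raw = a / (1.0 - b)
    clipped = float(min(max(raw, 0.0), 1.0))
    return float(raw), clipped, not (0.0 <= raw <= 1.0)


_BOUNDS = ([0.0, 0.0, 1e-3], [1.5, 1.5, 1e4])


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Least-squares fit of (a, b, tau_d); D and R_mobile derived from it.

    Initial guesses are scale-free: b from the minimum intensity, a from the
    range, tau_d from the time of half recovery.  Unweighted residuals.
    A flat trace (no recovery amplitude) is reported as non-converged with
    the diffusion coefficient undefined (NaN).
    """
    t = trace.time_s
    y = trace.intensity_norm
    w = trace.bleach_radius_um

    y_min, y_max = float(np.min(y)), float(np.max(y))
    span = y_max - y_min
    if span < 1e-6:  # flat trace: nothing to fit
        return FrapFit(
            amplitude_a=0.0, baseline_b=y_min, tau_d_s=np.nan,
            bleach_radius_um=w, diffusion_um2_s=np.nan,
            mobile_fraction=np.nan, mobile_fraction_clipped=np.nan,
            mobile_fraction_out_of_range=False, rss=float(np.sum((y - y.mean()) ** 2)),
            converged=False, n_points=t.size, label=trace.label,
        )

    half = y_min + 0.5 * span
    above = np.flatnonzero(y >= half)
    tau0 = float(t[above[0]]) if above.size else float(np.median(t))
    tau0 = min(max(tau0, _BOUNDS[0][2] * 10), _BOUNDS[1][2] / 10)
    p0 = [span, max(y_min, 0.0), tau0]

    try:
        popt, _ = optimize.curve_fit(
            recovery_model, t, y, p0=p0, bounds=_BOUNDS, maxfev=20000
        )
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = p0, False

    a, b, tau_d = (float(v) for v in popt)
    resid = y - recovery_model(t, a, b, tau_d)
    rss = float(np.sum(resid**2))
    if tau_d <= 0:
        raise RuntimeError(f"fitted tau_d non-positive ({tau_d}); trace {trace.label!r}")
    diffusion = w**2 / (4.0 * tau_d) if converged else np.nan
    if converged and b < 1.0:
        r_raw, r_clip, r_oob = mobile_fraction(a, b)
    else:
        r_raw, r_clip, r_oob = np.nan, np.nan, False
    return FrapFit(
        amplitude_a=a, baseline_b=b, tau_d_s=tau_d, bleach_radius_um=w,
        diffusion_um2_s=diffusion, mobile_fraction=r_raw,
        mobile_fraction_clipped=r_clip, mobile_fraction_out_of_range=r_oob,
        rss=rss, converged=converged, n_points=t.size, label=trace.label,
    )


def aggregate_diffusion(fits: Sequence[FrapFit]) -> dict:
    """Mean and sample sd of D over converged fits.

    Mirrors the experimental practice of averaging D over >= 10 bleached
    regions per composition.  With a single converged fit the sd is reported
    as NaN with ``sd_defined=False``.
    """
    ds = np.array([f.diffusion_um2_s for f in fits if f.converged], dtype=float)
    ds = ds[np.isfinite(ds)]
    if ds.size == 0:
        raise ValueError("no converged fits to aggregate")
    mean = float(np.mean(ds))
    if ds.size > 1:
        sd, sd_defined = float(np.std(ds, ddof=1)), True
    else:
        sd, sd_defined = float("nan"), False
        warnings.warn("single converged fit: sd undefined", stacklevel=2)
    return {"mean_D_um2_s": mean, "sd_D_um2_s": sd, "sd_defined": sd_defined, "n": int(ds.size)}


# ---------------------------------------------------------------------------
# I/O


def read_trace_csv(path, bleach_radius_um: float, label: str = "") -> FrapTrace:
    """Read a raw trace CSV (columns: time_s, bleach_intensity,
    reference_intensity) and double-normalise it.

    The pre-bleach levels are taken from the first sample (time 0 is the
    post-bleach origin; acquisition software typically stores the pre-bleach
    means in the first row).
    """
    df = pd.read_csv(path)
    required = {"time_s", "bleach_intensity", "reference_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    pre_b = float(df["bleach_intensity"].iloc[0])
    pre_r = float(df["reference_intensity"].iloc[0])
    body = df.iloc[1:]
    return normalize_trace(
        body["time_s"].to_numpy(),
        body["bleach_intensity"].to_numpy(),
        body["reference_intensity"].to_numpy(),
        pre_b, pre_r, bleach_radius_um, label=label or str(path),
    )


def write_fit_json(fit: FrapFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def write_cohort_csv(fits: Sequence[FrapFit], path) -> None:
    rows = [
        {
            "label": f.label, "D_um2_s": f.diffusion_um2_s, "a": f.amplitude_a,
            "b": f.baseline_b, "R_mobile": f.mobile_fraction, "rss": f.rss,
            "converged": f.converged,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
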