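"""Ratiometric two-channel image analysis and mass-action saturation fitting.

Workflow for the apparent vinculin-actin dissociation constant: threshold
the vinculin channel to mask the decorated network, subtract the
out-of-mask background from both channels, form per-pixel vinculin/actin
ratios (or line-scan plateau means), calibrate intensities to
concentrations with labelled-protein standards, and fit

    B = Bmax * A / (KD + A)

by nonlinear least squares. Under this law the occupancy ratio
B/A = Bmax/(KD + A) decreases with actin density, which is why sparse
networks show higher vinculin occupancy than dense ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.filters import threshold_otsu
from skimage.measure import profile_line

from polarimap.errors import FitFailureError
from polarimap.synthetic import mass_action_bound

__all__ = [
    "RatioDataset",
    "SaturationFit",
    "make_mask",
    "subtract_background",
    "ratio_image",
    "calibrate",
    "fit_saturation",
    "line_scan",
    "ratio_vs_density",
]


@dataclass
class RatioDataset:
    """Masked, background-corrected two-channel data ready for fitting."""

    actin: np.ndarray
    vinculin: np.ndarray
    ratio: np.ndarray        # nan outside mask / where actin <= 0
    mask: np.ndarray
    cal_actin: float = 1.0   # intensity per concentration unit, > 0
    cal_vinculin: float = 1.0


@dataclass
class SaturationFit:
    """Apparent KD and Bmax with confidence intervals (same units as input)."""

    kd: float
    bmax: float
    kd_ci: tuple[float, float]
    bmax_ci: tuple[float, float]
    ci_level: float
    residual_sd: float
    n: int


def make_mask(vinculin: np.ndarray, method="otsu") -> np.ndarray:
    """Binary mask of the vinculin-decorated network.

    ``method`` is either 'otsu' or a fixed threshold value; pixels strictly
    above the threshold are in the mask. An empty mask triggers a warning.
    """
    img = np.asarray(vinculin, dtype=float)
    if method == "otsu":
        thresh = threshold_otsu(img)
    else:
        thresh = float(method)
    mask = img > thresh
    if not mask.any():
        warnings.warn("mask is empty: no pixels above threshold", stacklevel=2)
    return mask


def subtract_background(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the median intensity of out-of-mask pixels; returns (image, bg)."""
    img = np.asarray(image, dtype=float)
    outside = img[~np.asarray(mask, dtype=bool)]
    bg = float(np.median(outside)) if outside.size else 0.0
    return img - bg, bg


def ratio_image(vinculin: np.ndarray, actin: np.ndarray, mask: np.ndarray,
                background_subtract: bool = True) -> np.ndarray:
    """Per-pixel vinculin/actin ratio inside the mask.

    Pixels outside the mask, or whose background-corrected actin signal is
    <= 0, are nan. Images must be co-registered and the same shape.
    """
    v = np.asarray(vinculin, dtype=float)
    a = np.asarray(actin, dtype=float)
    if v.shape != a.shape:
        raise ValueError(f"channel shapes differ: {v.shape} vs {a.shape}")
    m = np.asarray(mask, dtype=bool)
    if background_subtract:
        v, _ = subtract_background(v, m)
        a, _ = subtract_background(a, m)
    out = np.full(v.shape, np.nan)
    valid = m & (a > 0)
    out[valid] = v[valid] / a[valid]
    return out


def calibrate(concentrations, intensities) -> float:
    """Intensity-per-concentration factor from labelled-protein standards.

    Zero-intercept least squares (background is subtracted upstream):
    slope = sum(C*I) / sum(C^2). A single standard reduces to I/C.
    """
    c = np.asarray(concentrations, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if c.size == 0 or c.size != i.size:
        raise ValueError("need equally many concentrations and intensities (>= 1)")
    denom = float(np.sum(c * c))
    if denom == 0:
        raise ValueError("all standard concentrations are zero")
    return float(np.sum(c * i) / denom)


def fit_saturation(actin, bound, ci_level: float = 0.95,
                   p0: tuple[float, float] | None = None,
                   weighting: str = "relative") -> SaturationFit:
    """Fit B = Bmax*A/(KD+A) by nonlinear least squares.

    ``weighting='relative'`` (default) iteratively reweights residuals by
    the model value — the matched estimator when measurement error scales
    with the signal, as fluorescence-intensity noise does; ``'none'``
    gives ordinary unweighted least squares. Confidence intervals come
    from the parameter covariance with a t-distribution on n - 2 degrees
    of freedom (95% by default). A fit driven to the KD ~ 0 boundary (no
    curvature left in the data) or with very wide CIs raises a warning.
    """
    a = np.asarray(actin, dtype=float)
    b = np.asarray(bound, dtype=float)
    if a.size != b.size:
        raise ValueError("actin and bound must have the same length")
    if np.unique(a).size < 3:
        raise ValueError("need at least 3 distinct actin concentrations")
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if p0 is None:
        bmax0 = float(np.max(b)) * 1.2 if np.max(b) > 0 else 1.0
        half = 0.5 * bmax0
        kd0 = float(a[np.argmin(np.abs(b - half))]) or float(np.median(a))
        p0 = (kd0, bmax0)
    model = lambda x, kd, bmax: mass_action_bound(x, kd, bmax)  # noqa: E731
    try:
        popt, pcov = optimize.curve_fit(
            model, a, b, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000)
        if weighting == "relative":
            for _ in range(3):
                sigma = np.maximum(model(a, *popt), 1e-12 * max(float(np.max(b)), 1.0))
                popt, pcov = optimize.curve_fit(
                    model, a, b, p0=tuple(popt), sigma=sigma,
                    bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"saturation fit failed to converge: {exc}") from exc
    kd, bmax = map(float, popt)
    dof = max(a.size - 2, 1)
    resid = b - mass_action_bound(a, kd, bmax)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    tval = float(stats.t.ppf(0.5 + ci_level / 2, dof))
    perr = np.sqrt(np.diag(pcov))
    kd_ci = (kd - tval * perr[0], kd + tval * perr[0])
    bmax_ci = (bmax - tval * perr[1], bmax + tval * perr[1])
    a_min = float(np.min(a[a > 0])) if np.any(a > 0) else 0.0
    if a_min > 0 and kd < 1e-3 * a_min:
        # KD far below the lowest measured concentration: the curve is
        # saturated everywhere and the data carry no curvature information
        warnings.warn("KD fit hit the zero boundary: data show no curvature "
                      "(bound ~ constant over the measured actin range)",
                      stacklevel=2)
    elif not np.all(np.isfinite(perr)) or perr[0] > 10 * kd:
        warnings.warn("KD confidence interval is very wide: data poorly "
                      "constrain the saturation curve", stacklevel=2)
    return SaturationFit(kd=kd, bmax=bmax, kd_ci=kd_ci, bmax_ci=bmax_ci,
                         ci_level=ci_level, residual_sd=residual_sd, n=int(a.size))


def line_scan(image: np.ndarray, start: tuple[float, float],
              end: tuple[float, float], width: int = 1,
              plateau_tolerance: float = 0.10) -> dict:
    """Averaged intensity profile along a line, with its plateau mean.

    The profile is averaged across ``width`` perpendicular pixels. The
    plateau is the longest contiguous run of samples within
    ``plateau_tolerance`` (fractional) of the profile's running median;
    an all-ramp profile has no plateau (warning, nan mean).
    """
    profile = profile_line(np.asarray(image, dtype=float), start, end,
                           linewidth=width, mode="reflect")
    n = profile.size
    win = max(3, (n // 5) | 1)  # odd window, ~1/5 of the profile
    pad = win // 2
    padded = np.pad(profile, pad, mode="edge")
    running = np.array([np.median(padded[i:i + win]) for i in range(n)])
    scale = np.maximum(np.abs(running), 1e-12)
    ok = np.abs(profile - running) / scale <= plateau_tolerance

    # contiguous runs of ok samples, broken at intensity discontinuities
    # (otherwise a dark-bright-dark bar would read as one "plateau");
    # prefer the central run, else the longest
    jump = np.zeros(n, dtype=bool)
    jump[1:] = np.abs(np.diff(profile)) > plateau_tolerance * scale[1:]
    runs = []
    start_i = None
    for i in range(n):
        if ok[i] and not (jump[i] and start_i is not None):
            if start_i is None:
                start_i = i
        else:
            if start_i is not None:
                runs.append((start_i, i))
            start_i = i if ok[i] else None
    if start_i is not None:
        runs.append((start_i, n))
    central = [r for r in runs if r[0] <= n // 2 < r[1]]
    ordered = central + sorted(runs, key=lambda r: r[0] - r[1])
    for lo, hi in ordered:
        if hi - lo < max(3, n // 4):
            continue
        seg = profile[lo:hi]
        # a plateau must be genuinely flat, not a slowly tracking ramp
        flat = np.abs(seg - np.median(seg)) / max(abs(float(np.median(seg))), 1e-12)
        if np.median(flat) <= plateau_tolerance:
            return {"profile": profile, "plateau_mean": float(np.mean(seg)),
                    "plateau_slice": slice(lo, hi)}
    warnings.warn("no plateau found in line-scan profile", stacklevel=2)
    return {"profile": profile, "plateau_mean": float("nan"), "plateau_slice": None}


def ratio_vs_density(actin_values, ratio_values, bins=10) -> pd.DataFrame:
    """Binned mean +/- sd of the vinculin/actin ratio vs actin density.

    ``bins`` is an integer count or explicit bin edges over the actin
    intensity axis. Returns columns ``bin_left, bin_right, bin_center,
    mean_ratio, sd_ratio, n``; empty bins are dropped.
    """
    a = np.asarray(actin_values, dtype=float).ravel()
    r = np.asarray(ratio_values, dtype=float).ravel()
    valid = np.isfinite(a) & np.isfinite(r)
    a, r = a[valid], r[valid]
    if a.size == 0:
        raise ValueError("no valid (actin, ratio) pairs to bin")
    edges = np.histogram_bin_edges(a, bins=bins)
    which = np.clip(np.digitize(a, edges) - 1, 0, len(edges) - 2)
    rows = []
    for k in range(len(edges) - 1):
        sel = which == k
        if not sel.any():
            continue
        rows.append((edges[k], edges[k + 1], 0.5 * (edges[k] + edges[k + 1]),
                     float(np.mean(r[sel])),
                     float(np.std(r[sel], ddof=1)) if sel.sum() > 1 else 0.0,
                     int(sel.sum())))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "bin_center",
                                       "mean_ratio", "sd_ratio", "n"])
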