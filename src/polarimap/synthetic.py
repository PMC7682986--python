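"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the experimental inputs of the bundle-polarity /
binding / kinetics analyses:

* bundles of short (~0.7 um) capped actin filaments boxed into segments
  every 16.5 nm, each segment carrying an in-tomogram psi angle that
  differs by half a turn between the two filament polarities;
* two-channel (actin / vinculin) fluorescence images in which the bound
  ligand obeys the mass-action law B = Bmax * A / (KD + A);
* single-filament tip-position traces growing at k_on * [actin] subunits
  per second with a 2.76 nm rise per subunit;
* dendritic (Arp2/3-like) networks with Poisson-distributed branch
  junctions at a fixed branching angle.

All generators are bit-reproducible given their spec (which includes the
seed). Coordinates are in nm, angles in degrees wrapped to [-180, 180),
concentrations in the unit the caller chooses (kept consistent per spec).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from polarimap.angles import wrap_angle
from polarimap.errors import InvalidSpecError

__all__ = [
    "BundleSpec",
    "BindingSimSpec",
    "GrowthSimSpec",
    "GrowthTrace",
    "generate_bundle",
    "generate_saturation_dataset",
    "generate_growth_trace",
    "generate_growth_movie",
    "generate_two_channel_image",
    "generate_branched_network",
    "disk_density_map",
]

#: nm of filament length added per polymerized actin subunit (helical rise 27.6 A)
RISE_PER_SUBUNIT_NM = 2.76

#: axial distance between extracted segments of one filament, nm
SEGMENT_SPACING_NM = 16.5


# ---------------------------------------------------------------------------
# bundle geometry + psi angles


@dataclass(frozen=True)
class BundleSpec:
    """Geometry and noise model of a synthetic filament bundle.

    Filaments are parallel to +x, arranged on a square lattice in the y-z
    plane (near-square grid unless ``grid_shape`` is given). Segments are
    placed every ``segment_spacing`` nm. Each segment's psi angle is drawn
    around ``psi_plus`` for '+' filaments and around ``psi_plus`` + 180 for
    '-' filaments, with wrapped-normal noise of width ``psi_noise_sigma``.
    """

    n_filaments: int
    segments_per_filament: int
    segment_spacing: float = SEGMENT_SPACING_NM
    lattice_spacing: float = 30.0
    polarity_pattern: Literal["uniform", "alternating", "random"] = "uniform"
    p_plus: float = 0.5
    psi_noise_sigma: float = 0.0
    position_jitter: float = 0.0
    psi_plus: float = 30.0
    grid_shape: tuple[int, int] | None = None
    tomogram_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filaments < 1:
            raise InvalidSpecError("n_filaments must be >= 1")
        if self.segments_per_filament < 1:
            raise InvalidSpecError("segments_per_filament must be >= 1")
        if self.segment_spacing <= 0:
            raise InvalidSpecError("segment_spacing must be > 0")
        if self.lattice_spacing <= 0:
            raise InvalidSpecError("lattice_spacing must be > 0")
        if not 0.0 <= self.p_plus <= 1.0:
            raise InvalidSpecError("p_plus must be in [0, 1]")
        if self.psi_noise_sigma < 0 or self.position_jitter < 0:
            raise InvalidSpecError("noise parameters must be >= 0")
        if self.polarity_pattern not in ("uniform", "alternating", "random"):
            raise InvalidSpecError(f"unknown polarity_pattern {self.polarity_pattern!r}")


def _lattice_positions(spec: BundleSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (row, col, yz positions) for each filament on the lattice."""
    if spec.grid_shape is not None:
        n_rows, n_cols = spec.grid_shape
        if n_rows * n_cols < spec.n_filaments:
            raise InvalidSpecError("grid_shape too small for n_filaments")
    else:
        n_cols = int(math.ceil(math.sqrt(spec.n_filaments)))
        n_rows = int(math.ceil(spec.n_filaments / n_cols))
    idx = np.arange(spec.n_filaments)
    rows, cols = idx // n_cols, idx % n_cols
    yz = np.column_stack([cols * spec.lattice_spacing, rows * spec.lattice_spacing])
    return rows, cols, yz


def _assign_polarities(spec: BundleSpec, rows: np.ndarray, cols: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    if spec.polarity_pattern == "uniform":
        return np.full(spec.n_filaments, "+", dtype=object)
    if spec.polarity_pattern == "alternating":
        # checkerboard on the lattice: every axis-adjacent filament is opposite
        return np.where((rows + cols) % 2 == 0, "+", "-").astype(object)
    return np.where(rng.random(spec.n_filaments) < spec.p_plus, "+", "-").astype(object)


def generate_bundle(spec: BundleSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a segment pose table and its ground-truth polarity map.

    Returns
    -------
    poses : DataFrame
        Columns ``tomogram_id, filament_id, segment_id, x_nm, y_nm, z_nm,
        rot_deg, tilt_deg, psi_deg`` — one row per extracted segment.
    truth : DataFrame
        Columns ``filament_id, polarity`` with polarity in {'+', '-'}.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols, yz = _lattice_positions(spec)
    polarity = _assign_polarities(spec, rows, cols, rng)

    n_seg = spec.segments_per_filament
    records = []
    for fid in range(spec.n_filaments):
        x = np.arange(n_seg) * spec.segment_spacing
        y = np.full(n_seg, yz[fid, 0])
        z = np.full(n_seg, yz[fid, 1])
        if spec.position_jitter > 0:
            y = y + rng.normal(0.0, spec.position_jitter, n_seg)
            z = z + rng.normal(0.0, spec.position_jitter, n_seg)
        mu = spec.psi_plus if polarity[fid] == "+" else spec.psi_plus + 180.0
        psi = np.full(n_seg, mu)
        if spec.psi_noise_sigma > 0:
            psi = psi + rng.normal(0.0, spec.psi_noise_sigma, n_seg)
        psi = wrap_angle(psi)
        for sid in range(n_seg):
            records.append((spec.tomogram_id, fid, sid, x[sid], y[sid], z[sid],
                            0.0, 90.0, psi[sid]))

    poses = pd.DataFrame(records, columns=[
        "tomogram_id", "filament_id", "segment_id",
        "x_nm", "y_nm", "z_nm", "rot_deg", "tilt_deg", "psi_deg"])
    truth = pd.DataFrame({"filament_id": np.arange(spec.n_filaments),
                          "polarity": polarity})
    return poses, truth


# ---------------------------------------------------------------------------
# equilibrium binding


@dataclass(frozen=True)
class BindingSimSpec:
    """Mass-action saturation curve with multiplicative Gaussian noise.

    ``bound_i = bmax * A_i / (kd + A_i) * (1 + eps_i)``, eps ~ N(0, noise_cv).
    Concentration units are whatever the caller uses for ``true_kd`` and
    ``actin_range`` (they must match).
    """

    true_kd: float
    bmax: float
    actin_range: tuple[float, ...]
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kd <= 0:
            raise InvalidSpecError("true_kd must be > 0")
        if self.bmax <= 0:
            raise InvalidSpecError("bmax must be > 0")
        if self.noise_cv < 0:
            raise InvalidSpecError("noise_cv must be >= 0")
        if len(self.actin_range) == 0:
            raise InvalidSpecError("actin_range must not be empty")
        if any(a < 0 for a in self.actin_range):
            raise InvalidSpecError("actin concentrations must be >= 0")

    @classmethod
    def log_spaced(cls, true_kd: float, bmax: float, n_points: int = 25,
                   decades: float = 2.0, noise_cv: float = 0.0, seed: int = 0
                   ) -> "BindingSimSpec":
        """Grid of ``n_points`` concentrations log-spaced around ``true_kd``."""
        if n_points < 1:
            raise InvalidSpecError("n_points must be >= 1")
        grid = np.geomspace(true_kd * 10 ** (-decades / 2),
                            true_kd * 10 ** (decades / 2), n_points)
        return cls(true_kd=true_kd, bmax=bmax, actin_range=tuple(grid),
                   noise_cv=noise_cv, seed=seed)


def mass_action_bound(actin, kd: float, bmax: float):
    """Noise-free bound concentration under mass-action equilibrium."""
    a = np.asarray(actin, dtype=float)
    return bmax * a / (kd + a)


def generate_saturation_dataset(spec: BindingSimSpec) -> pd.DataFrame:
    """Bound-vs-actin table with columns ``actin, bound, bound_true``."""
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.actin_range, dtype=float)
    true = mass_action_bound(a, spec.true_kd, spec.bmax)
    noisy = true * (1.0 + rng.normal(0.0, spec.noise_cv, a.size)) if spec.noise_cv > 0 else true.copy()
    return pd.DataFrame({"actin": a, "bound": noisy, "bound_true": true})


# ---------------------------------------------------------------------------
# filament growth


@dataclass(frozen=True)
class GrowthSimSpec:
    """Single-filament barbed-end elongation at constant monomer concentration.

    Tip position advances at ``k_on * actin_conc`` subunits/s, i.e.
    ``k_on * actin_conc * rise_per_subunit`` nm/s, with additive normal
    localization noise on each sampled position.
    """

    k_on: float                      # per uM per s
    actin_conc: float                # uM
    rise_per_subunit: float = RISE_PER_SUBUNIT_NM   # nm
    duration: float = 300.0          # s
    frame_interval: float = 5.0      # s
    localization_noise: float = 0.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on < 0:
            raise InvalidSpecError("k_on must be >= 0")
        if self.actin_conc <= 0:
            raise InvalidSpecError("actin_conc must be > 0")
        if self.rise_per_subunit <= 0:
            raise InvalidSpecError("rise_per_subunit must be > 0")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise InvalidSpecError("duration and frame_interval must be > 0")
        if self.frame_interval >= self.duration:
            raise InvalidSpecError("frame_interval must be < duration")
        if self.localization_noise < 0:
            raise InvalidSpecError("localization_noise must be >= 0")


@dataclass
class GrowthTrace:
    """Tip position vs time of one growing filament."""

    time_s: np.ndarray
    tip_nm: np.ndarray
    true_rate_nm_per_s: float = float("nan")

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.tip_nm = np.asarray(self.tip_nm, dtype=float)
        if self.time_s.shape != self.tip_nm.shape:
            raise InvalidSpecError("time and tip arrays must have the same shape")


def generate_growth_trace(spec: GrowthSimSpec) -> GrowthTrace:
    """Simulate a tip-position trace; noise is additive normal per frame."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.frame_interval, spec.frame_interval)
    rate = spec.k_on * spec.actin_conc * spec.rise_per_subunit  # nm/s
    tip = rate * t
    if spec.localization_noise > 0:
        tip = tip + rng.normal(0.0, spec.localization_noise, t.size)
    return GrowthTrace(time_s=t, tip_nm=tip, true_rate_nm_per_s=rate)


def generate_growth_movie(spec: GrowthSimSpec, pixel_size_nm: float = 100.0,
                          height_px: int = 7, intensity: float = 1000.0,
                          noise_sd: float = 0.0) -> tuple[np.ndarray, GrowthTrace]:
    """Render a growth trace as a small time-lapse stack (T, H, W).

    The filament is a horizontal bright line starting at x = 0 whose length
    at each frame equals the (noise-free) tip position; used to exercise
    kymograph construction. Returns the stack and the underlying trace.
    """
    trace = generate_growth_trace(spec)
    rng = np.random.default_rng(spec.seed + 1)
    rate = spec.k_on * spec.actin_conc * spec.rise_per_subunit
    max_len_px = int(np.ceil(rate * spec.duration / pixel_size_nm)) + 3
    stack = np.zeros((trace.time_s.size, height_px, max_len_px), dtype=float)
    row = height_px // 2
    for i, t in enumerate(trace.time_s):
        tip_px = int(round(rate * t / pixel_size_nm))
        stack[i, row, : max(tip_px, 1)] = intensity
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    return stack, trace


# ---------------------------------------------------------------------------
# two-channel images


def disk_density_map(shape: tuple[int, int], center: tuple[float, float],
                     radius: float, value: float) -> np.ndarray:
    """Uniform-density disk on a zero background (density units = caller's)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    return np.where(mask, value, 0.0)


def generate_two_channel_image(density_map: np.ndarray, kd: float, bmax: float,
                               cal_actin: float = 1.0, cal_vinculin: float = 1.0,
                               background: float = 0.0, noise_sd: float = 0.0,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render co-registered actin and vinculin channels from an actin-density map.

    Per pixel, vinculin follows the mass-action law applied to the local
    actin density, each channel scaled by its calibration factor
    (intensity per concentration unit) plus a constant background and
    optional additive Gaussian noise.

    Returns ``(actin_image, vinculin_image, truth)`` where truth records
    the density map, the noise-free ratio field and all parameters.
    """
    if kd <= 0 or bmax <= 0:
        raise InvalidSpecError("kd and bmax must be > 0")
    if cal_actin <= 0 or cal_vinculin <= 0:
        raise InvalidSpecError("calibration factors must be > 0")
    rng = np.random.default_rng(seed)
    a = np.asarray(density_map, dtype=float)
    bound = mass_action_bound(a, kd, bmax)
    actin_img = cal_actin * a + background
    vinc_img = cal_vinculin * bound + background
    if noise_sd > 0:
        actin_img = actin_img + rng.normal(0.0, noise_sd, a.shape)
        vinc_img = vinc_img + rng.normal(0.0, noise_sd, a.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_true = np.where(a > 0, (cal_vinculin * bound) / (cal_actin * a), np.nan)
    truth = {"density_map": a, "bound_map": bound, "ratio_true": ratio_true,
             "kd": kd, "bmax": bmax, "cal_actin": cal_actin,
             "cal_vinculin": cal_vinculin, "background": background}
    return actin_img, vinc_img, truth


# ---------------------------------------------------------------------------
# branched networks


def generate_branched_network(branch_rate_per_um: float, branch_angle_deg: float = 70.0,
                              mother_length_um: float = 10.0,
                              branch_length_um: float = 2.0,
                              max_generations: int = 1,
                              seed: int = 0) -> nx.Graph:
    """Dendritic network: straight filaments with Poisson-placed branch junctions.

    Junctions occur along every filament as a Poisson process with rate
    ``branch_rate_per_um``; each junction nucleates a daughter filament at
    the branching angle (sides alternate), up to ``max_generations`` of
    daughters. Nodes carry 2D positions (um); edges carry ``length_um``.
    Junction nodes are flagged with ``junction=True``.
    """
    if branch_rate_per_um < 0:
        raise InvalidSpecError("branch_rate_per_um must be >= 0")
    if mother_length_um <= 0 or branch_length_um <= 0:
        raise InvalidSpecError("filament lengths must be > 0")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    next_id = [0]

    def add_node(pos, junction=False):
        nid = next_id[0]
        next_id[0] += 1
        g.add_node(nid, pos=(float(pos[0]), float(pos[1])), junction=junction)
        return nid

    def grow(start_node, direction_deg, length, generation):
        """Lay down one filament from an existing node, inserting junctions."""
        start_pos = np.asarray(g.nodes[start_node]["pos"])
        d = np.radians(direction_deg)
        u = np.array([np.cos(d), np.sin(d)])
        n_j = rng.poisson(branch_rate_per_um * length) if (
            branch_rate_per_um > 0 and generation < max_generations) else 0
        offsets = np.sort(rng.uniform(0.0, length, n_j))
        prev = start_node
        prev_off = 0.0
        side = 1
        daughters = []
        for off in offsets:
            node = add_node(start_pos + off * u, junction=True)
            g.add_edge(prev, node, length_um=float(off - prev_off))
            daughters.append((node, direction_deg + side * branch_angle_deg))
            side = -side
            prev, prev_off = node, off
        end = add_node(start_pos + length * u)
        g.add_edge(prev, end, length_um=float(length - prev_off))
        for node, ang in daughters:
            grow(node, ang, branch_length_um, generation + 1)

    root = add_node(np.zeros(2))
    grow(root, 0.0, mother_length_um, 0)
    return g
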