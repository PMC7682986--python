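"""Recover in-tomogram segment orientations and detect the two polarity modes.

During sub-tomogram reconstruction each segment accumulates a chain of
rotations (pre-alignment, projection, helical refinement). Undoing that
chain places the refined orientation back into the tomogram frame, where
the first Euler rotation about z — the psi angle — separates the two
possible polarities of a filament: per-bundle psi histograms are bimodal
with modes half a turn apart.

Euler convention: ZYZ intrinsic, degrees, with psi the FIRST rotation
about z, i.e. ``R = Rz(psi) @ Ry(tilt) @ Rz(rot)`` acting on column
vectors. All angle I/O is wrapped to [-180, 180).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from polarimap.angles import circular_distance, circular_mean, resultant_length, wrap_angle
from polarimap.errors import InvalidSpecError, InvalidTransformError

__all__ = [
    "SegmentPose",
    "PsiModes",
    "euler_to_rotation",
    "rotation_to_euler",
    "apply_chain",
    "invert_pose_chain",
    "detect_psi_modes",
    "classify_direction",
]


def euler_to_rotation(psi_deg: float, tilt_deg: float, rot_deg: float) -> Rotation:
    """Rotation from ZYZ-intrinsic Euler angles with psi applied first."""
    return Rotation.from_euler("ZYZ", [psi_deg, tilt_deg, rot_deg], degrees=True)


def rotation_to_euler(rotation: Rotation) -> tuple[float, float, float]:
    """(psi, tilt, rot) in degrees, psi wrapped to [-180, 180)."""
    with warnings.catch_warnings():
        # gimbal lock (tilt = 0 or 180) makes psi/rot individually ill-defined;
        # scipy resolves it by zeroing the third angle, which keeps psi usable
        warnings.simplefilter("ignore", UserWarning)
        psi, tilt, rot = rotation.as_euler("ZYZ", degrees=True)
    return float(wrap_angle(psi)), float(tilt), float(rot)


@dataclass
class SegmentPose:
    """One extracted actin segment: where it sits and how it is oriented.

    ``applied_transforms`` is the ordered list of rotations applied to the
    segment during reconstruction (first applied first); each entry is a
    3x3 matrix or a ``scipy`` Rotation.
    """

    tomogram_id: int
    filament_id: int
    segment_id: int
    position_nm: np.ndarray
    euler_deg: tuple[float, float, float]  # (rot, tilt, psi)
    applied_transforms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        if self.position_nm.shape != (3,) or not np.all(np.isfinite(self.position_nm)):
            raise InvalidSpecError("position must be a finite 3-vector in nm")
        rot, tilt, psi = self.euler_deg
        self.euler_deg = (float(rot), float(tilt), float(wrap_angle(psi)))

    @property
    def rotation(self) -> Rotation:
        rot, tilt, psi = self.euler_deg
        return euler_to_rotation(psi, tilt, rot)


def _as_rotation(transform) -> Rotation:
    if isinstance(transform, Rotation):
        return transform
    m = np.asarray(transform, dtype=float)
    if m.shape != (3, 3):
        raise InvalidTransformError(f"transform must be 3x3, got shape {m.shape}")
    if not np.allclose(m @ m.T, np.eye(3), atol=1e-8) or not np.isclose(np.linalg.det(m), 1.0, atol=1e-8):
        raise InvalidTransformError("transform is not a proper orthonormal rotation")
    return Rotation.from_matrix(m)


def apply_chain(rotation: Rotation, transforms) -> Rotation:
    """Apply a transform chain in order: ``R -> Tn @ ... @ T1 @ R``."""
    out = rotation
    for t in transforms:
        out = _as_rotation(t) * out
    return out


def invert_pose_chain(pose: SegmentPose) -> float:
    """In-tomogram psi angle of a segment, by undoing its transform chain.

    The refined pose is ``R_refined = Tn @ ... @ T1 @ R_tomo``; composing
    the inverses in reverse order recovers ``R_tomo``, whose first ZYZ
    Euler rotation about z is returned, wrapped to [-180, 180).
    """
    r = pose.rotation
    for t in reversed(pose.applied_transforms):
        r = _as_rotation(t).inv() * r
    psi, _, _ = rotation_to_euler(r)
    return psi


# ---------------------------------------------------------------------------
# psi-mode detection


@dataclass
class PsiModes:
    """The two circular modes of a bundle's psi distribution.

    ``separation`` is the circular distance between the modes, in [0, 180];
    it is None for a degenerate single-mode bundle. ``concentration`` holds
    the per-mode mean resultant length R (1 = fully concentrated).
    """

    mode_a: float
    mode_b: float | None
    separation: float | None
    concentration: tuple[float, float | None]
    n_a: int
    n_b: int
    single_mode: bool = False


def _vonmises_kde(psi_deg: np.ndarray, bandwidth_deg: float,
                  grid_step_deg: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Circular KDE with a von Mises kernel; kappa = 1/sigma^2 (radians)."""
    kappa = 1.0 / np.radians(bandwidth_deg) ** 2
    grid = np.arange(-180.0, 180.0, grid_step_deg)
    diff = np.radians(grid[:, None] - psi_deg[None, :])
    density = np.exp(kappa * (np.cos(diff) - 1.0)).sum(axis=1)
    return grid, density


def _kde_peaks(grid: np.ndarray, density: np.ndarray) -> list[float]:
    """Local maxima of a circular density, sorted by height (descending)."""
    left, right = np.roll(density, 1), np.roll(density, -1)
    is_peak = (density >= left) & (density > right)
    order = np.argsort(density[is_peak])[::-1]
    return list(grid[is_peak][order])


def detect_psi_modes(psi_values, bandwidth_deg: float = 10.0,
                     min_mode_fraction: float = 0.05,
                     max_iter: int = 100) -> PsiModes:
    """Find the two circular modes of a psi-angle sample.

    A von Mises kernel density estimate (default 10 deg bandwidth) seeds a
    2-cluster circular k-means: points are assigned to the nearer center
    by circular distance, centers are recomputed as circular means, until
    stable. If the smaller cluster carries less than ``min_mode_fraction``
    of the larger one's mass the sample is reported as single-mode (with a
    warning) and the separation is undefined.
    """
    psi = wrap_angle(np.asarray(psi_values, dtype=float))
    if psi.size < 2:
        raise InvalidSpecError("need at least 2 psi values to detect modes")

    grid, density = _vonmises_kde(psi, bandwidth_deg)
    peaks = _kde_peaks(grid, density)
    if len(peaks) < 2:
        center = circular_mean(psi)
        warnings.warn("psi sample is unimodal; polarity modes undefined", stacklevel=2)
        return PsiModes(mode_a=center, mode_b=None, separation=None,
                        concentration=(resultant_length(psi), None),
                        n_a=psi.size, n_b=0, single_mode=True)

    centers = np.array(peaks[:2], dtype=float)
    assign = np.zeros(psi.size, dtype=int)
    for _ in range(max_iter):
        d = np.stack([circular_distance(psi, c) for c in centers])
        new_assign = np.argmin(d, axis=0)
        for j in (0, 1):
            if np.any(new_assign == j):
                centers[j] = circular_mean(psi[new_assign == j])
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign

    n0, n1 = int(np.sum(assign == 0)), int(np.sum(assign == 1))
    if min(n0, n1) < min_mode_fraction * max(n0, n1):
        major = 0 if n0 >= n1 else 1
        warnings.warn("second psi mode carries <5% of the mass; treating as single-mode",
                      stacklevel=2)
        sel = assign == major
        return PsiModes(mode_a=float(centers[major]), mode_b=None, separation=None,
                        concentration=(resultant_length(psi[sel]), None),
                        n_a=int(sel.sum()), n_b=psi.size - int(sel.sum()),
                        single_mode=True)

    # deterministic labelling: A = larger cluster, ties broken by smaller angle
    if (n0, -centers[0]) >= (n1, -centers[1]):
        a, b = 0, 1
    else:
        a, b = 1, 0
    sep = float(circular_distance(centers[a], centers[b]))
    return PsiModes(
        mode_a=float(centers[a]), mode_b=float(centers[b]), separation=sep,
        concentration=(resultant_length(psi[assign == a]),
                       resultant_length(psi[assign == b])),
        n_a=int(np.sum(assign == a)), n_b=int(np.sum(assign == b)))


def classify_direction(psi_deg: float, modes: PsiModes) -> str:
    """Label a segment 'A' or 'B' by the circularly nearer mode; ties -> 'A'."""
    if modes.single_mode or modes.mode_b is None:
        return "A"
    da = circular_distance(psi_deg, modes.mode_a)
    db = circular_distance(psi_deg, modes.mode_b)
    return "A" if da <= db else "B"
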