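"""Deterministic FACT tractography on a per-voxel axial direction field.

FACT (fibre assignment by continuous tracking) propagates a streamline
piecewise-linearly: inside each voxel it travels along that voxel's single
axial direction — sign chosen to keep the turning angle acute — until it
crosses a voxel face, then adopts the next voxel's direction.  Tracking is
bidirectional from every seed; a streamline terminates on leaving the
tracking mask, turning more than the angle threshold, exceeding the maximum
length, or hitting a zero-direction voxel.

Coordinates are physical (x, y, z) μm with voxel centres at integer
multiples of the voxel size (0-based ``(z, y, x)`` array indexing).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from skimage import filters as _skfilters
from skimage import morphology as _skmorph

from .volume import ImageVolume, ROIMask

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TrackingConfig:
    """Streamline propagation and filtering parameters."""

    angle_threshold_deg: float = 60.0
    min_length_um: float | None = None       # default: 10 × voxel size
    max_length_um: float = math.inf
    seed_density: int = 1                     # seeds per mask voxel
    rng_seed: int = 0
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.angle_threshold_deg <= 90:
            raise ValueError("angle_threshold_deg must be in (0, 90]")
        if self.min_length_um is not None and self.min_length_um < 0:
            raise ValueError("min_length_um must be >= 0")
        if self.seed_density < 1:
            raise ValueError("seed_density must be >= 1")


@dataclasses.dataclass
class Streamline:
    """Ordered 3D polyline in physical (x, y, z) μm."""

    points: np.ndarray
    seed_index: int = -1
    reason: str = ""          # mask-exit / angle / length / zero-direction

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("streamline points must be (N, 3)")
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def endpoint_distance(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


# ---------------------------------------------------------------------------
# Masks and seeds
# ---------------------------------------------------------------------------

def make_mask(source: ImageVolume | np.ndarray, method: str | float = "otsu",
              opening_radius: int = 0, closing_radius: int = 0,
              direction: str = "above", voxel_size: float | None = None,
              label: str = "") -> ROIMask:
    """Threshold an intensity or FA volume into a binary ROI mask.

    ``method`` is either ``"otsu"`` or a fixed threshold value; ``direction``
    selects values ``"above"`` (e.g. FA) or ``"below"`` (e.g. dark myelin)
    the threshold.  Binary opening then closing with ball structuring
    elements of the given radii removes small spurious regions and closes
    holes.  Deterministic; an all-true or all-false result warns, it does
    not raise.
    """
    if isinstance(source, ImageVolume):
        data = source.data
        voxel_size = source.voxel_size
    else:
        data = np.asarray(source)
        if voxel_size is None:
            raise ValueError("voxel_size (nm) is required for a bare array")
    if opening_radius < 0 or closing_radius < 0:
        raise ValueError("morphology radii must be >= 0")
    thr = _skfilters.threshold_otsu(data) if method == "otsu" else float(method)
    mask = data > thr if direction == "above" else data < thr
    if opening_radius > 0:
        mask = _skmorph.binary_opening(mask, _skmorph.ball(opening_radius))
    if closing_radius > 0:
        mask = _skmorph.binary_closing(mask, _skmorph.ball(closing_radius))
    if mask.all():
        logger.warning("mask '%s' covers the whole volume", label)
    if not mask.any():
        logger.warning("mask '%s' is empty after thresholding/morphology", label)
        import warnings
        warnings.warn(f"mask '{label}' is empty", stacklevel=2)
    return ROIMask(mask, voxel_size, label=label)


def place_seeds(mask: ROIMask, config: TrackingConfig) -> np.ndarray:
    """Seed points in μm: voxel centres (density 1) or jittered (density > 1)."""
    idx = np.argwhere(mask.data)              # (M, 3) in (z, y, x)
    if len(idx) == 0:
        raise ValueError("cannot seed from an empty mask")
    voxel_um = mask.voxel_size / 1000.0
    centers = idx[:, ::-1].astype(float) * voxel_um     # (x, y, z) μm
    if config.seed_density == 1:
        return centers
    rng = np.random.default_rng(config.rng_seed)
    reps = np.repeat(centers, config.seed_density, axis=0)
    jitter = rng.uniform(-0.5, 0.5, size=reps.shape) * voxel_um
    return reps + jitter


# ---------------------------------------------------------------------------
# FACT propagation
# ---------------------------------------------------------------------------

def _voxel_index(pos_um: np.ndarray, voxel_um: float) -> tuple[int, int, int]:
    """(z, y, x) index of the voxel containing a physical (x, y, z) point.

    Voxel i spans [(i−0.5)·vox, (i+0.5)·vox); exactly-on-face positions
    advance into the voxel with the larger index (floor of pos/vox + 0.5).
    """
    ix = math.floor(pos_um[0] / voxel_um + 0.5)
    iy = math.floor(pos_um[1] / voxel_um + 0.5)
    iz = math.floor(pos_um[2] / voxel_um + 0.5)
    return iz, iy, ix


def _track_half(pos: np.ndarray, init_dir: np.ndarray, directions: np.ndarray,
                mask: np.ndarray, voxel_um: float, cos_thresh: float,
                max_length: float) -> tuple[list[np.ndarray], str]:
    """One propagation direction; returns points after the seed and a reason."""
    shape = mask.shape
    points: list[np.ndarray] = []
    prev = init_dir / np.linalg.norm(init_dir)
    length = 0.0
    pos = pos.copy()
    eps = 1e-6 * voxel_um
    for _ in range(10_000_000):
        iz, iy, ix = _voxel_index(pos, voxel_um)
        if not (0 <= iz < shape[0] and 0 <= iy < shape[1] and 0 <= ix < shape[2]) \
                or not mask[iz, iy, ix]:
            return points, "mask-exit"
        d = directions[iz, iy, ix].astype(float)
        nd = np.linalg.norm(d)
        if nd == 0:
            return points, "zero-direction"
        d = d / nd
        cosang = float(np.dot(d, prev))
        if cosang < 0:
            d = -d
            cosang = -cosang
        if cosang < cos_thresh:
            return points, "angle"
        # distance to the exit face of the current voxel along d
        t = math.inf
        centre = np.array([ix, iy, iz], float) * voxel_um
        for k in range(3):
            if abs(d[k]) < 1e-12:
                continue
            face = centre[k] + (0.5 if d[k] > 0 else -0.5) * voxel_um
            tk = (face - pos[k]) / d[k]
            t = min(t, max(tk, 0.0))
        if not math.isfinite(t):
            return points, "zero-direction"
        step = t + eps
        length += step
        if length > max_length:
            return points, "length"
        pos = pos + d * step
        points.append(pos.copy())
        prev = d
    return points, "length"


def track_fact(directions: np.ndarray, seeds: np.ndarray,
               tracking_mask: ROIMask, config: TrackingConfig
               ) -> list[Streamline]:
    """Deterministic FACT tracking from every seed.

    ``directions`` is a ``(z, y, x, 3)`` axial field in (x, y, z) component
    order.  Seeds outside the tracking mask are skipped with a log entry.
    Bidirectional halves are concatenated through the seed; streamlines
    shorter than the minimum length are discarded.
    """
    if directions.shape[:3] != tracking_mask.shape:
        raise ValueError("direction field and tracking mask grids differ")
    voxel_um = tracking_mask.voxel_size / 1000.0
    min_len = (config.min_length_um if config.min_length_um is not None
               else 10.0 * voxel_um)
    cos_thresh = math.cos(math.radians(config.angle_threshold_deg))
    mask = tracking_mask.data
    shape = mask.shape
    out: list[Streamline] = []
    for si, seed in enumerate(np.atleast_2d(np.asarray(seeds, float))):
        iz, iy, ix = _voxel_index(seed, voxel_um)
        if not (0 <= iz < shape[0] and 0 <= iy < shape[1] and 0 <= ix < shape[2]) \
                or not mask[iz, iy, ix]:
            logger.info("seed %d at %s lies outside the tracking mask; skipped",
                        si, np.round(seed, 2))
            continue
        v0 = directions[iz, iy, ix].astype(float)
        if np.linalg.norm(v0) == 0:
            logger.info("seed %d sits in a zero-direction voxel; skipped", si)
            continue
        fwd, fwd_reason = _track_half(seed, v0, directions, mask, voxel_um,
                                      cos_thresh, config.max_length_um)
        if config.bidirectional:
            bwd, bwd_reason = _track_half(seed, -v0, directions, mask, voxel_um,
                                          cos_thresh, config.max_length_um)
        else:
            bwd, bwd_reason = [], ""
        pts = list(reversed(bwd)) + [seed] + fwd
        if len(pts) < 2:
            continue
        sl = Streamline(np.asarray(pts), seed_index=si,
                        reason=fwd_reason or bwd_reason)
        if sl.length() >= min_len:
            out.append(sl)
    return out


def _visits_mask(streamline: Streamline, mask: ROIMask) -> bool:
    voxel_um = mask.voxel_size / 1000.0
    idx = np.floor(streamline.points[:, ::-1] / voxel_um + 0.5).astype(int)
    shape = mask.shape
    ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    idx = idx[ok]
    if len(idx) == 0:
        return False
    return bool(mask.data[idx[:, 0], idx[:, 1], idx[:, 2]].any())


def apply_roi_filters(streamlines: list[Streamline],
                      inclusion: list[ROIMask] | None = None,
                      rejection: list[ROIMask] | None = None,
                      min_length_um: float = 0.0) -> list[Streamline]:
    """Keep streamlines visiting every inclusion mask, no rejection mask,
    and of at least the minimum length."""
    kept = []
    for sl in streamlines:
        if sl.length() < min_length_um:
            continue
        if any(not _visits_mask(sl, m) for m in inclusion or []):
            continue
        if any(_visits_mask(sl, m) for m in rejection or []):
            continue
        kept.append(sl)
    return kept
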