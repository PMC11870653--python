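"""Synthetic white-matter phantoms with known fibre geometry.

Volumes emulate osmium-stained phase-contrast tomography of white matter:
myelinated fibres appear as dark tubes on a brighter background, cell bodies
and blood vessels as bright spheres/cylinders that deflect nearby fibres, and
demyelinated regions as a locally reduced fibre/background contrast with a
higher cell density.  Every builder returns the rendered image together with
a :class:`GroundTruth` holding the true per-voxel (axial) orientations, the
fibre centreline polylines in μm, and a per-voxel region label map — so each
downstream stage can be validated without external data.

Rendering is anti-aliased: a voxel's intensity is
``background − gap × coverage`` where coverage rises linearly from 0 to 1 as
the tube boundary sweeps across the voxel.  This leaves sub-voxel gradient
information at fibre walls, which the structure tensor needs.

All outputs are deterministic functions of (spec, seed).  Orientations are
axial: ``v`` and ``−v`` are the same truth, and all angle comparisons
downstream use the acute angle.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .volume import ImageVolume, voxel_to_um

BACKGROUND = 0
FIBRE_1 = 1
FIBRE_2 = 2
OBSTACLE = 3
DEMYELINATED = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    FIBRE_1: "fibre population 1",
    FIBRE_2: "fibre population 2",
    OBSTACLE: "obstacle",
    DEMYELINATED: "demyelinated",
}


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomSpec:
    """Declarative description of a synthetic volume.

    Geometry defaults are calibrated to the reported anatomy: laminae up to
    40–45 μm thick with inclination angles up to ~35°, near-orthogonal
    crossings, fibre radii of a couple of μm at ~0.5–1 μm voxel sizes.
    Intensities are arbitrary units with fibre < background (myelin is dark).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1000.0          # nm, isotropic
    fibre_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)   # (x, y, z)
    fibre_radius_um: float | tuple[float, float] = 2.0
    fibre_spacing_um: float | tuple[float, float] = 6.0
    direction_jitter_deg: float | tuple[float, float] = 0.0
    lamina_thickness_um: float = 40.0
    lamina_inclination_deg: float = 35.0
    crossing_angle_deg: float = 90.0
    slab_normal: tuple[float, float, float] | None = None      # auto if None
    fibre_intensity: float = 60.0
    background_intensity: float = 160.0
    noise_sigma: float = 0.0
    rng_seed: int = 0
    jitter_frac: float = 0.15           # lattice jitter as a fraction of spacing

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not (0 < self.fibre_intensity < self.background_intensity):
            raise ValueError("need 0 < fibre_intensity < background_intensity "
                             "(myelin is dark on a bright background)")
        for r in self.radii:
            if r <= 0:
                raise ValueError("fibre radii must be > 0")
        if any(s <= 0 for s in self.spacings) or self.lamina_thickness_um <= 0:
            raise ValueError("spacings and thicknesses must be > 0")
        if not 0 <= self.crossing_angle_deg <= 90:
            raise ValueError("crossing_angle_deg must be in [0, 90]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        n = np.linalg.norm(self.fibre_axis)
        if n == 0:
            raise ValueError("fibre_axis must be nonzero")
        self.fibre_axis = tuple(np.asarray(self.fibre_axis, float) / n)

    @property
    def radii(self) -> tuple[float, ...]:
        r = self.fibre_radius_um
        return tuple(r) if isinstance(r, (tuple, list)) else (float(r),)

    def _per_population(self, value) -> tuple[float, ...]:
        n = len(self.radii)
        if isinstance(value, (tuple, list)):
            return tuple(float(v) for v in value)
        return (float(value),) * n

    @property
    def spacings(self) -> tuple[float, ...]:
        return self._per_population(self.fibre_spacing_um)

    @property
    def jitters_deg(self) -> tuple[float, ...]:
        return self._per_population(self.direction_jitter_deg)

    @property
    def voxel_um(self) -> float:
        return self.voxel_size / 1000.0

    @property
    def intensity_gap(self) -> float:
        return self.background_intensity - self.fibre_intensity

    def check_resolvable(self) -> None:
        min_r = 2.0 * self.voxel_um
        for r in self.radii:
            if r < min_r:
                raise ValueError(
                    f"fibre radius {r} μm is below the resolvable minimum of "
                    f"{min_r} μm (2 voxels at {self.voxel_um} μm voxel size)"
                )


@dataclasses.dataclass
class ObstacleSpec:
    """A bright sphere (cell body) or cylinder (blood vessel).

    Fibre centrelines within ``deflection_halo_um`` of the surface are
    displaced radially away from it; the displacement is
    ``d(r) = R · (R + h − r)/h`` for ``R ≤ r ≤ R + h`` (clipped to ``R``
    inside), applied in the plane perpendicular to the fibre axis, decaying
    smoothly to zero at the halo edge.  This yields maximum deviations on the
    scale of the obstacle radius.
    """

    kind: str                                   # "sphere" or "cylinder"
    center: tuple[float, float, float]          # voxel coordinates (z, y, x)
    radius_um: float
    deflection_halo_um: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)   # (x, y, z), cylinders
    intensity: float | None = None              # bright; default set at render
    deflects: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder"):
            raise ValueError(f"unknown obstacle kind {self.kind!r}")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.deflection_halo_um == 0.0:
            self.deflection_halo_um = self.radius_um
        if self.deflection_halo_um < self.radius_um:
            raise ValueError("deflection_halo_um must be >= radius_um")
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("cylinder axis must be nonzero")
        self.axis = tuple(np.asarray(self.axis, float) / n)

    def center_um(self, voxel_size_nm: float) -> np.ndarray:
        """Obstacle centre in physical (x, y, z) μm."""
        return voxel_to_um(np.asarray(self.center, float), voxel_size_nm)


@dataclasses.dataclass
class FibrePath:
    """A fibre centreline polyline in physical (x, y, z) μm."""

    points: np.ndarray          # (N, 3) μm
    radius_um: float
    population: int = FIBRE_1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a fibre path needs >= 2 (x, y, z) points")


@dataclasses.dataclass
class GroundTruth:
    """True per-voxel orientations, centrelines, and region labels.

    ``orientation`` is an ``(z, y, x, 3)`` field of axial unit vectors in
    (x, y, z) component order, zero outside fibre voxels.  ``labels`` covers
    the grid exactly once with the ``LABEL_NAMES`` ids.  ``render_params``
    retains everything needed to re-render the image bit-for-bit from
    ``fibre_paths``.
    """

    orientation: np.ndarray
    fibre_paths: list[FibrePath]
    labels: np.ndarray
    voxel_size: float
    render_params: dict = dataclasses.field(default_factory=dict)
    axis_distance_um: np.ndarray | None = None   # distance to nearest centreline

    def interior_mask(self, erode_um: float = 1.0) -> np.ndarray:
        """Fibre voxels at least ``erode_um`` inside the tube wall."""
        if self.axis_distance_um is None:
            raise ValueError("no axis distance field recorded")
        radii = np.zeros(self.labels.shape, float)
        fibre = (self.labels == FIBRE_1) | (self.labels == FIBRE_2) | \
                (self.labels == DEMYELINATED)
        # per-voxel radius of the winning path
        rmap = self.render_params.get("radius_map")
        if rmap is None:
            rmap = np.full(self.labels.shape, max(p.radius_um for p in self.fibre_paths))
        radii[fibre] = rmap[fibre]
        return fibre & (self.axis_distance_um <= radii - erode_um)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    th = math.radians(angle_deg)
    axis = np.asarray(axis, float)
    return (v * math.cos(th) + np.cross(axis, v) * math.sin(th)
            + axis * np.dot(axis, v) * (1 - math.cos(th)))


def _perp_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (e1, e2) of the plane ⊥ axis."""
    a = np.asarray(axis, float)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(a, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def _auto_slab_normal(fibre_axis: np.ndarray) -> np.ndarray:
    """Grid axis least aligned with the fibre axis (ties: z, then y, then x)."""
    cands = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]),
             np.array([1.0, 0.0, 0.0])]
    dots = [abs(float(np.dot(fibre_axis, c))) for c in cands]
    return cands[int(np.argmin(dots))]


def axial_unit(v: np.ndarray) -> np.ndarray:
    """Normalise and fix the axial sign: first nonzero component positive."""
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        return v
    v = v / n
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def acute_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Acute angle between axial directions, elementwise over trailing dim 3."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    dots = np.abs(np.sum(a * b, axis=-1))
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip(dots / (na * nb), -1.0, 1.0)
    return np.degrees(np.arccos(c))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_MAX_SEG_VOX = 16.0   # subdivide long segments so bounding boxes stay tight


def _iter_segments(path: FibrePath, voxel_um: float):
    pts = path.points
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        length = np.linalg.norm(b - a)
        nsub = max(1, int(math.ceil(length / (_MAX_SEG_VOX * voxel_um))))
        for j in range(nsub):
            t0, t1 = j / nsub, (j + 1) / nsub
            yield a + (b - a) * t0, a + (b - a) * t1


def _paint_tubes(shape, voxel_um, paths, dist, radius_map, pop_map, tangent):
    """Update per-voxel nearest-centreline fields from tube paths."""
    nz, ny, nx = shape
    for path in paths:
        r = path.radius_um
        for a, b in _iter_segments(path, voxel_um):
            u = b - a
            seg_len2 = float(np.dot(u, u))
            if seg_len2 == 0:
                continue
            margin = r + 1.5 * voxel_um
            lo = np.minimum(a, b) - margin
            hi = np.maximum(a, b) + margin
            # physical (x, y, z) μm -> index ranges (z, y, x)
            ix0, iy0, iz0 = (max(0, int(math.floor(v / voxel_um))) for v in lo)
            ix1, iy1, iz1 = (int(math.ceil(v / voxel_um)) + 1 for v in hi)
            ix1, iy1, iz1 = min(ix1, nx), min(iy1, ny), min(iz1, nz)
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
            zz, yy, xx = np.meshgrid(
                np.arange(iz0, iz1), np.arange(iy0, iy1), np.arange(ix0, ix1),
                indexing="ij",
            )
            pts = np.stack([xx, yy, zz], axis=-1) * voxel_um   # (…, 3) xyz μm
            rel = pts - a
            t = np.clip(np.tensordot(rel, u, axes=([-1], [0])) / seg_len2, 0.0, 1.0)
            proj = a + t[..., None] * u
            d = np.linalg.norm(pts - proj, axis=-1)
            sl = (slice(iz0, iz1), slice(iy0, iy1), slice(ix0, ix1))
            # winner: smallest distance relative to tube surface
            better = (d - r) < (dist[sl] - radius_map[sl])
            if not better.any():
                continue
            dist[sl] = np.where(better, d, dist[sl])
            radius_map[sl] = np.where(better, r, radius_map[sl])
            pop_map[sl] = np.where(better, path.population, pop_map[sl])
            tan = axial_unit(u)
            for c in range(3):
                tangent[sl + (c,)] = np.where(better, tan[c], tangent[sl + (c,)])


def _paint_obstacle_distance(shape, voxel_um, obstacle: ObstacleSpec,
                             voxel_size_nm: float) -> np.ndarray:
    """Distance from every voxel centre to the obstacle axis/centre (μm)."""
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1) * voxel_um
    c = obstacle.center_um(voxel_size_nm)
    rel = pts - c
    if obstacle.kind == "sphere":
        return np.linalg.norm(rel, axis=-1)
    ax = np.asarray(obstacle.axis, float)
    rel_perp = rel - np.tensordot(rel, ax, axes=([-1], [0]))[..., None] * ax
    return np.linalg.norm(rel_perp, axis=-1)


def render(truth_paths: list[FibrePath], grid_shape, voxel_size_nm: float,
           background_intensity: float, fibre_intensity: float,
           obstacles: list[ObstacleSpec] | None = None,
           demyelination: list[dict] | None = None,
           ) -> tuple[ImageVolume, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render an image volume from fibre centrelines (+ obstacles, pathology).

    Returns ``(volume, labels, orientation, axis_distance, radius_map)``.
    Deterministic; re-rendering from the same inputs is bit-identical.
    """
    voxel_um = voxel_size_nm / 1000.0
    shape = tuple(grid_shape)
    dist = np.full(shape, np.inf, dtype=np.float64)
    radius_map = np.zeros(shape, dtype=np.float64)
    pop_map = np.zeros(shape, dtype=np.int16)
    tangent = np.zeros(shape + (3,), dtype=np.float64)

    _paint_tubes(shape, voxel_um, truth_paths, dist, radius_map, pop_map, tangent)

    gap = background_intensity - fibre_intensity
    with np.errstate(invalid="ignore"):
        coverage = np.clip((radius_map - dist) / voxel_um + 0.5, 0.0, 1.0)
    coverage[~np.isfinite(dist)] = 0.0
    image = background_intensity - gap * coverage

    labels = np.where(dist <= radius_map, pop_map, BACKGROUND).astype(np.int16)
    orientation = np.where((labels > 0)[..., None], tangent, 0.0)

    # demyelination: scale the fibre/background gap inside each region,
    # applied before obstacle/cell painting (cells stay fully bright)
    demyelination = demyelination or []
    for dm in demyelination:
        (z0, z1), (y0, y1), (x0, x1) = dm["region"]
        sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        image[sl] = background_intensity - \
            (background_intensity - image[sl]) * dm["contrast_factor"]
        reg_fibre = labels[sl] > 0
        labels[sl][reg_fibre] = DEMYELINATED

    for obs in obstacles or []:
        od = _paint_obstacle_distance(shape, voxel_um, obs, voxel_size_nm)
        intensity = obs.intensity
        if intensity is None:
            intensity = background_intensity + 0.5 * gap
        cov = np.clip((obs.radius_um - od) / voxel_um + 0.5, 0.0, 1.0)
        image = image * (1 - cov) + intensity * cov
        inside = od <= obs.radius_um
        labels[inside] = OBSTACLE
        orientation[inside] = 0.0

    vol = ImageVolume(image, voxel_size_nm, provenance="phantom")
    return vol, labels, orientation, dist, radius_map


def _finalise(spec: PhantomSpec, paths: list[FibrePath],
              obstacles: list[ObstacleSpec] | None = None,
              demyelination: list[dict] | None = None,
              ) -> tuple[ImageVolume, GroundTruth]:
    vol, labels, orientation, dist, radius_map = render(
        paths, spec.grid_shape, spec.voxel_size,
        spec.background_intensity, spec.fibre_intensity,
        obstacles=obstacles, demyelination=demyelination,
    )
    truth = GroundTruth(
        orientation=orientation,
        fibre_paths=paths,
        labels=labels,
        voxel_size=spec.voxel_size,
        render_params={
            "grid_shape": tuple(spec.grid_shape),
            "background_intensity": spec.background_intensity,
            "fibre_intensity": spec.fibre_intensity,
            "obstacles": list(obstacles or []),
            "demyelination": list(demyelination or []),
            "radius_map": radius_map,
        },
        axis_distance_um=dist,
    )
    return vol, truth


def rerender(truth: GroundTruth) -> ImageVolume:
    """Re-render the image volume from the ground-truth fibre paths."""
    rp = truth.render_params
    vol, _, _, _, _ = render(
        truth.fibre_paths, rp["grid_shape"], truth.voxel_size,
        rp["background_intensity"], rp["fibre_intensity"],
        obstacles=rp.get("obstacles"), demyelination=rp.get("demyelination"),
    )
    return vol


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _lattice_2d(extent1: float, extent2: float, spacing: float, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    """Jittered square lattice covering [0, extent1] × [0, extent2] (μm)."""
    u1 = np.arange(spacing / 2.0, extent1, spacing)
    u2 = np.arange(spacing / 2.0, extent2, spacing)
    g1, g2 = np.meshgrid(u1, u2, indexing="ij")
    pts = np.stack([g1.ravel(), g2.ravel()], axis=-1)
    if jitter > 0 and len(pts):
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def _line_path(centre: np.ndarray, direction: np.ndarray, extent_um: np.ndarray,
               radius: float, population: int) -> FibrePath | None:
    """Clip an infinite line to the volume's bounding box (with margin)."""
    d = np.asarray(direction, float)
    lo = -np.full(3, 2.0)
    hi = extent_um + 2.0
    tmin, tmax = -np.inf, np.inf
    for k in range(3):
        if abs(d[k]) < 1e-12:
            if not (lo[k] <= centre[k] <= hi[k]):
                return None
        else:
            t0 = (lo[k] - centre[k]) / d[k]
            t1 = (hi[k] - centre[k]) / d[k]
            tmin = max(tmin, min(t0, t1))
            tmax = min(tmax, max(t0, t1))
    if tmax <= tmin:
        return None
    pts = np.stack([centre + tmin * d, centre + tmax * d])
    return FibrePath(pts, radius, population)


def build_parallel_fibre_volume(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Dense parallel fibres along ``spec.fibre_axis``.

    Emulates a corpus-callosum-like region: densely packed dark tubes on a
    jittered square lattice, all sharing one axial direction.  With two radii
    in ``fibre_radius_um``, the cross-section is split into two halves along
    the first perpendicular lattice axis, one radius (and population label)
    per half — the scale-selection test phantom.
    """
    spec.check_resolvable()
    rng = np.random.default_rng(spec.rng_seed)
    axis = np.asarray(spec.fibre_axis, float)
    e1, e2 = _perp_basis(axis)
    nz, ny, nx = spec.grid_shape
    extent = np.array([nx, ny, nz], float) * spec.voxel_um   # (x, y, z) μm

    # lattice extents: project the volume box onto e1/e2
    corners = np.array([[x, y, z] for x in (0, extent[0]) for y in (0, extent[1])
                        for z in (0, extent[2])])
    p1 = corners @ e1
    p2 = corners @ e2
    radii = spec.radii
    spacings = spec.spacings
    jitters = spec.jitters_deg
    span1 = p1.max() - p1.min()
    span2 = p2.max() - p2.min()
    n_pop = len(radii)
    paths: list[FibrePath] = []
    for ip in range(n_pop):
        r, spacing, jdeg = radii[ip], spacings[ip], jitters[ip]
        pop = FIBRE_1 if ip == 0 else FIBRE_2
        # each population occupies an equal band of the e1 extent
        u0, u1 = span1 * ip / n_pop, span1 * (ip + 1) / n_pop
        jit = min(spec.jitter_frac * spacing,
                  max(0.0, (spacing - 2 * r) / 2.0 - 0.25))
        lat = _lattice_2d(u1 - u0, span2, spacing, jit, rng)
        for (u, v) in lat:
            d = axis
            if jdeg > 0:
                # tilt about e1 so each fibre stays inside its population band
                d = axial_unit(_rotate(axis, e1, rng.normal(0.0, jdeg)))
            centre = (p1.min() + u0 + u) * e1 + (p2.min() + v) * e2
            path = _line_path(centre, d, extent, r, pop)
            if path is not None:
                paths.append(path)
    vol, truth = _finalise(spec, paths)
    if spec.noise_sigma > 0:
        vol = add_imaging_noise(vol, spec.noise_sigma, spec.rng_seed)
    return vol, truth


def _slab_builder(spec: PhantomSpec, angle_between_deg: float,
                  pop_labels: tuple[int, int]) -> tuple[ImageVolume, GroundTruth]:
    """Shared machinery for laminar and crossing phantoms.

    Alternating slabs stacked along ``slab_normal``; fibre directions of
    adjacent slabs are ``spec.fibre_axis`` rotated about the normal by
    ``±angle/2`` so they differ by exactly ``angle_between_deg`` while both
    stay in the plane containing the fibre axis.
    """
    spec.check_resolvable()
    rng = np.random.default_rng(spec.rng_seed)
    axis = np.asarray(spec.fibre_axis, float)
    normal = (np.asarray(spec.slab_normal, float) if spec.slab_normal is not None
              else _auto_slab_normal(axis))
    normal = normal / np.linalg.norm(normal)
    if abs(np.dot(axis, normal)) > 1e-9:
        raise ValueError("slab normal must be perpendicular to the fibre axis")
    d0 = axial_unit(_rotate(axis, normal, +angle_between_deg / 2.0))
    d1 = axial_unit(_rotate(axis, normal, -angle_between_deg / 2.0))

    nz, ny, nx = spec.grid_shape
    extent = np.array([nx, ny, nz], float) * spec.voxel_um
    thick = spec.lamina_thickness_um
    n_extent = float(extent @ np.abs(normal))
    n_slabs = int(math.ceil(n_extent / thick))
    r = spec.radii[0]
    spacing = spec.fibre_spacing_um
    paths: list[FibrePath] = []
    for k in range(n_slabs):
        d = d0 if k % 2 == 0 else d1
        pop = pop_labels[k % 2]
        e_across = np.cross(normal, d)
        e_across /= np.linalg.norm(e_across)
        # rows within the slab along the normal, columns across the slab
        w0, w1 = k * thick, min((k + 1) * thick, n_extent)
        rows = np.arange(w0 + spacing / 2.0, w1, spacing)
        if len(rows) == 0:
            rows = np.array([(w0 + w1) / 2.0])
        corners = np.array([[x, y, z] for x in (0, extent[0])
                            for y in (0, extent[1]) for z in (0, extent[2])])
        pa = corners @ e_across
        cols = np.arange(pa.min() + spacing / 2.0, pa.max(), spacing)
        jit = min(spec.jitter_frac * spacing,
                  max(0.0, (spacing - 2 * r) / 2.0 - 0.25))
        for w in rows:
            for c in cols:
                cj = c + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
                wj = np.clip(w + (rng.uniform(-jit, jit) if jit > 0 else 0.0),
                             w0 + r, max(w0 + r, w1 - r))
                centre = wj * normal + cj * e_across
                path = _line_path(centre, d, extent, r, pop)
                if path is not None:
                    paths.append(path)
    vol, truth = _finalise(spec, paths)
    truth.render_params["slab_directions"] = (d0, d1)
    truth.render_params["slab_normal"] = normal
    if spec.noise_sigma > 0:
        vol = add_imaging_noise(vol, spec.noise_sigma, spec.rng_seed)
    return vol, truth


def build_laminar_volume(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Alternating laminae whose fibre directions differ by the inclination.

    Slabs of ``lamina_thickness_um`` are stacked along the slab normal;
    adjacent slabs' directions differ by ``lamina_inclination_deg`` (both in
    the plane containing ``fibre_axis``).  Inclination 0° degenerates to a
    parallel phantom organised in slabs.
    """
    if not 0 <= spec.lamina_inclination_deg < 90:
        raise ValueError("lamina_inclination_deg must be in [0, 90)")
    return _slab_builder(spec, spec.lamina_inclination_deg, (FIBRE_1, FIBRE_2))


def build_crossing_volume(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Two interleaved laminar populations crossing at ``crossing_angle_deg``."""
    if spec.crossing_angle_deg <= 0:
        raise ValueError("crossing_angle_deg must be > 0 for a crossing phantom")
    return _slab_builder(spec, spec.crossing_angle_deg, (FIBRE_1, FIBRE_2))


# ---------------------------------------------------------------------------
# Obstacles, pathology, noise
# ---------------------------------------------------------------------------

def _densify(path: FibrePath, step_um: float) -> FibrePath:
    pts = path.points
    out = [pts[0]]
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        seg = np.linalg.norm(b - a)
        n = max(1, int(math.ceil(seg / step_um)))
        for j in range(1, n + 1):
            out.append(a + (b - a) * (j / n))
    return FibrePath(np.asarray(out), path.radius_um, path.population)


def deflect_path(path: FibrePath, obstacles: list[ObstacleSpec],
                 voxel_size_nm: float, step_um: float) -> FibrePath:
    """Displace a centreline radially away from obstacle surfaces.

    ``d(r) = R · (R + h − r)/h`` for ``R ≤ r ≤ R + h`` (clipped to ``R``
    inside the obstacle), zero beyond the halo, applied in the plane
    perpendicular to the fibre's overall axis.  Paths entirely outside every
    halo are returned unchanged (same object).
    """
    fibre_dir = axial_unit(path.points[-1] - path.points[0])
    probe = _densify(path, max(step_um, 1.0)).points
    relevant = []
    for obs in obstacles:
        if not obs.deflects:
            continue
        reach = obs.radius_um + obs.deflection_halo_um + path.radius_um
        c = obs.center_um(voxel_size_nm)
        # bounding check against a densely sampled undisplaced polyline
        d = _point_line_distances(probe, obs, c)
        if np.min(d) < reach:
            relevant.append((obs, c))
    if not relevant:
        return path
    dense = _densify(path, step_um)
    pts = dense.points.copy()
    for obs, c in relevant:
        R, h = obs.radius_um, obs.deflection_halo_um
        rel = pts - c
        if obs.kind == "cylinder":
            ax = np.asarray(obs.axis, float)
            rel = rel - np.outer(rel @ ax, ax)
        # r is the true distance to the obstacle axis/centre; the
        # displacement direction lies in the plane ⊥ the fibre axis
        r = np.linalg.norm(rel, axis=1)
        rel_perp = rel - np.outer(rel @ fibre_dir, fibre_dir)
        amount = R * np.clip((R + h - r) / h, 0.0, 1.0)
        active = (r < R + h) & (amount > 0)
        perp_norm = np.linalg.norm(rel_perp, axis=1)
        safe = np.where(perp_norm > 1e-9, perp_norm, 1.0)
        direction = rel_perp / safe[:, None]
        # degenerate: radial direction parallel to the fibre — push along a
        # fixed normal instead
        deg = active & (perp_norm <= 1e-9)
        if deg.any():
            fallback = _perp_basis(fibre_dir)[0]
            direction[deg] = fallback
        pts[active] += amount[active, None] * direction[active]
    return FibrePath(pts, path.radius_um, path.population)


def _point_line_distances(points: np.ndarray, obs: ObstacleSpec,
                          center_um: np.ndarray) -> np.ndarray:
    rel = points - center_um
    if obs.kind == "cylinder":
        ax = np.asarray(obs.axis, float)
        rel = rel - np.outer(rel @ ax, ax)
    return np.linalg.norm(rel, axis=1)


def insert_obstacles(volume: ImageVolume, truth: GroundTruth,
                     obstacles: list[ObstacleSpec]) -> tuple[ImageVolume, GroundTruth]:
    """Add bright obstacles and deflect nearby fibres around them.

    Fibre centrelines within each obstacle's halo are displaced radially away
    from its surface (see :func:`deflect_path`); the image is re-rendered from
    the deflected centrelines and the obstacles painted on top.
    """
    if not obstacles:
        return volume, truth
    rp = truth.render_params
    shape = rp["grid_shape"]
    voxel_um = truth.voxel_size / 1000.0
    extent = np.array([shape[2], shape[1], shape[0]], float) * voxel_um
    for obs in obstacles:
        c = obs.center_um(truth.voxel_size)
        if np.any(c < 0) or np.any(c > extent):
            raise ValueError(f"obstacle centre {obs.center} is outside the grid")
        # an obstacle must leave room for fibres to pass in the cross-section
        perp_extents = []
        fibre_dir = axial_unit(truth.fibre_paths[0].points[-1]
                               - truth.fibre_paths[0].points[0]) \
            if truth.fibre_paths else np.array([1.0, 0.0, 0.0])
        for k, e in enumerate(np.eye(3)):
            if abs(np.dot(e, fibre_dir)) < 0.9:
                perp_extents.append(extent[k])
        if perp_extents and 2 * obs.radius_um >= min(perp_extents):
            raise ValueError(
                f"obstacle of radius {obs.radius_um} μm covers the entire "
                f"cross-section (min perpendicular extent "
                f"{min(perp_extents):.1f} μm)"
            )
    step = voxel_um
    new_paths = [deflect_path(p, obstacles, truth.voxel_size, step)
                 for p in truth.fibre_paths]
    all_obstacles = list(rp.get("obstacles", [])) + list(obstacles)
    vol, labels, orientation, dist, radius_map = render(
        new_paths, shape, truth.voxel_size,
        rp["background_intensity"], rp["fibre_intensity"],
        obstacles=all_obstacles, demyelination=rp.get("demyelination"),
    )
    new_rp = dict(rp)
    new_rp["obstacles"] = all_obstacles
    new_rp["radius_map"] = radius_map
    new_truth = GroundTruth(orientation, new_paths, labels, truth.voxel_size,
                            new_rp, axis_distance_um=dist)
    return vol, new_truth


def apply_demyelination(volume: ImageVolume, truth: GroundTruth,
                        region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
                        contrast_factor: float,
                        extra_cell_density: float = 0.0,
                        cell_radius_um: float = 3.0,
                        rng_seed: int = 0) -> tuple[ImageVolume, GroundTruth]:
    """Emulate a focal demyelination lesion inside a box region.

    The fibre/background intensity gap inside ``region`` (voxel index ranges
    ``((z0, z1), (y0, y1), (x0, x1))``) is multiplied by ``contrast_factor``
    (≤ 1, brighter = less myelin contrast) and bright cell-body spheres are
    added at ``extra_cell_density`` per mm³.  Ground-truth orientations are
    preserved — the fibres are still there, just less contrasted — and fibre
    voxels inside the region are re-labelled ``DEMYELINATED``.
    """
    if not 0 < contrast_factor <= 1:
        raise ValueError("contrast_factor must be in (0, 1]")
    shape = truth.render_params["grid_shape"]
    (z0, z1), (y0, y1), (x0, x1) = region
    if not (0 <= z0 < z1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
            and 0 <= x0 < x1 <= shape[2]):
        raise ValueError(f"region {region} is outside the grid {shape}")
    if contrast_factor == 1.0 and extra_cell_density == 0:
        return volume, truth

    voxel_um = truth.voxel_size / 1000.0
    rng = np.random.default_rng(rng_seed)
    region_mm3 = ((z1 - z0) * (y1 - y0) * (x1 - x0)) * (voxel_um * 1e-3) ** 3
    n_cells = int(round(extra_cell_density * region_mm3))
    cells = []
    rp = truth.render_params
    gap = rp["background_intensity"] - rp["fibre_intensity"]
    for _ in range(n_cells):
        czyx = rng.uniform([z0, y0, x0], [z1, y1, x1])
        cells.append(ObstacleSpec(
            kind="sphere", center=tuple(czyx), radius_um=cell_radius_um,
            deflection_halo_um=cell_radius_um,
            intensity=rp["background_intensity"] + 0.4 * gap,
            deflects=False,
        ))
    demy = list(rp.get("demyelination", []))
    demy.append({"region": region, "contrast_factor": contrast_factor})
    all_obstacles = list(rp.get("obstacles", [])) + cells
    vol, labels, orientation, dist, radius_map = render(
        truth.fibre_paths, shape, truth.voxel_size,
        rp["background_intensity"], rp["fibre_intensity"],
        obstacles=all_obstacles, demyelination=demy,
    )
    new_rp = dict(rp)
    new_rp["obstacles"] = all_obstacles
    new_rp["demyelination"] = demy
    new_rp["radius_map"] = radius_map
    new_truth = GroundTruth(orientation, truth.fibre_paths, labels,
                            truth.voxel_size, new_rp, axis_distance_um=dist)
    return vol, new_truth


def build_scale_test_volume(grid: int = 96, voxel_size_nm: float = 500.0,
                            rng_seed: int = 5, noise_sigma: float = 5.0
                            ) -> tuple[ImageVolume, GroundTruth]:
    """Two-population phantom for dominant-scale selection tests.

    One band of thin (1 μm radius), densely packed axons with realistic
    micro-dispersion (~15° angular jitter) and a higher density of bright
    cell bodies (~10 % volume), next to a band of thick (4 μm) well-aligned
    fasciculi without extra-axonal cells — mirroring the reported asymmetry
    of cell/vessel content between pathways.  At a large analysis scale the
    thin axons' contrast washes out and cell surfaces dominate, at a small
    scale the thick fasciculi's interiors carry no gradient, so the dominant
    scale separates the two regions.
    """
    spec = PhantomSpec(grid_shape=(grid,) * 3, voxel_size=voxel_size_nm,
                       fibre_radius_um=(1.0, 4.0),
                       fibre_spacing_um=(2.5, 10.0),
                       direction_jitter_deg=(15.0, 2.0),
                       rng_seed=rng_seed)
    vol, truth = build_parallel_fibre_volume(spec)
    extent = grid * spec.voxel_um
    margin = 8 * spec.voxel_um
    # locate the thin band (population 1) along y from the labels
    thin_y = np.argwhere(truth.labels == FIBRE_1)[:, 1].mean() * spec.voxel_um
    half = extent / 2.0
    lo, hi = ((half + margin, extent - margin) if thin_y > half
              else (margin, half - margin))
    rng = np.random.default_rng(rng_seed + 1)
    vox = spec.voxel_um
    cells = [ObstacleSpec(
        kind="sphere",
        center=(float(rng.uniform(margin, extent - margin) / vox),
                float(rng.uniform(lo, hi) / vox),
                float(rng.uniform(margin, extent - margin) / vox)),
        radius_um=float(rng.uniform(2.5, 4.0)), deflects=False)
        for _ in range(60)]
    vol, truth = insert_obstacles(vol, truth, cells)
    if noise_sigma > 0:
        vol = add_imaging_noise(vol, noise_sigma, rng_seed)
    return vol, truth


#: canonical (σ, ρ) pair for the scale-selectivity analysis: one fine and
#: one coarse integration scale, in voxels
SCALE_TEST_SCALES = ((0.5, 1.0), (3.0, 6.0))


def add_imaging_noise(volume: ImageVolume, noise_sigma: float,
                      rng_seed: int) -> ImageVolume:
    """Add independent zero-mean Gaussian noise, deterministic given the seed."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(rng_seed)
    noisy = volume.data + rng.normal(0.0, noise_sigma, size=volume.data.shape)
    return ImageVolume(noisy, volume.voxel_size,
                       f"{volume.provenance} [noise σ={noise_sigma}]".strip())
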