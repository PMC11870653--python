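"""Scale-space 3D structure tensor estimation and diffusion-like conversion.

The structure tensor at a voxel is the Gaussian(ρ)-weighted local average of
the outer product ``g gᵀ`` of the Gaussian(σ)-derivative image gradient.  Its
eigenvalues are large across strong edges, so for a fibre the *smallest*
eigenvalue's eigenvector points along the fibre.  To reuse diffusion-tensor
conventions (principal eigenvector = fibre direction, FA formula) the raw
eigenvalues λ* (normalised to sum 1) are converted through the single-γ
model ``λi = exp(−λi*/γ)`` and renormalised to sum 1, which inverts the
ordering.

A suite of (σ, ρ) *scales* can be evaluated; each voxel then keeps the scale
with the largest scale-normalised FA,
``d_j = argmax_i( FA_ji / max_j(FA_ji) )``,
making the derived quantities independent of fibre diameter.

Kernel bookkeeping: Gaussian integration kernels are truncated at radius
``ceil(2ρ)`` voxels (derivative kernels at ``ceil(4σ)``), and the physical
"kernel size" quoted for a scale is the full width
``(2·ceil(2ρ)+1) · effective voxel size``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

logger = logging.getLogger(__name__)

#: (ρ, σ) suites in voxels used for multi-scale analysis (monkey ESRF data).
DEFAULT_RHO = (5.50, 4.50, 3.50, 3.50, 2.50, 2.50, 1.50, 1.00)
DEFAULT_SIGMA = (3.00, 2.75, 2.50, 1.50, 1.50, 1.00, 1.00, 0.50)
DEFAULT_GAMMA = 0.30


@dataclasses.dataclass
class ScaleParams:
    """An ordered suite of (σ, ρ) scales plus the γ conversion parameter."""

    scales: tuple[tuple[float, float], ...] = tuple(zip(DEFAULT_SIGMA, DEFAULT_RHO))
    gamma: float = DEFAULT_GAMMA
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        self.scales = tuple((float(s), float(r)) for s, r in self.scales)
        if not self.scales:
            raise ValueError("at least one (sigma, rho) scale is required")
        for s, r in self.scales:
            if s <= 0 or r <= 0:
                raise ValueError(f"sigma and rho must be > 0, got ({s}, {r})")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


def kernel_size_um(rho_voxels: float, voxel_size_nm: float,
                   scaling_factor: int = 1) -> float:
    """Physical full width of the ρ integration kernel in μm.

    The kernel is truncated at radius ``ceil(2ρ)`` voxels, so its full width
    is ``2·ceil(2ρ)+1`` voxels at the effective (downsampled) voxel size.
    """
    if rho_voxels <= 0 or voxel_size_nm <= 0 or scaling_factor < 1:
        raise ValueError("rho, voxel size and scaling factor must be positive")
    width_voxels = 2 * math.ceil(2 * rho_voxels) + 1
    return width_voxels * voxel_size_nm * scaling_factor / 1000.0


# ---------------------------------------------------------------------------
# Tensor and eigen containers
# ---------------------------------------------------------------------------

#: component order of the six unique tensor entries
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclasses.dataclass
class TensorField:
    """Per-voxel symmetric 3×3 structure tensors (six unique components)."""

    components: np.ndarray      # (z, y, x, 6) in TENSOR_COMPONENTS order
    voxel_size: float           # nm
    sigma: float                # voxels
    rho: float                  # voxels
    scale_id: int = 0
    zero_tol: float = 0.0       # trace at/below this is a zero tensor

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]  # type: ignore[return-value]

    def matrices(self) -> np.ndarray:
        """Full (…, 3, 3) symmetric matrices."""
        c = self.components
        m = np.empty(c.shape[:3] + (3, 3), dtype=c.dtype)
        m[..., 0, 0], m[..., 1, 1], m[..., 2, 2] = c[..., 0], c[..., 1], c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    def border_width(self) -> int:
        """Voxels within one ρ-kernel radius of the border are unreliable."""
        return math.ceil(2 * self.rho)

    def border_mask(self) -> np.ndarray:
        w = self.border_width()
        mask = np.ones(self.shape, dtype=bool)
        if all(s > 2 * w for s in self.shape):
            mask[w:-w, w:-w, w:-w] = False
        return mask


@dataclasses.dataclass
class EigenField:
    """Sorted eigen-decomposition of a tensor field.

    ``raw`` holds λ1* ≥ λ2* ≥ λ3* ≥ 0 normalised to sum 1 off ``zero_mask``;
    ``vectors[..., k, :]`` is the orthonormal (x, y, z) eigenvector paired
    with raw λ*_{k+1}.  After :func:`convert_eigenvalues`, ``converted``
    holds λ1 ≥ λ2 ≥ λ3 (sum 1) and the principal (fibre) direction is the
    eigenvector of the *smallest* raw eigenvalue.
    """

    raw: np.ndarray                     # (z, y, x, 3) descending
    vectors: np.ndarray                 # (z, y, x, 3, 3), raw-descending order
    zero_mask: np.ndarray               # (z, y, x) bool
    voxel_size: float
    scale_id: int = 0
    sigma: float = 0.0
    rho: float = 0.0
    converted: np.ndarray | None = None  # (z, y, x, 3) descending
    fa: np.ndarray | None = None         # (z, y, x)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.raw.shape[:3]  # type: ignore[return-value]

    def principal_direction(self) -> np.ndarray:
        """Axial fibre direction per voxel: eigenvector of the smallest raw λ*."""
        return self.vectors[..., 2, :]

    def border_mask(self) -> np.ndarray:
        w = math.ceil(2 * self.rho)
        mask = np.ones(self.shape, dtype=bool)
        if w > 0 and all(s > 2 * w for s in self.shape):
            mask[w:-w, w:-w, w:-w] = False
        elif w == 0:
            mask[:] = False
        return mask


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _truncate_for_radius(std: float, radius: int) -> float:
    """scipy's gaussian_filter truncates at round(truncate*std); pick truncate
    so the kernel radius is exactly the requested voxel count."""
    return radius / std


def compute_structure_tensor(volume: ImageVolume, sigma: float, rho: float,
                             scale_id: int = 0) -> TensorField:
    """Three-step structure tensor: gradient, outer product, ρ-aggregation.

    Gradients use Gaussian(σ)-derivative filtering, aggregation a Gaussian(ρ)
    kernel; both separable, with mirror-reflection boundary handling.
    Kernels are truncated at radius ``ceil(4σ)`` / ``ceil(2ρ)`` voxels.
    """
    if sigma <= 0 or rho <= 0:
        raise ValueError("sigma and rho must be > 0")
    grad_radius = math.ceil(4 * sigma)
    agg_radius = math.ceil(2 * rho)
    needed = 2 * max(grad_radius, agg_radius) + 1
    if min(volume.shape) < needed:
        raise ValueError(
            f"volume shape {volume.shape} is smaller than the kernel support; "
            f"need at least {needed} voxels per axis for sigma={sigma}, rho={rho}"
        )
    data = np.asarray(volume.data, dtype=np.float64)
    t_grad = _truncate_for_radius(sigma, grad_radius)
    t_agg = _truncate_for_radius(rho, agg_radius)

    # gradient components in (x, y, z) order; array axes are (z, y, x)
    grads = []
    for axis in (2, 1, 0):
        order = [0, 0, 0]
        order[axis] = 1
        grads.append(ndimage.gaussian_filter(
            data, sigma=sigma, order=tuple(order), mode="mirror",
            truncate=t_grad))
    gx, gy, gz = grads

    pairs = [(gx, gx), (gy, gy), (gz, gz), (gx, gy), (gx, gz), (gy, gz)]
    comps = np.empty(data.shape + (6,), dtype=np.float64)
    for k, (a, b) in enumerate(pairs):
        comps[..., k] = ndimage.gaussian_filter(a * b, sigma=rho, mode="mirror",
                                                truncate=t_agg)
    zero_tol = 1e-12 * float(np.var(data))
    return TensorField(comps, volume.voxel_size, sigma=sigma, rho=rho,
                       scale_id=scale_id, zero_tol=zero_tol)


def _fix_vector_signs(vectors: np.ndarray) -> np.ndarray:
    """Axial sign convention: first nonzero component positive (vectorised)."""
    tol = 1e-12
    x, y, z = vectors[..., 0], vectors[..., 1], vectors[..., 2]
    s = np.where(np.abs(x) > tol, np.sign(x),
                 np.where(np.abs(y) > tol, np.sign(y), np.sign(z)))
    s = np.where(s == 0, 1.0, s)
    return vectors * s[..., None]


def eigendecompose_field(tensors: TensorField) -> EigenField:
    """Sorted eigen-decomposition; raw eigenvalues clipped at 0, sum-normalised.

    Voxels whose tensor trace is at/below the zero tolerance get the
    ``zero_mask`` flag (their eigenvalues are left as 1/3 isotropic
    placeholders and excluded from statistics).
    """
    mats = tensors.matrices()
    w, v = np.linalg.eigh(mats)          # ascending eigenvalues; v[..., :, i]
    # raw descending: reverse
    raw = w[..., ::-1]
    vecs = np.swapaxes(v, -1, -2)[..., ::-1, :]   # vecs[..., k, :] ↔ raw[..., k]
    raw = np.clip(raw, 0.0, None)
    trace = raw.sum(axis=-1)
    zero_mask = trace <= tensors.zero_tol
    safe = np.where(zero_mask, 1.0, trace)
    raw = raw / safe[..., None]
    raw[zero_mask] = 1.0 / 3.0
    vecs = _fix_vector_signs(vecs)
    return EigenField(raw=raw, vectors=vecs, zero_mask=zero_mask,
                      voxel_size=tensors.voxel_size, scale_id=tensors.scale_id,
                      sigma=tensors.sigma, rho=tensors.rho)


def convert_eigenvalues(eigen: EigenField, gamma: float) -> EigenField:
    """Convert to a diffusion-like tensor via λi = exp(−λi*/γ), renormalised.

    ``exp(−x/γ)`` is decreasing, so the converted ordering is the reverse of
    the raw ordering: the fibre direction (smallest raw λ*) is paired with
    the largest converted λ.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    lam = np.exp(-eigen.raw / gamma)
    lam = lam / lam.sum(axis=-1, keepdims=True)
    eigen.converted = lam[..., ::-1].copy()      # descending converted order
    return eigen


def fractional_anisotropy(eigen: EigenField) -> np.ndarray:
    """FA of the converted eigenvalues; 0 on the zero mask by convention."""
    if eigen.converted is None:
        raise ValueError("convert_eigenvalues must run before FA")
    lam = eigen.converted
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(eigen.zero_mask, 0.0, np.clip(fa, 0.0, 1.0))
    eigen.fa = fa
    return fa


@dataclasses.dataclass
class DominantScaleMap:
    """Per-voxel winning scale index and its normalised FA score."""

    index: np.ndarray       # (z, y, x) int
    score: np.ndarray       # (z, y, x) float
    n_scales: int


def scale_space_select(per_scale: list[EigenField],
                       params: ScaleParams) -> tuple[EigenField, DominantScaleMap]:
    """Pick, per voxel, the scale with the largest scale-normalised FA.

    Each scale's FA map is normalised by that scale's maximum FA over all
    voxels; the scale with the largest normalised value wins, ties going to
    the lowest scale index.  A scale whose maximum FA is 0 contributes score
    0 everywhere.
    """
    if not per_scale:
        raise ValueError("need at least one EigenField")
    shape = per_scale[0].shape
    for ef in per_scale:
        if ef.shape != shape or ef.voxel_size != per_scale[0].voxel_size:
            raise ValueError("all scales must share grid and voxel size")
        if ef.fa is None:
            raise ValueError("FA must be computed for every scale first")

    scores = np.empty((len(per_scale),) + shape)
    for i, ef in enumerate(per_scale):
        fa_max = float(ef.fa.max())
        if fa_max <= 0:
            logger.warning("scale %d has zero maximum FA; score set to 0", i)
            scores[i] = 0.0
        else:
            scores[i] = ef.fa / fa_max
    index = np.argmax(scores, axis=0)        # first max wins -> lowest index
    score = np.take_along_axis(scores, index[None], axis=0)[0]

    if len(per_scale) == 1:
        selected = per_scale[0]
    else:
        sel_raw = np.empty(shape + (3,))
        sel_conv = np.empty(shape + (3,))
        sel_vecs = np.empty(shape + (3, 3))
        sel_fa = np.empty(shape)
        sel_zero = np.empty(shape, dtype=bool)
        for i, ef in enumerate(per_scale):
            m = index == i
            sel_raw[m] = ef.raw[m]
            sel_conv[m] = ef.converted[m]
            sel_vecs[m] = ef.vectors[m]
            sel_fa[m] = ef.fa[m]
            sel_zero[m] = ef.zero_mask[m]
        rho_max = max(ef.rho for ef in per_scale)
        sigma_max = max(ef.sigma for ef in per_scale)
        selected = EigenField(raw=sel_raw, vectors=sel_vecs, zero_mask=sel_zero,
                              voxel_size=per_scale[0].voxel_size, scale_id=-1,
                              sigma=sigma_max, rho=rho_max,
                              converted=sel_conv, fa=sel_fa)
    return selected, DominantScaleMap(index=index, score=score,
                                      n_scales=len(per_scale))


def analyse_volume(volume: ImageVolume, params: ScaleParams,
                   ) -> tuple[EigenField, DominantScaleMap]:
    """Full single-volume analysis: (optional downsample is the caller's job)
    per-scale tensors → eigen → γ conversion → FA → dominant-scale selection."""
    fields = []
    for i, (sigma, rho) in enumerate(params.scales):
        tf = compute_structure_tensor(volume, sigma, rho, scale_id=i)
        ef = eigendecompose_field(tf)
        convert_eigenvalues(ef, params.gamma)
        fractional_anisotropy(ef)
        fields.append(ef)
    return scale_space_select(fields, params)
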