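"""Orientation statistics: FOD spherical histograms, Bingham dispersion, FA.

Principal directions are *axial* (v ≡ −v).  The fibre orientation
distribution (FOD) is a histogram over one hemisphere parametrised by
azimuth and elevation around a chosen pole axis — the anatomical axis with
the least directional contribution, so that no mass sits near the degenerate
pole.  Bins do not have equal areas, so each bin's solid angle is used to
normalise the histogram into a density (Σ p·Δω = 1).

The FOD's parametric summary is an antipodally symmetric Bingham
distribution ∝ exp(−κ1 (a1·x)² − κ2 (a2·x)²) with mean axis a3 and
concentrations κ1 ≥ κ2 ≥ 0.  From it:

* ODI = (2/π)·arctan(1/√(κ1 κ2)) — overall angular spread, 0 (aligned) to 1
  (uniform);
* DA  = (2/π)·arctan((κ1 − κ2)/κ2) — anisotropy of the spread, 0 (circular)
  to 1 (planar, κ2 = 0).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import integrate, optimize, special, stats

from .structure_tensor import EigenField
from .volume import ROIMask

KAPPA_CAP = 1.0e4

_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}
# azimuth reference axes (a, b) per pole: phi = atan2(v·b, v·a)
_AZIMUTH_FRAME = {"z": ("x", "y"), "y": ("z", "x"), "x": ("y", "z")}


# ---------------------------------------------------------------------------
# Direction extraction
# ---------------------------------------------------------------------------

def extract_principal_directions(
    eigen: EigenField,
    include: ROIMask | None = None,
    exclude: list[ROIMask] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal (fibre) directions + FA under inclusion/exclusion ROIs.

    Selection = include ∩ ¬(∪ exclude) ∩ ¬zero_mask ∩ ¬border.  Returns the
    axial unit vectors (N, 3) and the matching FA values (N,).
    """
    if eigen.fa is None or eigen.converted is None:
        raise ValueError("eigen field must have converted eigenvalues and FA")
    select = np.ones(eigen.shape, dtype=bool)
    if include is not None:
        if include.shape != eigen.shape:
            raise ValueError("include mask grid does not match the eigen field")
        select &= include.data
    for m in exclude or []:
        if m.shape != eigen.shape:
            raise ValueError("exclude mask grid does not match the eigen field")
        select &= ~m.data
    select &= ~eigen.zero_mask
    select &= ~eigen.border_mask()
    if not select.any():
        inc = int(include.data.sum()) if include is not None else int(np.prod(eigen.shape))
        exc = [m.count() for m in (exclude or [])]
        raise ValueError(
            f"empty selection: include={inc} voxels, exclude={exc}, "
            f"zero_mask={int(eigen.zero_mask.sum())}, "
            f"border={int(eigen.border_mask().sum())}"
        )
    return eigen.principal_direction()[select], eigen.fa[select]


def auto_pole_axis(directions: np.ndarray) -> str:
    """Grid axis minimising the mean |v·axis| (ties broken z, then y, then x)."""
    d = np.asarray(directions, float)
    if d.ndim != 2 or d.shape[1] != 3 or len(d) == 0:
        raise ValueError("directions must be a non-empty (N, 3) array")
    scores = {ax: float(np.mean(np.abs(d @ v))) for ax, v in _AXIS_VECTORS.items()}
    best = min(scores.values())
    for ax in ("z", "y", "x"):
        if scores[ax] <= best + 1e-12:
            return ax
    return "z"


# ---------------------------------------------------------------------------
# FOD spherical histogram
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SphericalHistogram:
    """Area-normalised FOD over one hemisphere around ``pole_axis``.

    ``density[i, j]`` is the probability density (per steradian) in the
    elevation ring i, azimuth column j; ``solid_angle`` holds each bin's Δω.
    The pole cap (ring 0) is a single bin stored at column 0 with the other
    columns' solid angles set to 0.
    """

    pole_axis: str
    theta_edges_deg: np.ndarray     # polar angle from the pole, [0, 90]
    phi_edges_deg: np.ndarray       # azimuth, [0, 360]
    counts: np.ndarray              # (n_theta, n_phi)
    solid_angle: np.ndarray         # (n_theta, n_phi) steradians
    density: np.ndarray             # (n_theta, n_phi) per steradian
    n: int

    def normalisation(self) -> float:
        return float(np.sum(self.density * self.solid_angle))

    def bin_center_vector(self, i: int, j: int) -> np.ndarray:
        """Unit (x, y, z) vector at the centre of bin (i, j)."""
        if i == 0:
            theta = 0.0
            phi = 0.0
        else:
            theta = math.radians(0.5 * (self.theta_edges_deg[i]
                                        + self.theta_edges_deg[i + 1]))
            phi = math.radians(0.5 * (self.phi_edges_deg[j]
                                      + self.phi_edges_deg[j + 1]))
        a, b = (_AXIS_VECTORS[k] for k in _AZIMUTH_FRAME[self.pole_axis])
        p = _AXIS_VECTORS[self.pole_axis]
        return (math.sin(theta) * math.cos(phi) * a
                + math.sin(theta) * math.sin(phi) * b
                + math.cos(theta) * p)


def _to_hemisphere(directions: np.ndarray, pole: np.ndarray) -> np.ndarray:
    d = np.asarray(directions, float)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero direction vector")
    d = d / norms
    comp = d @ pole
    return np.where(comp[:, None] < 0, -d, d)


def build_fod(directions: np.ndarray, pole_axis: str | None = None,
              bin_width_deg: float = 5.0) -> SphericalHistogram:
    """Bin axial directions into an area-normalised spherical histogram.

    Directions are mapped to the hemisphere whose pole-axis component is
    ≥ 0 (antipodal symmetry), then binned by polar angle θ from the pole and
    azimuth φ.  Density = count / (n · Δω); the pole cap is a single bin.
    """
    d = np.asarray(directions, float)
    if d.ndim != 2 or d.shape[1] != 3 or len(d) == 0:
        raise ValueError("directions must be a non-empty (N, 3) array")
    if not 1.0 <= bin_width_deg <= 30.0:
        raise ValueError("bin width must be between 1 and 30 degrees")
    if pole_axis is None:
        pole_axis = auto_pole_axis(d)
    if pole_axis not in _AXIS_VECTORS:
        raise ValueError(f"pole_axis must be one of x/y/z, got {pole_axis!r}")
    pole = _AXIS_VECTORS[pole_axis]
    a, b = (_AXIS_VECTORS[k] for k in _AZIMUTH_FRAME[pole_axis])
    d = _to_hemisphere(d, pole)

    theta = np.degrees(np.arccos(np.clip(d @ pole, -1.0, 1.0)))
    phi = np.degrees(np.arctan2(d @ b, d @ a)) % 360.0

    theta_edges = np.arange(0.0, 90.0, bin_width_deg)
    theta_edges = np.append(theta_edges, 90.0)
    phi_edges = np.arange(0.0, 360.0, bin_width_deg)
    phi_edges = np.append(phi_edges, 360.0)
    n_t, n_p = len(theta_edges) - 1, len(phi_edges) - 1

    ti = np.clip(np.searchsorted(theta_edges, theta, side="right") - 1, 0, n_t - 1)
    pj = np.clip(np.searchsorted(phi_edges, phi, side="right") - 1, 0, n_p - 1)
    pj[ti == 0] = 0                       # pole cap is a single bin

    counts = np.zeros((n_t, n_p))
    np.add.at(counts, (ti, pj), 1.0)

    cos0 = np.cos(np.radians(theta_edges[:-1]))
    cos1 = np.cos(np.radians(theta_edges[1:]))
    dphi = np.radians(np.diff(phi_edges))
    solid = (cos0 - cos1)[:, None] * dphi[None, :]
    solid[0, :] = 0.0
    solid[0, 0] = 2 * np.pi * (1.0 - np.cos(np.radians(theta_edges[1])))

    n = len(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(solid > 0, counts / (n * solid), 0.0)
    return SphericalHistogram(pole_axis, theta_edges, phi_edges, counts,
                              solid, density, n)


def top_modes(hist: SphericalHistogram, k: int = 2,
              min_separation_deg: float | None = None) -> list[np.ndarray]:
    """The k highest-density histogram modes as axial unit vectors.

    Greedy peak picking: the densest bin wins, then bins within
    ``min_separation_deg`` (default 2 bin widths, acute angle) of an already
    chosen mode are suppressed, and so on.
    """
    if min_separation_deg is None:
        min_separation_deg = 2.0 * float(np.diff(hist.theta_edges_deg[:2])[0])
    dens = hist.density.copy()
    modes: list[np.ndarray] = []
    order = np.argsort(dens, axis=None)[::-1]
    for flat in order:
        if len(modes) >= k:
            break
        i, j = np.unravel_index(flat, dens.shape)
        if hist.solid_angle[i, j] <= 0 or dens[i, j] <= 0:
            continue
        v = hist.bin_center_vector(int(i), int(j))
        if any(_acute_deg(v, m) < min_separation_deg for m in modes):
            continue
        modes.append(v)
    return modes


def _acute_deg(a: np.ndarray, b: np.ndarray) -> float:
    c = abs(float(np.dot(a, b))) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.degrees(math.acos(min(1.0, c)))


# ---------------------------------------------------------------------------
# Bingham fit and dispersion indices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BinghamFit:
    """Antipodally symmetric Bingham fit to a set of axial directions."""

    axes: np.ndarray            # (3, 3); axes[k] is a_{k+1}, a3 = mean axis
    kappa1: float
    kappa2: float
    odi: float
    da: float
    log_likelihood: float
    n: int
    degenerate: bool = False


def _bingham_log_norm(kappa1: float, kappa2: float) -> float:
    """log of C(κ1, κ2) = (1/4π)∮ exp(−κ1 x1² − κ2 x2²) dΩ.

    The azimuth integral reduces to a Bessel I0 term, leaving a smooth 1D
    integral in u = cos θ (θ measured from a3), evaluated adaptively:
    C = ½ ∫₋₁¹ exp(−κ2 (1−u²)) · e^{Δ(1−u²)/2} i0e(Δ(1−u²)/2) du, Δ = κ1−κ2.
    """
    k1, k2 = max(kappa1, kappa2), min(kappa1, kappa2)
    delta = k1 - k2

    def integrand(u: float) -> float:
        s2 = 1.0 - u * u
        return math.exp(-k2 * s2) * special.i0e(0.5 * delta * s2)

    val, _ = integrate.quad(integrand, -1.0, 1.0, epsabs=1e-10, epsrel=1e-8,
                            limit=200)
    return math.log(0.5 * val)


def fit_bingham(directions: np.ndarray) -> BinghamFit:
    """Maximum-likelihood Bingham fit.

    Axes come from the eigen-decomposition of the orientation scatter matrix
    S = (1/n) Σ v vᵀ (a3 = largest-eigenvalue axis); concentrations maximise
    the Bingham likelihood with κ capped at 1e4.  A scatter matrix with three
    equal eigenvalues (uniform axes) returns κ1 = κ2 = 0 with the degeneracy
    flag set.
    """
    d = np.asarray(directions, float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("directions must be (N, 3)")
    n = len(d)
    if n < 10:
        raise ValueError(f"need at least 10 directions for a Bingham fit, got {n}")
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    scatter = d.T @ d / n
    w, v = np.linalg.eigh(scatter)          # ascending
    # a1 = least-scatter axis (strongest penalty), a3 = mean axis
    axes = np.stack([v[:, 0], v[:, 1], v[:, 2]]).copy()
    s1 = float(np.mean((d @ axes[0]) ** 2))
    s2 = float(np.mean((d @ axes[1]) ** 2))

    if np.allclose(w, 1.0 / 3.0, atol=5e-3):
        k1 = k2 = 0.0
        ll = -n * math.log(4 * math.pi)
        odi, da = dispersion_indices_from_kappas(k1, k2)
        return BinghamFit(axes, k1, k2, odi, da, ll, n, degenerate=True)

    def nll(kappas: np.ndarray) -> float:
        k1, k2 = float(kappas[0]), float(kappas[1])
        return k1 * s1 + k2 * s2 + _bingham_log_norm(k1, k2)

    # moment-style initial guess: E[(a_i·x)²] ≈ 1/(2κ_i) when concentrated
    init = np.clip([0.5 / max(s1, 1e-8), 0.5 / max(s2, 1e-8)], 0.0, KAPPA_CAP)
    res = optimize.minimize(nll, init, method="L-BFGS-B",
                            bounds=[(0.0, KAPPA_CAP)] * 2)
    k1, k2 = float(res.x[0]), float(res.x[1])
    if k2 > k1:                              # keep κ1 ≥ κ2, swapping axes too
        k1, k2 = k2, k1
        axes[[0, 1]] = axes[[1, 0]]
    ll = -n * (float(res.fun) + math.log(4 * math.pi))
    odi, da = dispersion_indices_from_kappas(k1, k2)
    return BinghamFit(axes, k1, k2, odi, da, ll, n, degenerate=False)


def dispersion_indices_from_kappas(kappa1: float, kappa2: float
                                   ) -> tuple[float, float]:
    """ODI and DA from the Bingham concentrations (closed forms).

    ODI = (2/π)·arctan(1/√(κ1 κ2)); 1 when either κ is 0 (no concentration).
    DA  = (2/π)·arctan((κ1 − κ2)/κ2); 0 for circular spread (κ1 = κ2) and 1
    for fully anisotropic spread (κ2 = 0 < κ1).
    """
    if kappa1 < kappa2:
        raise ValueError("requires kappa1 >= kappa2")
    if kappa1 * kappa2 <= 0:
        odi = 1.0
    else:
        odi = (2.0 / math.pi) * math.atan(1.0 / math.sqrt(kappa1 * kappa2))
    if kappa1 == kappa2:
        da = 0.0
    elif kappa2 <= 0:
        da = 1.0
    else:
        da = (2.0 / math.pi) * math.atan((kappa1 - kappa2) / kappa2)
    return odi, da


def dispersion_indices(fit: BinghamFit) -> tuple[float, float]:
    """(ODI, DA) of an existing fit."""
    return dispersion_indices_from_kappas(fit.kappa1, fit.kappa2)


def sample_bingham(axes: np.ndarray, kappa1: float, kappa2: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw axial unit vectors from a Bingham density by rejection sampling."""
    axes = np.asarray(axes, float)
    out = []
    have = 0
    while have < n:
        m = max(4 * (n - have), 1000)
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        x1 = v @ axes[0]
        x2 = v @ axes[1]
        p = np.exp(-kappa1 * x1 ** 2 - kappa2 * x2 ** 2)
        keep = rng.uniform(size=m) < p
        out.append(v[keep])
        have += int(keep.sum())
    return np.concatenate(out)[:n]


# ---------------------------------------------------------------------------
# FA distribution summaries
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistributionSummary:
    """KDE + robust summary of a bounded scalar distribution (e.g. FA)."""

    grid: np.ndarray | None         # support grid on [0, 1]
    density: np.ndarray | None      # KDE values on the grid
    mean: float
    sd: float
    median: float
    iqr: float
    n: int
    degenerate: bool = False

    def report(self) -> str:
        """Summary in the field's reporting style."""
        return (f"mean±sd: {self.mean:.2f}±{self.sd:.2f}, "
                f"median/IQR: {self.median:.2f}/{self.iqr:.2f} (n={self.n})")


def fa_density(fa_values: np.ndarray, bandwidth: float | str = "scott",
               grid_points: int = 512) -> DistributionSummary:
    """Gaussian KDE over FA with Scott's-rule bandwidth, support [0, 1].

    Inputs with < 2 distinct values yield a degenerate summary (no curve)
    with the flag set.
    """
    x = np.asarray(fa_values, float).ravel()
    if len(x) == 0:
        raise ValueError("no FA values given")
    q25, q75 = np.percentile(x, [25, 75])
    base = dict(mean=float(np.mean(x)), sd=float(np.std(x)),
                median=float(np.median(x)), iqr=float(q75 - q25), n=len(x))
    if len(np.unique(x)) < 2:
        return DistributionSummary(grid=None, density=None, degenerate=True,
                                   **base)
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_points)
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area          # clip support to [0, 1]
    return DistributionSummary(grid=grid, density=dens, degenerate=False,
                               **base)


def component_volume_fraction(mask: ROIMask, reference: ROIMask) -> float:
    """Percentage of the reference region occupied by the mask component."""
    if mask.shape != reference.shape:
        raise ValueError("mask grids do not match")
    ref_n = reference.count()
    if ref_n == 0:
        raise ValueError("reference mask is empty")
    overlap = int(np.logical_and(mask.data, reference.data).sum())
    return 100.0 * overlap / ref_n
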