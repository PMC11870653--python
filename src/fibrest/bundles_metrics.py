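"""Streamline clustering, shape metrics, and group comparison tests.

QuickBundles groups streamlines into "fasciculus" bundles in a single pass:
each streamline (resampled to K points) joins the first bundle whose running
centroid is within the MDF distance threshold, else founds a new bundle.
MDF is the minimum average direct-flip distance — the mean pointwise
Euclidean distance, minimised over the two point orderings.

Each centroid streamline is quantified by two shape metrics:

* tortuosity τ = L / d — trajectory length over endpoint chord, ≥ 1
  (1 = perfectly straight);
* maximum deviation d_max — the largest orthogonal distance of an interior
  point (i = 2..N−1) from the endpoint chord, in μm — the trajectory's
  maximum "amplitude".

Metric distributions are compared with two-sample Kolmogorov–Smirnov
(distribution equality), two-sided Wilcoxon rank-sum (median equality), and
Brown–Forsythe (variance equality; median-centred Levene) tests at α = 0.05.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .tractography import Streamline

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Resampling and the MDF distance
# ---------------------------------------------------------------------------

def resample_streamline(s: Streamline, k: int) -> Streamline:
    """Resample to k points equally spaced in arc length, endpoints exact."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = s.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("cannot resample a zero-length streamline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 3))
    out[0], out[-1] = pts[0], pts[-1]
    idx = np.clip(np.searchsorted(cum, targets[1:-1], side="right") - 1,
                  0, len(seg) - 1)
    frac = (targets[1:-1] - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    out[1:-1] = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    return Streamline(out, seed_index=s.seed_index, reason=s.reason)


def mdf_distance(a: np.ndarray | Streamline, b: np.ndarray | Streamline,
                 k: int | None = None) -> float:
    """Minimum average direct-flip distance between two k-point polylines."""
    pa = a.points if isinstance(a, Streamline) else np.asarray(a, float)
    pb = b.points if isinstance(b, Streamline) else np.asarray(b, float)
    if k is not None and (len(pa) != k or len(pb) != k):
        raise ValueError(f"streamlines must be resampled to k={k} points")
    if len(pa) != len(pb):
        raise ValueError("streamlines must have the same number of points")
    direct = float(np.mean(np.linalg.norm(pa - pb, axis=1)))
    flipped = float(np.mean(np.linalg.norm(pa - pb[::-1], axis=1)))
    return min(direct, flipped)


# ---------------------------------------------------------------------------
# QuickBundles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Bundle:
    """A QuickBundles cluster: running-mean centroid + member indices."""

    centroid: Streamline
    members: list[int]
    threshold_um: float


def quickbundles_cluster(streamlines: list[Streamline], threshold_um: float,
                         k: int = 18) -> list[Bundle]:
    """Single-pass sequential clustering with running flip-aligned centroids.

    Streamlines are visited in input order; each joins the first (nearest)
    bundle whose current centroid is within ``threshold_um`` MDF, else it
    founds a new bundle.  Members are flip-aligned to the centroid before
    updating the running mean.  Deterministic given the input order.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be > 0")
    if not streamlines:
        return []
    resampled = [resample_streamline(s, k).points for s in streamlines]
    sums: list[np.ndarray] = []
    counts: list[int] = []
    members: list[list[int]] = []
    for i, pts in enumerate(resampled):
        best_j, best_d, best_flip = -1, np.inf, False
        for j, (ssum, cnt) in enumerate(zip(sums, counts)):
            centroid = ssum / cnt
            direct = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
            flipped = float(np.mean(np.linalg.norm(pts[::-1] - centroid, axis=1)))
            d = min(direct, flipped)
            if d < best_d:
                best_j, best_d, best_flip = j, d, flipped < direct
        if best_j >= 0 and best_d <= threshold_um:
            aligned = pts[::-1] if best_flip else pts
            sums[best_j] = sums[best_j] + aligned
            counts[best_j] += 1
            members[best_j].append(i)
        else:
            sums.append(pts.copy())
            counts.append(1)
            members.append([i])
    bundles = []
    for ssum, cnt, mem in zip(sums, counts, members):
        centroid = Streamline(ssum / cnt, seed_index=streamlines[mem[0]].seed_index)
        bundles.append(Bundle(centroid=centroid, members=mem,
                              threshold_um=threshold_um))
    return bundles


# ---------------------------------------------------------------------------
# Shape metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StreamlineMetrics:
    """τ, d_max, trajectory length L and endpoint distance d for a streamline."""

    tortuosity: float           # unitless, >= 1; NaN when undefined (d = 0)
    max_deviation_um: float     # μm; NaN when undefined
    length_um: float
    endpoint_distance_um: float


def tortuosity(s: Streamline) -> float:
    """τ = L / d (trajectory length over endpoint chord), ≥ 1.

    Coincident endpoints (d = 0) leave τ undefined; NaN is returned and
    logged so such streamlines can be excluded from distributions.
    """
    d = s.endpoint_distance()
    if d <= 0:
        logger.info("tortuosity undefined: coincident endpoints")
        return float("nan")
    return s.length() / d


def max_deviation(s: Streamline) -> float:
    """Largest orthogonal distance (μm) of interior points from the chord.

    Interior means i = 2..N−1; polylines with ≤ 2 points return 0 by
    convention.  Undefined (NaN) when the endpoints coincide.
    """
    pts = s.points
    if len(pts) <= 2:
        return 0.0
    vd = pts[-1] - pts[0]
    dd = float(np.dot(vd, vd))
    if dd <= 0:
        logger.info("max deviation undefined: coincident endpoints")
        return float("nan")
    vi = pts[1:-1] - pts[0]
    proj = (vi @ vd)[:, None] / dd * vd
    return float(np.max(np.linalg.norm(vi - proj, axis=1)))


def streamline_metrics(s: Streamline) -> StreamlineMetrics:
    return StreamlineMetrics(
        tortuosity=tortuosity(s),
        max_deviation_um=max_deviation(s),
        length_um=s.length(),
        endpoint_distance_um=s.endpoint_distance(),
    )


def bundle_metrics(bundles: list[Bundle]) -> list[StreamlineMetrics]:
    """Shape metrics of the centroid streamline of each bundle."""
    return [streamline_metrics(b.centroid) for b in bundles]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TestReport:
    """KS / Wilcoxon rank-sum / Brown–Forsythe comparison of two samples."""

    ks_statistic: float
    ks_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    brown_forsythe_statistic: float
    brown_forsythe_p: float
    alpha: float
    n_a: int
    n_b: int
    degenerate: bool = False

    def decisions(self) -> dict[str, bool]:
        """True where the null hypothesis is rejected at α."""
        return {
            "ks_reject": self.ks_p < self.alpha,
            "wilcoxon_reject": self.wilcoxon_p < self.alpha,
            "brown_forsythe_reject": self.brown_forsythe_p < self.alpha,
        }

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(self.decisions())
        return d


def compare_groups(a: np.ndarray, b: np.ndarray,
                   alpha: float = 0.05) -> TestReport:
    """All three non-parametric tests between two metric samples.

    Kolmogorov–Smirnov (two-sample) for distribution equality, two-sided
    Wilcoxon rank-sum for median equality, Brown–Forsythe (Levene with
    median centring) for variance equality; decisions at the given α.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 5 or len(b) < 5:
        raise ValueError(f"each group needs n >= 5, got {len(a)} and {len(b)}")
    degenerate = (np.ptp(a) == 0) and (np.ptp(b) == 0)
    if degenerate:
        logger.warning("both samples are constant; test results are degenerate")
    ks = stats.ks_2samp(a, b)
    wrs = stats.ranksums(a, b)
    if degenerate:
        bf_stat, bf_p = 0.0, 1.0
    else:
        bf_stat, bf_p = stats.levene(a, b, center="median")
    return TestReport(
        ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        wilcoxon_statistic=float(wrs.statistic), wilcoxon_p=float(wrs.pvalue),
        brown_forsythe_statistic=float(bf_stat), brown_forsythe_p=float(bf_p),
        alpha=alpha, n_a=len(a), n_b=len(b), degenerate=degenerate,
    )
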