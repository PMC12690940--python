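"""Cortical depth profiles of labeled cells from light-sheet point clouds.

The brain surface is approximated by the convex hull of all detections; a
depth axis is anchored at the hull-surface point nearest the lesion's
center of mass (mean position of the lesion-channel cells) and directed
along the inward normal of that hull facet.  Profile-channel cells inside
a 1-mm-wide square column around the axis are binned by depth in 0.01 mm
steps, depths are rescaled to [0, 1] by the 95th-percentile depth, and
the curve is resampled to 100 bins and normalized to unit sum so that
laminar distributions are comparable across animals.  Curve shapes are
compared between groups via PCA (SVD of the mean-centered curve matrix)
with a two-sided Mann-Whitney U test on PC1 scores.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cohortstats import mann_whitney_u

__all__ = [
    "PointCloud3D",
    "DepthProfile",
    "ProfileComparison",
    "DepthProfileError",
    "compute_depth_profile",
    "compare_profiles",
]

DEFAULT_BIN_STEP = 0.01  # mm
DEFAULT_COLUMN_WIDTH = 1.0  # mm
N_CURVE_BINS = 100


class DepthProfileError(RuntimeError):
    """Raised with the failing stage ('hull', 'channel' or 'column') named."""


@dataclass
class PointCloud3D:
    """Light-sheet detections: positions (mm) with per-point channel labels."""

    positions: np.ndarray  # (N, 3) mm
    channel_labels: np.ndarray  # (N,) str
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.channel_labels = np.asarray(self.channel_labels)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.channel_labels.shape != (self.positions.shape[0],):
            raise ValueError("one channel label per point required")

    def channel(self, label: str) -> np.ndarray:
        return self.positions[self.channel_labels == label]


@dataclass
class DepthProfile:
    """Depth distribution of one animal's labeled cells."""

    counts: np.ndarray  # raw counts per bin_step along the axis
    bin_edges: np.ndarray  # mm, for `counts`
    normalized_curve: np.ndarray  # 100-bin relative-depth curve, unit sum
    axis_origin: np.ndarray  # mm point on the hull surface
    axis_direction: np.ndarray  # unit inward normal
    bin_step: float = DEFAULT_BIN_STEP
    column_width: float = DEFAULT_COLUMN_WIDTH
    n_in_column: int = 0

    @classmethod
    def from_curve(cls, curve: np.ndarray) -> "DepthProfile":
        """Wrap an already-binned relative-depth curve (normalized to unit sum)."""
        curve = np.asarray(curve, dtype=float)
        total = curve.sum()
        if total <= 0:
            raise ValueError("curve must have positive mass")
        return cls(counts=curve.copy(), bin_edges=np.linspace(0, 1, curve.size + 1),
                   normalized_curve=curve / total, axis_origin=np.zeros(3),
                   axis_direction=np.array([0.0, 0.0, -1.0]),
                   n_in_column=int(round(total)))


@dataclass
class ProfileComparison:
    pc_scores: np.ndarray  # (n_profiles,) PC1 scores
    explained_variance_ratio: np.ndarray
    p_value: float
    u_statistic: float | None = None


def _closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle (3x3 vertex rows) to p (Ericson's method)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def compute_depth_profile(cloud: PointCloud3D, lesion_channel: str = "GFP",
                          profile_channel: str = "tdTomato",
                          bin_step: float = DEFAULT_BIN_STEP,
                          column_width: float = DEFAULT_COLUMN_WIDTH,
                          n_bins: int = N_CURVE_BINS,
                          min_column_points: int = 50) -> DepthProfile:
    """Depth distribution of the profile channel under the lesion axis.

    See the module docstring for the geometric construction.  Raises
    :class:`DepthProfileError` naming the failing stage on a degenerate
    hull, a missing channel, or fewer than ``min_column_points`` cells in
    the column.
    """
    try:
        hull = ConvexHull(cloud.positions)
    except (QhullError, ValueError) as exc:
        raise DepthProfileError(f"hull: degenerate point cloud ({exc})") from exc
    lesion_pts = cloud.channel(lesion_channel)
    profile_pts = cloud.channel(profile_channel)
    if lesion_pts.shape[0] == 0 or profile_pts.shape[0] == 0:
        raise DepthProfileError(
            f"channel: need points in both {lesion_channel!r} and {profile_channel!r}")
    center = lesion_pts.mean(axis=0)

    best_d2, best_pt, best_facet = np.inf, None, None
    pts = cloud.positions
    for fi, simplex in enumerate(hull.simplices):
        q = _closest_point_on_triangle(center, pts[simplex])
        d2 = float(((q - center) ** 2).sum())
        if d2 < best_d2:
            best_d2, best_pt, best_facet = d2, q, fi
    origin = best_pt
    outward = hull.equations[best_facet, :3]
    axis = -outward / np.linalg.norm(outward)

    # fixed perpendicular column axes
    e = np.zeros(3)
    e[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(axis, e)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    rel = profile_pts - origin
    depth = rel @ axis
    in_col = (np.abs(rel @ u) <= column_width / 2) & (np.abs(rel @ v) <= column_width / 2)
    col_depth = depth[in_col]
    if col_depth.size < min_column_points:
        raise DepthProfileError(
            f"column: only {col_depth.size} profile points inside the "
            f"{column_width} mm column (need >= {min_column_points})")

    edges = np.arange(0.0, col_depth.max() + bin_step, bin_step)
    if edges.size < 2:
        edges = np.array([0.0, bin_step])
    counts, edges = np.histogram(col_depth, bins=edges)

    d95 = float(np.percentile(col_depth, 95))
    if d95 <= 0:
        d95 = float(col_depth.max()) or bin_step
    reldepth = col_depth / d95
    curve, _ = np.histogram(reldepth[reldepth <= 1.0], bins=n_bins, range=(0.0, 1.0))
    total = curve.sum()
    if total == 0:
        raise DepthProfileError("column: no points in the normalized depth range")
    return DepthProfile(
        counts=counts, bin_edges=edges,
        normalized_curve=curve / total,
        axis_origin=origin, axis_direction=axis,
        bin_step=bin_step, column_width=column_width,
        n_in_column=int(col_depth.size),
    )


def compare_profiles(profiles: Sequence[DepthProfile],
                     groups: Sequence[int]) -> ProfileComparison:
    """PCA of curve shapes with a Mann-Whitney test on PC1 scores.

    Curves are stacked (animals x bins) and column-mean-centered; PCs come
    from the SVD, with PC1's sign fixed so its loading at the shallowest
    bin is non-negative.  Identical curves (zero variance) give p = 1.
    Requires at least 3 profiles per group.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("groups must contain exactly two labels")
    if min((groups == g).sum() for g in labels) < 3:
        raise ValueError("need at least 3 profiles per group")
    X = np.vstack([p.normalized_curve for p in profiles])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0, atol=1e-14):
        return ProfileComparison(
            pc_scores=np.zeros(X.shape[0]),
            explained_variance_ratio=np.zeros(min(X.shape)),
            p_value=1.0,
        )
    u_mat, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if vt[0, 0] < 0:
        vt = -vt
        u_mat = -u_mat
    scores = u_mat[:, 0] * s[0]
    evr = s ** 2 / np.sum(s ** 2)
    res = mann_whitney_u(scores[groups == labels[0]], scores[groups == labels[1]])
    return ProfileComparison(pc_scores=scores, explained_variance_ratio=evr,
                             p_value=res.p_raw, u_statistic=res.statistic)
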