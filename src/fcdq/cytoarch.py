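"""3D cell detection and mTOR-hyperactivation classification from slice imagery.

The substrate is a Z-stack of per-frame 2D instance-label masks (the output
of a human-in-the-loop segmentation tool) plus matched intensity frames.
Cells are counted in 3D by accumulating per-frame mask centroids on a
coarse grid, thresholding persistence across frames, counting 8-connected
accumulator objects, and refining positions by k-means on the full-
resolution centroids.  Each detected neuron gets a moment-equivalent
ellipse from its largest cross-section, an effective diameter, and a mean
labeling intensity; neurons are classified pS6-high vs baseline either by
bi-Gaussian histogram thresholding or by a background-multiple threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from shapely.geometry import LineString, Point
from skimage.measure import regionprops
from sklearn.cluster import KMeans

__all__ = [
    "CellStack",
    "CellDetection",
    "IntensityModel",
    "DensityReport",
    "CortexGeometry",
    "UnimodalIntensityError",
    "detect_cells_3d",
    "stretch_contrast_mip",
    "cell_mean_intensity",
    "threshold_bigauss",
    "threshold_background",
    "classify_and_report",
    "tangential_extent",
    "cortical_thickening",
]


class UnimodalIntensityError(RuntimeError):
    """Bi-Gaussian fit failed or collapsed; use the background-multiple method."""


@dataclass
class CellStack:
    """Per-frame instance-label masks (+ optional intensity frames).

    ``label_frames`` is (n_frames, H, W) with non-negative integer labels,
    0 = background; ``intensity_frames`` matches its shape when present.
    Physical geometry: ``xy_scale`` um/px, ``z_step`` um between frames.
    """

    label_frames: np.ndarray
    intensity_frames: np.ndarray | None
    xy_scale: float
    z_step: float

    def __post_init__(self) -> None:
        if self.label_frames.ndim != 3:
            raise ValueError("label_frames must be (n_frames, H, W)")
        if not np.issubdtype(self.label_frames.dtype, np.integer):
            raise ValueError("label frames must hold integer instance labels")
        if self.intensity_frames is not None \
                and self.intensity_frames.shape != self.label_frames.shape:
            raise ValueError("intensity frames must match label frames in shape")
        if not self.z_step > 0:
            raise ValueError("z_step must be positive")

    @property
    def n_frames(self) -> int:
        return self.label_frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.label_frames.shape[1:]


@dataclass
class CellDetection:
    """One detected neuron: 3D centroid, moment ellipse, intensity, class."""

    centroid: tuple[float, float, float]  # (x um, y um, z um)
    max_area_frame: int
    major_axis: float  # um
    minor_axis: float  # um
    orientation: float  # rad, skimage convention (row axis to major axis)
    effective_diameter: float  # um, sqrt(major*minor)
    mean_intensity: float = float("nan")
    class_label: str = "unclassified"


@dataclass(frozen=True)
class IntensityModel:
    """Bi-Gaussian fit of the 256-bin cell-intensity histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mu1: float
    sigma1: float
    amp1: float
    mu2: float
    sigma2: float
    amp2: float

    @property
    def threshold(self) -> float:
        return (self.mu1 + self.mu2) / 2.0


@dataclass(frozen=True)
class DensityReport:
    n_cells: int
    counting_volume: float  # mm^3
    density: float  # cells / mm^3
    fraction_high: float | None = None
    overlap_fraction: float | None = None


@dataclass
class CortexGeometry:
    """Surface and gray/white-matter boundary polylines (um) with a center."""

    surface_curve: np.ndarray  # (N, 2)
    gwm_curve: np.ndarray  # (M, 2)
    center: tuple[float, float]


def _round_half_away(x: float) -> float:
    """Round half away from zero (deterministic, unlike banker's rounding)."""
    return math.copysign(math.floor(abs(x) + 0.5), x)


def detect_cells_3d(stack: CellStack, downsample: int = 4, count_threshold: int = 4,
                    margin_frames: int = 5, seed: int = 0,
                    n_init: int = 50) -> list[CellDetection]:
    """Count and localize cells in 3D from per-frame instance masks.

    Procedure: per-frame mask centroids are mapped onto a ``downsample``-times
    coarser grid (coordinates divided and rounded, half away from zero) and
    accumulated binarily across frames; accumulator cells persisting in at
    least ``count_threshold`` frames are kept and their 8-connected
    components give the cell count K.  Full-resolution centroids from the
    frames excluding the first/last ``margin_frames`` (so cells straddling
    consecutive stacks are not double counted) are then clustered by
    k-means with k=K (k-means++ init, ``n_init`` restarts, fixed seed).
    Per cluster the frame with the largest member-mask area (ties to the
    lower frame index) supplies the moment-equivalent ellipse; the
    effective diameter is the equal-area value sqrt(major*minor), and the
    mean intensity (when intensity frames are present) is the voxel mean
    over all of the cluster's member masks.

    Returns an empty list when no accumulator object survives.
    """
    if not np.issubdtype(stack.label_frames.dtype, np.integer):
        raise ValueError("label frames must be integer-valued")
    if stack.n_frames <= 2 * margin_frames:
        raise ValueError("stack must have more than 2*margin_frames frames")

    # (frame, label, centroid_row, centroid_col, area, intensity_sum)
    records = []
    for k in range(stack.n_frames):
        frame = stack.label_frames[k]
        if not frame.any():
            continue
        intens = stack.intensity_frames[k] if stack.intensity_frames is not None else None
        for rp in regionprops(frame, intensity_image=intens):
            isum = rp.intensity_mean * rp.area if intens is not None else np.nan
            records.append((k, rp.label, rp.centroid[0], rp.centroid[1], rp.area, isum))
    if not records:
        return []

    H, W = stack.frame_shape
    acc_shape = (int(H // downsample + 2), int(W // downsample + 2))
    acc = np.zeros(acc_shape, dtype=np.int32)
    by_frame: dict[int, set[tuple[int, int]]] = {}
    for k, _lab, cr, cc, _a, _i in records:
        coarse = (int(_round_half_away(cr / downsample)),
                  int(_round_half_away(cc / downsample)))
        by_frame.setdefault(k, set()).add(coarse)
    for coords in by_frame.values():
        for r, c in coords:
            acc[r, c] += 1
    kept = acc >= count_threshold
    _labeled, n_objects = ndimage.label(kept, structure=np.ones((3, 3), dtype=int))
    if n_objects == 0:
        return []

    inner = [rec for rec in records
             if margin_frames <= rec[0] < stack.n_frames - margin_frames]
    if not inner:
        return []
    pts = np.array([(rec[2], rec[3]) for rec in inner])
    k_eff = min(n_objects, len(inner))
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=n_init,
                random_state=seed).fit(pts)

    detections: list[CellDetection] = []
    for ci in range(k_eff):
        members = [rec for rec, lab in zip(inner, km.labels_) if lab == ci]
        if not members:
            continue
        # largest member-mask area; ties toward lower frame index, then label
        best = max(members, key=lambda rec: (rec[4], -rec[0], -rec[1]))
        frame_idx, lab = best[0], best[1]
        mask = stack.label_frames[frame_idx] == lab
        rp = regionprops(mask.astype(np.uint8))[0]
        major = rp.axis_major_length * stack.xy_scale
        minor = rp.axis_minor_length * stack.xy_scale
        cx = rp.centroid[1] * stack.xy_scale
        cy = rp.centroid[0] * stack.xy_scale
        cz = frame_idx * stack.z_step
        if stack.intensity_frames is not None:
            tot = sum(rec[5] for rec in members)
            npx = sum(rec[4] for rec in members)
            mean_int = float(tot / npx)
        else:
            mean_int = float("nan")
        detections.append(CellDetection(
            centroid=(float(cx), float(cy), float(cz)),
            max_area_frame=int(frame_idx),
            major_axis=float(major), minor_axis=float(minor),
            orientation=float(rp.orientation),
            effective_diameter=float(np.sqrt(major * minor)),
            mean_intensity=mean_int,
        ))
    return detections


def stretch_contrast_mip(stack: CellStack) -> np.ndarray:
    """Maximum-intensity projection with a 1st-99th percentile LUT stretch.

    The per-pixel maximum over frames is rescaled affinely so the 1st
    percentile maps to 0 and the 99th to 255, clipped to [0, 255].
    """
    if stack.intensity_frames is None:
        raise ValueError("stack has no intensity frames")
    mip = stack.intensity_frames.max(axis=0)
    p1, p99 = np.percentile(mip, [1, 99])
    if p99 <= p1:
        raise ValueError("contrast stretch undefined for a (near-)constant image")
    return np.clip((mip - p1) * 255.0 / (p99 - p1), 0.0, 255.0)


def cell_mean_intensity(mip: np.ndarray, det: CellDetection,
                        xy_scale: float = 1.0) -> float:
    """Mean MIP intensity inside a detection's fitted ellipse.

    The ellipse (center, axes in um, skimage orientation convention) is
    converted to pixel units via ``xy_scale`` and the mean is taken over
    pixels whose centers fall inside.
    """
    cx = det.centroid[0] / xy_scale
    cy = det.centroid[1] / xy_scale
    a = det.major_axis / 2.0 / xy_scale
    b = det.minor_axis / 2.0 / xy_scale
    theta = det.orientation
    H, W = mip.shape
    r0 = max(0, int(np.floor(cy - a)))
    r1 = min(H - 1, int(np.ceil(cy + a)))
    c0 = max(0, int(np.floor(cx - a)))
    c1 = min(W - 1, int(np.ceil(cx + a)))
    if r1 < r0 or c1 < c0:
        raise ValueError("ellipse lies fully outside the image")
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    dy = rows[:, None] - cy
    dx = cols[None, :] - cx
    # skimage: major axis direction is (d_col, d_row) = (sin(theta), cos(theta))
    u = dx * np.sin(theta) + dy * np.cos(theta)
    v = dx * np.cos(theta) - dy * np.sin(theta)
    inside = (u / max(a, 1e-12)) ** 2 + (v / max(b, 1e-12)) ** 2 <= 1.0
    if not inside.any():
        raise ValueError("ellipse covers no pixel centers inside the image")
    return float(mip[r0:r1 + 1, c0:c1 + 1][inside].mean())


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def threshold_bigauss(intensities: Sequence[float]) -> IntensityModel:
    """Bi-Gaussian threshold of a cell-intensity histogram.

    Builds a 256-bin histogram over 0-255, fits a two-Gaussian curve to
    the bin counts by nonlinear least squares (means initialized at the
    25th/75th percentiles, sigmas at half the sample SD, amplitudes at the
    max count), and sets the threshold at the midpoint of the two fitted
    centers.  Raises :class:`UnimodalIntensityError` when the fit does not
    converge or the centers collapse (< 2 bins apart) -- callers should
    fall back to the background-multiple method.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 intensity values")
    edges = np.linspace(0.0, 255.0, 257)
    counts, _ = np.histogram(np.clip(x, 0, 255), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    m1_0, m2_0 = np.percentile(x, [25, 75])
    s0 = max(x.std() / 2.0, 0.5)
    a0 = float(counts.max())
    p0 = [a0, m1_0, s0, a0, m2_0, s0]
    bounds = ([0.0, 0.0, 1e-3, 0.0, 0.0, 1e-3],
              [np.inf, 255.0, 255.0, np.inf, 255.0, 255.0])
    try:
        popt, _ = optimize.curve_fit(_two_gauss, centers, counts, p0=p0,
                                     bounds=bounds, maxfev=10_000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise UnimodalIntensityError(
            "bi-Gaussian fit did not converge; use threshold_background") from exc
    a1, m1, s1, a2, m2, s2 = popt
    if m1 > m2:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    if abs(m2 - m1) < 2.0:
        raise UnimodalIntensityError(
            "fitted centers < 2 bins apart (unimodal histogram); "
            "use threshold_background")
    return IntensityModel(bin_edges=edges, counts=counts,
                          mu1=float(m1), sigma1=float(s1), amp1=float(a1),
                          mu2=float(m2), sigma2=float(s2), amp2=float(a2))


def threshold_background(image: np.ndarray, background_points: Sequence[tuple[int, int]],
                         factor: float = 3.0) -> float:
    """Background-multiple threshold: factor x mean intensity at the points.

    ``background_points`` are (row, col) pixels manually placed in the
    first cortical layer.  Conventional factors: 3.0 for pS6, 1.5 for
    GFP/NeuN labeling.
    """
    pts = list(background_points)
    if not pts:
        raise ValueError("need at least one background point")
    vals = [float(image[r, c]) for r, c in pts]
    return factor * float(np.mean(vals))


def classify_and_report(dets: list[CellDetection], threshold: float,
                        counting_volume: float,
                        reference_dets: list[CellDetection] | None = None,
                        count_mode: str = "high",
                        match_radius: float = 5.0) -> DensityReport:
    """Classify detections high/low at ``threshold`` and report densities.

    ``density`` is n_high / counting_volume (``count_mode="all"`` counts
    every detection instead, for pan-neuronal NeuN-style densities).  With
    ``reference_dets`` given (e.g. GFP+ cells), ``overlap_fraction`` is
    the fraction of reference cells whose nearest detection within
    ``match_radius`` um is classified high.  Class labels are written onto
    the detections in place.
    """
    if not counting_volume > 0:
        raise ValueError("counting_volume must be positive")
    for d in dets:
        d.class_label = "high" if d.mean_intensity >= threshold else "low"
    n_high = sum(1 for d in dets if d.class_label == "high")
    n_counted = len(dets) if count_mode == "all" else n_high
    fraction_high = n_high / len(dets) if dets else None
    overlap = None
    if reference_dets is not None:
        if dets:
            coords = np.array([d.centroid for d in dets])
            hits = 0
            for ref in reference_dets:
                dist = np.linalg.norm(coords - np.asarray(ref.centroid), axis=1)
                j = int(np.argmin(dist))
                if dist[j] <= match_radius and dets[j].class_label == "high":
                    hits += 1
            overlap = hits / len(reference_dets) if reference_dets else None
        else:
            overlap = 0.0 if reference_dets else None
    return DensityReport(
        n_cells=n_counted, counting_volume=float(counting_volume),
        density=n_counted / counting_volume,
        fraction_high=fraction_high, overlap_fraction=overlap,
    )


def tangential_extent(cell_positions_tangential: Sequence[float],
                      trim: float = 0.01) -> tuple[float, float]:
    """Tangential lesion bounds separating ``trim`` of the cells on each side.

    Nearest-rank quantile rule: with n positions, the k = ceil(trim*n)
    most extreme points on each side fall outside the returned bounds
    (trim=0 gives the min/max).
    """
    x = np.sort(np.asarray(cell_positions_tangential, dtype=float))
    if x.size < 2:
        raise ValueError("need at least two positions")
    k = int(math.ceil(trim * x.size))
    k = min(k, (x.size - 1) // 2)
    return float(x[k]), float(x[x.size - 1 - k])


def _thickness(geom: CortexGeometry) -> float:
    surf = np.asarray(geom.surface_curve, dtype=float)
    gwm = LineString(np.asarray(geom.gwm_curve, dtype=float))
    center = np.asarray(geom.center, dtype=float)
    i = int(np.argmin(np.linalg.norm(surf - center, axis=1)))
    # tangent from the two neighboring segments at the center vertex
    dirs = []
    if i > 0:
        dirs.append(surf[i] - surf[i - 1])
    if i < len(surf) - 1:
        dirs.append(surf[i + 1] - surf[i])
    tangent = np.sum([d / np.linalg.norm(d) for d in dirs], axis=0)
    tangent = tangent / np.linalg.norm(tangent)
    normal = np.array([-tangent[1], tangent[0]])
    both = np.vstack([surf, np.asarray(geom.gwm_curve, dtype=float)])
    reach = 10.0 * float(np.linalg.norm(both.max(axis=0) - both.min(axis=0))) + 1.0
    for sign in (1.0, -1.0):
        ray = LineString([center, center + sign * normal * reach])
        inter = ray.intersection(gwm)
        if not inter.is_empty:
            return float(inter.distance(Point(center))
                         if inter.geom_type == "Point"
                         else Point(center).distance(inter))
    raise ValueError("inward normal ray does not intersect the gray/white boundary")


def cortical_thickening(lesion_geom: CortexGeometry,
                        contra_geom: CortexGeometry) -> tuple[float, float, float]:
    """Cortical thickness at the lesion vs the homotopic contralateral site.

    Thickness is the distance from the surface center along the inward
    surface normal to the first intersection with the gray/white-matter
    boundary; thickening = (t_lesion / t_contra - 1) * 100 %.
    """
    t_lesion = _thickness(lesion_geom)
    t_contra = _thickness(contra_geom)
    return t_lesion, t_contra, (t_lesion / t_contra - 1.0) * 100.0
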