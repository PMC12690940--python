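"""Synthetic-data generators with exact ground truth.

Every input kind the pipeline consumes can be generated here so that all
downstream modules are testable without external data:

* a topologically faithful 15-area dorsal cortical reference map,
* cohorts of elliptical-blob lesion masks whose position/area statistics
  mirror the printed seizing / non-seizing group summaries,
* confocal-style Z-stacks of spherical cells as per-frame instance-label
  masks plus matched intensity frames (two intensity populations),
* axonal diameter profiles with Gaussian bouton bumps,
* light-sheet-style 3D point clouds under a curved cortical surface with
  a prescribed depth density.

All randomness flows from one ``numpy.random.default_rng(seed)`` per
call; a fixed seed reproduces outputs bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .boutons import AxonTrace, Bouton, BoutonSet, bouton_volume
from .cytoarch import CellStack
from .depthprof import PointCloud3D
from .topography import CorticalArea, DorsalImageMask, MapGrid, ReferenceMap

__all__ = [
    "CohortSimParams",
    "CellFieldSimParams",
    "TraceSimParams",
    "CloudSimParams",
    "CloudTruth",
    "make_reference_map",
    "simulate_lesion_cohort",
    "draw_cohort_truth",
    "simulate_cell_stack",
    "simulate_axon_trace",
    "simulate_cortical_cloud",
]

# normal spread matching a printed IQR: IQR = 1.349 sigma
IQR_TO_SD = 1.0 / 1.349


# --------------------------------------------------------------------------- #
# reference map
# --------------------------------------------------------------------------- #

_AREA_LAYOUT: list[tuple[str, str, str, tuple[float, float, float, float]]] = [
    # (name, abbreviation, domain, (x0, y0, x1, y1) in mm, y anterior of lambda)
    ("Auditory cortex", "A", "Sensory", (3.5, 0.0, 4.2, 2.0)),
    ("Primary visual cortex", "V", "Sensory", (1.7, 0.0, 2.9, 2.0)),
    ("Secondary visual cortex, lateral", "V2l", "Sensory", (2.9, 0.0, 3.5, 2.0)),
    ("Secondary visual cortex, medial", "V2m", "Sensory", (0.9, 0.0, 1.7, 2.0)),
    ("Primary somatosensory cortex", "S1", "Sensory", (0.5, 2.8, 3.3, 5.5)),
    ("Secondary somatosensory cortex", "S2", "Sensory", (3.3, 2.8, 4.2, 5.5)),
    ("Primary motor cortex", "M1", "Executive", (1.5, 5.5, 4.2, 7.5)),
    ("Secondary motor cortex", "M2", "Executive", (0.5, 5.5, 1.5, 7.5)),
    ("Frontal association cortex", "FA", "Executive", (1.0, 7.5, 3.0, 8.5)),
    ("Medial orbital cortex", "MO", "Executive", (0.0, 7.5, 1.0, 8.5)),
    ("Parietal association cortex", "PA", "Limbic/Associative", (0.5, 2.0, 4.2, 2.8)),
    ("Prelimbic cortex", "PL", "Limbic/Associative", (0.0, 5.5, 0.5, 7.5)),
    ("Cingulate cortex", "CG", "Limbic/Associative", (0.0, 2.0, 0.5, 5.5)),
    ("Retrosplenial cortex", "RS", "Limbic/Associative", (0.4, 0.0, 0.9, 2.0)),
    ("Retrosplenial granular cortex", "RSg", "Limbic/Associative", (0.0, 0.0, 0.4, 2.0)),
]


def make_reference_map() -> ReferenceMap:
    """Synthetic dorsal cortical atlas: 15 areas in 3 functional domains.

    The polygons are a rectangular tiling of one hemisphere (midline at
    x=0, lambda at the origin, anterior positive) arranged in the standard
    posterior-to-anterior order: visual/auditory/retrosplenial areas
    posterior, somatosensory in the middle, motor and frontal association
    areas anterior.  Bregma sits 4.2 mm anterior of lambda.  Shapes are
    schematic; the area names, abbreviations and domain grouping are the
    anatomically meaningful content.
    """
    areas = tuple(
        CorticalArea(name=n, abbreviation=a, polygon=box(*b))
        for n, a, _, b in _AREA_LAYOUT
    )
    domains = {a: d for _, a, d, _ in _AREA_LAYOUT}
    return ReferenceMap(areas=areas, domains=domains, bregma=(0.0, 4.2), lambda_=(0.0, 0.0))


# --------------------------------------------------------------------------- #
# lesion cohorts
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CohortSimParams:
    """Cohort of elliptical lesion blobs matched to printed group summaries.

    Frontal-edge positions (mm anterior of lambda) and areas (mm^2) are
    drawn from normal distributions with center = printed group median and
    spread = printed IQR / 1.349.  Defaults correspond to 12 seizing
    animals at 7.4 (6.5-7.8) mm and 14 non-seizing at 6.1 (5.6-6.4) mm,
    areas 10.2 vs 6.8 mm^2.
    """

    n_seizing: int = 12
    n_nonseizing: int = 14
    pos_center_s: float = 7.4
    pos_center_ns: float = 6.1
    pos_spread_s: float = (7.8 - 6.5) * IQR_TO_SD
    pos_spread_ns: float = (6.4 - 5.6) * IQR_TO_SD
    area_center_s: float = 10.2
    area_center_ns: float = 6.8
    area_spread: float = 4.0
    pixel_scale: float = 0.02  # mm/px of the simulated dorsal images
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seizing < 1 or self.n_nonseizing < 1:
            raise ValueError("group counts must be >= 1")
        if min(self.pos_spread_s, self.pos_spread_ns, self.area_spread) < 0:
            raise ValueError("spreads must be non-negative")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")


#: AP/lateral aspect ratio of the simulated elliptical lesion blobs
_LESION_ASPECT = 1.3
_MIN_AREA = 0.5  # mm^2, redraw smaller areas


def draw_cohort_truth(params: CohortSimParams,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-animal frontal-edge positions, areas and labels (no rasters)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows = []
    for group, n, pc, ps, ac in [
        ("seizing", params.n_seizing, params.pos_center_s, params.pos_spread_s,
         params.area_center_s),
        ("nonseizing", params.n_nonseizing, params.pos_center_ns, params.pos_spread_ns,
         params.area_center_ns),
    ]:
        for i in range(n):
            pos = rng.normal(pc, ps)
            area = rng.normal(ac, params.area_spread)
            while area < _MIN_AREA:
                area = rng.normal(ac, params.area_spread)
            rows.append(
                dict(animal_id=f"{'S' if group == 'seizing' else 'NS'}{i + 1:02d}",
                     seizing=group == "seizing", position_drawn=pos, area_drawn=area)
            )
    return pd.DataFrame(rows)


def _rasterize_ellipse_on_grid(grid: MapGrid, xc: float, yc: float,
                               a_ap: float, b_lat: float) -> np.ndarray:
    X, Y = grid.pixel_centers()
    return ((X - xc) / b_lat) ** 2 + ((Y - yc) / a_ap) ** 2 <= 1.0


def simulate_lesion_cohort(params: CohortSimParams,
                           refmap: ReferenceMap | None = None,
                           grid_scale: float = 0.02,
                           max_attempts: int = 100,
                           ) -> tuple[list[DorsalImageMask], pd.DataFrame]:
    """Simulate one dorsal lesion mask per animal plus an exact truth table.

    Each lesion is an ellipse (AP semi-axis : lateral = 1.3 : 1) whose
    anterior edge sits at the drawn frontal position.  Every animal's image
    is rendered under its own small random similarity (rotation within
    ~5 deg, scale 0.95-1.05, translation jitter) so that the landmark
    registration step has real work to do; bregma/lambda pixel landmarks
    are stored in the sidecar metadata.

    The truth table's ``area_mm2`` / ``frontal_edge_mm`` are measured from
    the ellipse rasterized on the common map grid (``grid_scale`` mm/px),
    i.e. they are exact for downstream scoring and converge to the analytic
    values as the grid is refined.  Blobs that would leave the raster are
    resampled (up to ``max_attempts``; then the simulation fails).
    """
    if refmap is None:
        refmap = make_reference_map()
    rng = np.random.default_rng(params.seed)
    grid = MapGrid.for_map(refmap, scale=grid_scale)
    ps = params.pixel_scale
    # image canvas: map extent plus headroom for rotation/translation
    ext_x = grid.shape[1] * grid.scale
    ext_y = grid.shape[0] * grid.scale
    W = int(np.ceil(ext_x * 1.2 / ps))
    H = int(np.ceil(ext_y * 1.2 / ps))
    map_center = np.array([grid.x0 + ext_x / 2, grid.y_max - ext_y / 2])

    specs = []
    for group, n, pc, psd, ac in [
        ("seizing", params.n_seizing, params.pos_center_s, params.pos_spread_s,
         params.area_center_s),
        ("nonseizing", params.n_nonseizing, params.pos_center_ns, params.pos_spread_ns,
         params.area_center_ns),
    ]:
        for i in range(n):
            specs.append((f"{'S' if group == 'seizing' else 'NS'}{i + 1:02d}",
                          group == "seizing", pc, psd, ac))

    masks: list[DorsalImageMask] = []
    truth_rows = []
    for animal_id, seizing, pc, psd, ac in specs:
        for attempt in range(max_attempts):
            pos = rng.normal(pc, psd)
            area = rng.normal(ac, params.area_spread)
            if area < _MIN_AREA:
                continue
            a_ap = np.sqrt(area * _LESION_ASPECT / np.pi)
            b_lat = a_ap / _LESION_ASPECT
            xc = rng.normal(2.0, 0.4)
            yc = pos - a_ap
            # must stay on the common map grid
            if (pos > grid.y_max - grid.scale or yc - a_ap < grid.y_max - ext_y
                    or xc - b_lat < grid.x0 or xc + b_lat > grid.x0 + ext_x):
                continue
            theta = rng.uniform(-0.08, 0.08)
            k = rng.uniform(0.95, 1.05) / ps  # px per mm
            jitter = rng.uniform(-10, 10, size=2)
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            t = np.array([(W - 1) / 2, (H - 1) / 2]) + jitter - k * R @ map_center

            def to_up(p):
                return k * (np.atleast_2d(p) @ R.T) + t

            # rasterize the ellipse in image space via the inverse mapping
            cols, rows_idx = np.meshgrid(np.arange(W), np.arange(H))
            up = np.column_stack([cols.ravel(), (H - 1) - rows_idx.ravel()])
            mm = (up - t) @ R / k  # R^-1 = R^T, applied from the right
            inside = ((mm[:, 0] - xc) / b_lat) ** 2 + ((mm[:, 1] - yc) / a_ap) ** 2 <= 1.0
            raster = inside.reshape(H, W).astype(np.uint8)
            if not raster.any() or raster[0].any() or raster[-1].any() \
                    or raster[:, 0].any() or raster[:, -1].any():
                continue
            br_up = to_up(refmap.bregma)[0]
            la_up = to_up(refmap.lambda_)[0]
            masks.append(DorsalImageMask(
                raster=raster, pixel_scale=ps,
                bregma_px=(float(br_up[0]), float((H - 1) - br_up[1])),
                lambda_px=(float(la_up[0]), float((H - 1) - la_up[1])),
                animal_id=animal_id, seizing=seizing,
            ))
            truth_mask = _rasterize_ellipse_on_grid(grid, xc, yc, a_ap, b_lat)
            rows = np.nonzero(truth_mask.any(axis=1))[0]
            truth_rows.append(dict(
                animal_id=animal_id, seizing=seizing,
                area_mm2=float(truth_mask.sum() * grid.pixel_area),
                frontal_edge_mm=float(grid.y_of_row(rows.min()) - refmap.lambda_[1]),
                position_drawn=float(pos), area_drawn=float(area),
                xc_mm=float(xc), yc_mm=float(yc),
                a_ap_mm=float(a_ap), b_lat_mm=float(b_lat),
            ))
            break
        else:
            raise RuntimeError(
                f"could not place lesion blob for {animal_id} in {max_attempts} attempts")
    return masks, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------- #
# cell stacks
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CellFieldSimParams:
    """Spherical-cell Z-stack with two intensity populations.

    Geometry defaults follow the acquisition convention of the study
    (square frames at 0.79 um/px, 1 um Z-step); cell diameters default to
    the two neuron populations reported in dysplastic cortex (~15 um
    baseline vs ~24 um mTOR-hyperactive).  ``min_separation`` is
    center-to-center and must not be smaller than the largest diameter so
    instance masks stay unambiguous.
    """

    n_cells: int = 15
    frame_shape: tuple[int, int] = (256, 256)
    n_frames: int = 40
    xy_scale: float = 0.79  # um/px
    z_step: float = 1.0  # um
    diameter_low: float = 15.0
    diameter_high: float = 24.0
    intensity_low_mean: float = 60.0
    intensity_high_mean: float = 180.0
    intensity_sd: float = 10.0
    background_mean: float = 20.0
    fraction_high: float = 0.3
    min_separation: float = 30.0
    min_xy_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_high <= 1.0:
            raise ValueError("fraction_high must lie in [0, 1]")
        if not self.min_separation > 0:
            raise ValueError("min_separation must be positive")
        ext = min(self.frame_shape[0], self.frame_shape[1]) * self.xy_scale
        if max(self.diameter_low, self.diameter_high) >= ext:
            raise ValueError("cell diameters must be smaller than the frame extent")


def simulate_cell_stack(params: CellFieldSimParams, with_intensity: bool = True,
                        max_attempts: int = 10_000,
                        ) -> tuple[CellStack, pd.DataFrame]:
    """Simulate a Z-stack of non-overlapping spherical cells.

    Per-frame instance-label masks are exact circle cross-sections of the
    spheres (labels 1..n); intensity frames add Gaussian pixel noise to a
    per-cell mean drawn from the cell's population distribution, over a
    noisy background, clipped to the 8-bit range.  The truth table holds
    centers (um, index*scale convention), diameters, population labels and
    per-cell mean intensities.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.frame_shape
    ext = np.array([W * params.xy_scale, H * params.xy_scale,
                    params.n_frames * params.z_step])
    high = rng.random(params.n_cells) < params.fraction_high
    diam = np.where(high, params.diameter_high, params.diameter_low)

    centers = np.empty((params.n_cells, 3))
    for i in range(params.n_cells):
        r = diam[i] / 2
        for attempt in range(max_attempts):
            c = rng.uniform([r, r, r], ext - r)
            ok = i == 0 or np.all(np.linalg.norm(centers[:i] - c, axis=1)
                                  >= params.min_separation)
            if ok and params.min_xy_separation is not None and i > 0:
                ok = np.all(np.linalg.norm(centers[:i, :2] - c[:2], axis=1)
                            >= params.min_xy_separation)
            if ok:
                centers[i] = c
                break
        else:
            raise RuntimeError(
                f"could not place cell {i + 1}/{params.n_cells} with "
                f"min_separation={params.min_separation} in {max_attempts} attempts")

    labels = np.zeros((params.n_frames, H, W), dtype=np.uint16)
    for i in range(params.n_cells):
        cx, cy, cz = centers[i]
        r = diam[i] / 2
        for k in range(params.n_frames):
            dz = k * params.z_step - cz
            if abs(dz) >= r:
                continue
            rk = np.sqrt(r ** 2 - dz ** 2)
            c0 = max(0, int(np.floor((cx - rk) / params.xy_scale)))
            c1 = min(W - 1, int(np.ceil((cx + rk) / params.xy_scale)))
            r0 = max(0, int(np.floor((cy - rk) / params.xy_scale)))
            r1 = min(H - 1, int(np.ceil((cy + rk) / params.xy_scale)))
            cols = np.arange(c0, c1 + 1) * params.xy_scale - cx
            rows = np.arange(r0, r1 + 1) * params.xy_scale - cy
            disk = rows[:, None] ** 2 + cols[None, :] ** 2 <= rk ** 2
            patch = labels[k, r0:r1 + 1, c0:c1 + 1]
            patch[disk] = i + 1

    cell_mean = np.where(high, params.intensity_high_mean, params.intensity_low_mean) \
        + rng.normal(0.0, params.intensity_sd, params.n_cells)
    intensity = None
    if with_intensity:
        intensity = rng.normal(params.background_mean, params.intensity_sd,
                               size=labels.shape)
        cellvox = labels > 0
        mean_lut = np.concatenate([[0.0], cell_mean])
        intensity[cellvox] = mean_lut[labels[cellvox]] \
            + rng.normal(0.0, params.intensity_sd, int(cellvox.sum()))
        intensity = np.clip(intensity, 0.0, 255.0)

    truth = pd.DataFrame(dict(
        cell=np.arange(1, params.n_cells + 1),
        x_um=centers[:, 0], y_um=centers[:, 1], z_um=centers[:, 2],
        diameter_um=diam,
        population=np.where(high, "high", "low"),
        intensity_mean=cell_mean,
    ))
    stack = CellStack(label_frames=labels, intensity_frames=intensity,
                      xy_scale=params.xy_scale, z_step=params.z_step)
    return stack, truth


# --------------------------------------------------------------------------- #
# axon traces
# --------------------------------------------------------------------------- #

FWHM_TO_SIGMA = 1.0 / 2.355  # Gaussian sigma per unit full-width-half-maximum


@dataclass(frozen=True)
class TraceSimParams:
    """Straight axon with Gaussian diameter bumps (boutons).

    ``boutons`` is a list of ``(arc_position um, rel_height fraction of
    shaft, fwhm um)``; ``noise_sd`` is multiplicative (fraction of the
    local diameter).  Noise is spatially correlated over
    ``noise_correlation`` um (white noise smoothed by a Gaussian kernel,
    then rescaled to sd = noise_sd): diameter estimates from traced image
    data share the optical point-spread support between neighboring
    nodes, so independent per-node noise would be unphysical at
    submicron node spacing.
    """

    length: float = 100.0
    node_spacing: float = 0.2
    shaft_diameter: float = 0.5
    boutons: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    noise_correlation: float = 1.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        for pos, h, w in self.boutons:
            if not 0.0 <= pos <= self.length:
                raise ValueError("bouton arc positions must lie within the trace")
            if h < 0 or w <= 0:
                raise ValueError("bouton rel_height must be >= 0 and width > 0")


def _bump_profile(s: np.ndarray, boutons, shaft: float) -> np.ndarray:
    d = np.ones_like(s)
    for pos, h, w in boutons:
        sigma = w * FWHM_TO_SIGMA
        d = d + h * np.exp(-0.5 * ((s - pos) / sigma) ** 2)
    return shaft * d


def simulate_axon_trace(params: TraceSimParams) -> tuple[AxonTrace, BoutonSet]:
    """Simulate a diameter profile; truth holds each bump's peak metrics."""
    rng = np.random.default_rng(params.seed)
    s = np.arange(0.0, params.length + params.node_spacing / 2, params.node_spacing)
    d = _bump_profile(s, params.boutons, params.shaft_diameter)
    if params.noise_sd > 0:
        white = rng.normal(0.0, 1.0, s.size)
        sig_nodes = params.noise_correlation / params.node_spacing
        if sig_nodes > 0.3:
            from scipy.ndimage import gaussian_filter1d
            eps = gaussian_filter1d(white, sig_nodes, mode="reflect")
            sd = eps.std()
            eps = eps / sd if sd > 0 else eps
        else:
            eps = white
        d = d * (1.0 + params.noise_sd * eps)
    nodes = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    trace = AxonTrace(nodes=nodes, diameters=d)
    truth_boutons = []
    for pos, h, w in params.boutons:
        peak_d = float(_bump_profile(np.array([pos]), params.boutons,
                                     params.shaft_diameter)[0])
        truth_boutons.append(Bouton(
            arc_position=float(pos), peak_diameter=peak_d, width=float(w),
            prominence=float(h), volume=bouton_volume(peak_d, float(w)),
        ))
    truth = BoutonSet(
        shaft_diameter=params.shaft_diameter,
        boutons=tuple(sorted(truth_boutons, key=lambda b: b.arc_position)),
        trace_length=float(s[-1]),
    )
    return trace, truth


# --------------------------------------------------------------------------- #
# cortical point clouds
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CloudSimParams:
    """Point cloud under a curved cortical surface with known depth density.

    ``depth_density`` tabulates a (not necessarily normalized) non-negative
    density over relative depth [0, 1]; ``None`` means uniform.  The
    surface is a paraboloid dome ``z = -curvature/2 * (x^2+y^2)`` with the
    lesion channel clustered around ``lesion_center``.
    """

    slab_extent: float = 1.6  # mm, square side
    cortical_thickness: float = 1.0  # mm
    surface_curvature: float = 0.1  # 1/mm
    n_cells: int = 10_000
    depth_density: tuple[float, ...] | None = None
    lesion_center: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_density is not None:
            dd = np.asarray(self.depth_density, dtype=float)
            if np.any(dd < 0) or dd.sum() <= 0:
                raise ValueError("depth_density must be non-negative with positive mass")


@dataclass
class CloudTruth:
    """Ground truth of a simulated cloud for scoring depth-profile recovery."""

    normalized_curve: np.ndarray  # input density tabulated on 100 bins, unit sum
    rel_depths: np.ndarray  # sampled relative depths of the profile channel
    surface_z: np.ndarray  # surface height at each point's (x, y)


def _sample_from_density(density: np.ndarray, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    p = density / density.sum()
    nb = density.size
    idx = rng.choice(nb, size=n, p=p)
    return (idx + rng.uniform(0.0, 1.0, n)) / nb


def simulate_cortical_cloud(params: CloudSimParams,
                            profile_channel: str = "tdTomato",
                            lesion_channel: str = "GFP",
                            ) -> tuple[PointCloud3D, CloudTruth]:
    """Sample a labeled 3D point cloud with a prescribed depth distribution.

    The profile channel's relative depths are drawn from ``depth_density``
    and embedded beneath the dome surface; the lesion channel is a compact
    cluster of shallow-to-mid-depth points around ``lesion_center`` whose
    center of mass defines the depth axis downstream.  Truth tabulates the
    input density on the standard 100-bin output grid.
    """
    rng = np.random.default_rng(params.seed)
    density = (np.ones(100) if params.depth_density is None
               else np.asarray(params.depth_density, dtype=float))
    L, T = params.slab_extent, params.cortical_thickness

    xy = rng.uniform(-L / 2, L / 2, size=(params.n_cells, 2))
    t = _sample_from_density(density, params.n_cells, rng)
    surf = -params.surface_curvature / 2 * (xy ** 2).sum(axis=1)
    z = surf - t * T
    pts_profile = np.column_stack([xy, z])

    n_gfp = max(200, params.n_cells // 10)
    gxy = rng.normal(params.lesion_center, 0.12, size=(n_gfp, 2))
    gxy = np.clip(gxy, -L / 2, L / 2)
    # lesion label spans the surface (apical processes in layer 1) to mid-depth
    gt = rng.uniform(0.0, 0.6, n_gfp)
    gsurf = -params.surface_curvature / 2 * (gxy ** 2).sum(axis=1)
    pts_gfp = np.column_stack([gxy, gsurf - gt * T])

    positions = np.vstack([pts_profile, pts_gfp])
    channels = np.array([profile_channel] * params.n_cells + [lesion_channel] * n_gfp)
    cloud = PointCloud3D(positions=positions, channel_labels=channels)

    # tabulate the input density on the pipeline's output axis: depths are
    # rescaled by the 95th-percentile depth downstream, so the truth curve
    # is expressed in the same units (relative depth / q95 of the density)
    src_centers = (np.arange(density.size) + 0.5) / density.size
    cdf = np.cumsum(density) / density.sum()
    q95 = float(np.interp(0.95, cdf, src_centers))
    centers = (np.arange(100) + 0.5) / 100
    curve = np.interp(centers * q95, src_centers, density, left=density[0], right=0.0)
    curve = curve / curve.sum()
    truth = CloudTruth(normalized_curve=curve, rel_depths=t,
                       surface_z=np.concatenate([surf, gsurf]))
    return cloud, truth
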