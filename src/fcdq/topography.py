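"""Lesion-to-atlas topography and the seizure-prediction logistic model.

Dorsal fluorescence lesion masks are registered onto a reference cortical
map via a landmark (bregma/lambda) similarity transform, and per-animal
predictors are derived in map coordinates:

* lesion area (mm^2),
* frontal-edge position (mm anterior of lambda, anterior positive),
* LSI, the lesion severity index  ``sqrt(area) + frontal_edge``,
* per-area and per-domain atlas coverage fractions.

Group overlap is summarized by a signed heatmap (+1/N_seizing per seizing
mask pixel, -1/N_nonseizing per non-seizing mask pixel), and seizure
outcome is modeled by logistic regression on the frontal-edge position,
``p(x) = 1 / (1 + exp(-(beta0 + beta1*x)))``.

Coordinate conventions
----------------------
Map coordinates are in mm with lambda at the origin, x lateral (midline 0)
and y anterior-positive.  Rasters are row-major with row 0 the
anterior-most row; pixel landmarks are (x_px, y_px) = (column, row) with
y_px increasing posteriorly.  Internally pixel points are flipped to a
y-up frame so that map->image mappings are proper (reflection-free)
similarities.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "CorticalArea",
    "ReferenceMap",
    "DorsalImageMask",
    "SimilarityTransform",
    "LesionRecord",
    "LogisticModel",
    "MapGrid",
    "fit_similarity_transform",
    "project_mask_to_map",
    "lesion_metrics",
    "area_coverage",
    "domain_coverage",
    "build_group_heatmap",
    "fit_seizure_logistic",
]

DEFAULT_GRID_SCALE = 0.02  # mm/px of the common map-space raster


class DegenerateLandmarksError(ValueError):
    """Raised when landmark configurations cannot determine a similarity."""


@dataclass(frozen=True)
class CorticalArea:
    name: str
    abbreviation: str
    polygon: Polygon


@dataclass(frozen=True)
class ReferenceMap:
    """Polygonal cortical-area atlas in mm map coordinates.

    ``domains`` maps each area abbreviation to one of the three functional
    domains (Sensory, Executive, Limbic/Associative).  ``bregma`` must lie
    anterior of ``lambda_`` (larger y).
    """

    areas: tuple[CorticalArea, ...]
    domains: Mapping[str, str]
    bregma: tuple[float, float]
    lambda_: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.bregma[1] > self.lambda_[1]:
            raise ValueError("bregma must be strictly anterior of lambda")
        for a in self.areas:
            if not a.polygon.is_valid:
                raise ValueError(f"polygon for {a.abbreviation} is not simple")

    @property
    def abbreviations(self) -> list[str]:
        return [a.abbreviation for a in self.areas]

    def area(self, abbreviation: str) -> CorticalArea:
        for a in self.areas:
            if a.abbreviation == abbreviation:
                return a
        raise KeyError(abbreviation)

    def bounds(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(a.polygon.bounds for a in self.areas))
        return min(xs0), min(ys0), max(xs1), max(ys1)


@dataclass
class DorsalImageMask:
    """Binary dorsal lesion mask with pixel scale and skull landmarks."""

    raster: np.ndarray  # 2D, nonzero = lesion
    pixel_scale: float  # mm/px
    bregma_px: tuple[float, float] | None  # (x=col, y=row)
    lambda_px: tuple[float, float] | None
    animal_id: str = ""
    seizing: bool | None = None

    @property
    def is_empty(self) -> bool:
        return not np.any(self.raster)


@dataclass(frozen=True)
class SimilarityTransform:
    """2D similarity y = scale * R(rotation) @ x + translation."""

    scale: float
    rotation: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        r = inv_scale * np.array([[c, -s], [s, c]])
        t = -r @ np.asarray(self.translation)
        return SimilarityTransform(inv_scale, inv_rot, (float(t[0]), float(t[1])))


@dataclass
class LesionRecord:
    """Per-animal lesion metrics in map coordinates."""

    animal_id: str
    area: float  # mm^2
    frontal_edge: float  # mm anterior of lambda
    lsi: float  # sqrt(area) + frontal_edge
    coverage: dict[str, float] = field(default_factory=dict)
    seizing: bool | None = None


@dataclass(frozen=True)
class LogisticModel:
    """Fitted seizure-outcome logistic model (results object).

    ``halfway_point = -beta0/beta1`` is the position where the predicted
    seizure probability crosses 0.5; ``accuracy`` is in-sample at the 0.5
    cutoff.  ``separated`` flags complete separation (coefficients diverge
    and are unreliable).
    """

    beta0: float
    beta1: float
    loglik: float
    lrt_p: float
    halfway_point: float
    accuracy: float
    n: int
    separated: bool = False
    n_iter: int = 0

    def predict(self, x) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            "Seizure logistic model",
            f"  n = {self.n}",
            f"  beta0 = {self.beta0:.4f}",
            f"  beta1 = {self.beta1:.4f} per mm",
            f"  LRT p = {self.lrt_p:.4g}",
            f"  50% point = {self.halfway_point:.3f} mm",
            f"  in-sample accuracy = {self.accuracy:.1%}",
        ]
        if self.separated:
            lines.append("  WARNING: complete separation; coefficients unreliable")
        return "\n".join(lines)


@dataclass(frozen=True)
class MapGrid:
    """Fixed map-space raster geometry: row 0 anterior, mm coordinates."""

    x0: float  # mm of the left edge
    y_max: float  # mm of the top (anterior) edge
    scale: float  # mm/px
    shape: tuple[int, int]  # (ny, nx)

    @classmethod
    def for_map(cls, refmap: ReferenceMap, scale: float = DEFAULT_GRID_SCALE,
                margin: float = 0.5) -> "MapGrid":
        x_lo, y_lo, x_hi, y_hi = refmap.bounds()
        x_lo = min(x_lo, refmap.lambda_[0]) - margin
        y_lo = min(y_lo, refmap.lambda_[1]) - margin
        x_hi = max(x_hi, refmap.bregma[0]) + margin
        y_hi = max(y_hi, refmap.bregma[1]) + margin
        nx = int(np.ceil((x_hi - x_lo) / scale))
        ny = int(np.ceil((y_hi - y_lo) / scale))
        return cls(x0=x_lo, y_max=y_lo + ny * scale, scale=scale, shape=(ny, nx))

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) mm coordinate arrays of all pixel centers, shape ``self.shape``."""
        ny, nx = self.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.scale
        ys = self.y_max - (np.arange(ny) + 0.5) * self.scale
        return np.meshgrid(xs, ys)

    def y_of_row(self, row) -> np.ndarray:
        return self.y_max - (np.asarray(row) + 0.5) * self.scale

    @property
    def pixel_area(self) -> float:
        return self.scale ** 2


def fit_similarity_transform(src_landmarks, dst_landmarks) -> SimilarityTransform:
    """Least-squares similarity (Umeyama closed form, no reflection).

    Minimizes ``sum ||scale*R(theta) src + t - dst||^2``; exact with two
    distinct point pairs.  Raises :class:`DegenerateLandmarksError` when
    the source points coincide.
    """
    src = np.atleast_2d(np.asarray(src_landmarks, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_landmarks, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2 or src.shape[1] != 2:
        raise ValueError("need >= 2 matched 2D point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    var_s = (sc ** 2).sum() / src.shape[0]
    if var_s < 1e-18:
        raise DegenerateLandmarksError("source landmarks are coincident")
    cov = dc.T @ sc / src.shape[0]
    u, d, vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(u @ vt)) or 1.0
    s_diag = np.array([1.0, sgn])
    rot = u @ np.diag(s_diag) @ vt
    scale = float((d * s_diag).sum() / var_s)
    if scale <= 0:
        raise DegenerateLandmarksError("degenerate landmark configuration")
    t = mu_d - scale * rot @ mu_s
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    return SimilarityTransform(scale, theta, (float(t[0]), float(t[1])))


def _px_to_up(points_px: np.ndarray, n_rows: int) -> np.ndarray:
    """Flip pixel (x=col, y=row) points to a y-up frame."""
    p = np.atleast_2d(np.asarray(points_px, dtype=float)).copy()
    p[:, 1] = (n_rows - 1) - p[:, 1]
    return p


def project_mask_to_map(mask: DorsalImageMask, refmap: ReferenceMap,
                        grid: MapGrid | None = None,
                        grid_scale: float = DEFAULT_GRID_SCALE) -> np.ndarray:
    """Warp a dorsal mask into map space on a fixed grid.

    The similarity from map landmarks (bregma, lambda in mm) to the mask's
    pixel landmarks is fitted; each map-grid pixel center is pushed through
    it and the mask is sampled by nearest neighbor (the inverse warp of the
    image-to-map transform).  Total area is preserved within ~2% at the
    default 0.02 mm/px grid for typical lesion sizes.
    """
    if mask.bregma_px is None or mask.lambda_px is None:
        missing = "bregma_px" if mask.bregma_px is None else "lambda_px"
        raise ValueError(f"mask landmark {missing} is missing")
    if grid is None:
        grid = MapGrid.for_map(refmap, scale=grid_scale)
    n_rows = mask.raster.shape[0]
    dst_up = _px_to_up(np.array([mask.bregma_px, mask.lambda_px]), n_rows)
    t = fit_similarity_transform([refmap.bregma, refmap.lambda_], dst_up)
    X, Y = grid.pixel_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    px = t.apply(pts)
    col = np.rint(px[:, 0]).astype(int)
    row = np.rint((n_rows - 1) - px[:, 1]).astype(int)
    ok = (row >= 0) & (row < mask.raster.shape[0]) & (col >= 0) & (col < mask.raster.shape[1])
    out = np.zeros(pts.shape[0], dtype=bool)
    out[ok] = mask.raster[row[ok], col[ok]] != 0
    return out.reshape(grid.shape)


def lesion_metrics(mask_in_map: np.ndarray, refmap: ReferenceMap, grid: MapGrid,
                   animal_id: str = "", seizing: bool | None = None) -> LesionRecord:
    """Area, frontal-edge position and LSI of a map-space lesion mask."""
    mask = np.asarray(mask_in_map, dtype=bool)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    area = float(mask.sum() * grid.pixel_area)
    rows = np.nonzero(mask.any(axis=1))[0]
    frontal = float(grid.y_of_row(rows.min()) - refmap.lambda_[1])
    return LesionRecord(
        animal_id=animal_id,
        area=area,
        frontal_edge=frontal,
        lsi=float(np.sqrt(area) + frontal),
        seizing=seizing,
    )


def area_coverage(mask_in_map: np.ndarray, refmap: ReferenceMap,
                  grid: MapGrid) -> dict[str, float]:
    """Fraction of each atlas polygon covered by the lesion mask."""
    mask = np.asarray(mask_in_map, dtype=bool)
    X, Y = grid.pixel_centers()
    cov: dict[str, float] = {}
    for a in refmap.areas:
        inside = shapely.contains_xy(a.polygon, X.ravel(), Y.ravel()).reshape(grid.shape)
        denom = int(inside.sum())
        cov[a.abbreviation] = float((mask & inside).sum() / denom) if denom else 0.0
    return cov


def domain_coverage(coverage: Mapping[str, float], refmap: ReferenceMap) -> dict[str, float]:
    """Domain-level coverage: unweighted mean over member-area fractions."""
    out: dict[str, list[float]] = {}
    for abbr, frac in coverage.items():
        out.setdefault(refmap.domains[abbr], []).append(frac)
    return {dom: float(np.mean(v)) for dom, v in out.items()}


def build_group_heatmap(masks_seizing: Sequence[np.ndarray],
                        masks_nonseizing: Sequence[np.ndarray]) -> np.ndarray:
    """Signed overlap heatmap: +1/N_s per seizing mask, -1/N_ns per non-seizing."""
    if len(masks_seizing) == 0 and len(masks_nonseizing) == 0:
        raise ValueError("at least one group must contain a mask")
    ref = (masks_seizing or masks_nonseizing)[0]
    heat = np.zeros(np.asarray(ref).shape, dtype=float)
    if masks_seizing:
        for m in masks_seizing:
            heat += np.asarray(m, dtype=bool) / len(masks_seizing)
    if masks_nonseizing:
        for m in masks_nonseizing:
            heat -= np.asarray(m, dtype=bool) / len(masks_nonseizing)
    return heat


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_seizure_logistic(x: Sequence[float], y: Sequence[int],
                         tol: float = 1e-10, max_iter: int = 100,
                         separation_norm: float = 1e3) -> LogisticModel:
    """Maximum-likelihood logistic regression of a binary outcome on position.

    Newton-Raphson with step halving; convergence when the Newton step norm
    falls below ``tol``.  The likelihood-ratio test compares against the
    intercept-only model (chi-square, 1 df).  Complete separation is
    detected by coefficient divergence (``||beta|| > 1e3``) and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched x/y with n >= 4")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones_like(x), x])
    pbar = y.mean()
    beta = np.array([np.log(pbar / (1 - pbar)), 0.0])
    ll = _loglik(X @ beta, y)
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped Newton: halve until the likelihood does not decrease
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll_new = _loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll = _loglik(X @ beta, y)
        # complete separation: coefficients diverge, or the likelihood
        # saturates at its perfect-classification asymptote of 0
        if np.linalg.norm(beta) > separation_norm or ll > -1e-8:
            separated = True
            break
        if np.linalg.norm(lam * step) < tol:
            break
    ll0 = _loglik(np.full_like(x, np.log(pbar / (1 - pbar))), y)
    lrt = max(0.0, 2.0 * (ll - ll0))
    lrt_p = float(stats.chi2.sf(lrt, df=1))
    halfway = float(-beta[0] / beta[1]) if beta[1] != 0 else np.nan
    pred = 1.0 / (1.0 + np.exp(-(X @ beta)))
    accuracy = float(np.mean((pred > 0.5) == (y == 1)))
    return LogisticModel(
        beta0=float(beta[0]), beta1=float(beta[1]), loglik=ll, lrt_p=lrt_p,
        halfway_point=halfway, accuracy=accuracy, n=int(x.size),
        separated=separated, n_iter=it,
    )
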