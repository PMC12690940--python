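"""Readers/writers for on-disk formats, run configuration and the pipeline.

Conventions fixed here for the whole package:

* images are row/column rasters, origin top-left, 0-based; pixel landmark
  points are (x=column, y=row);
* physical coordinates are mm for macroscopic data and um for microscopic
  data, anterior positive along the AP axis; bins are half-open [lo, hi);
* SWC radii are converted to diameters by multiplying by 2 (formats in
  the wild disagree; this package is explicit about it);
* all numeric CSV output keeps full float precision (repr round-trip).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from . import boutons as _boutons
from . import cytoarch as _cyto
from . import depthprof as _depth
from . import topography as _topo
from .boutons import AxonTrace
from .topography import CorticalArea, DorsalImageMask, MapGrid, ReferenceMap

__all__ = [
    "RunConfig",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "read_trace",
    "write_trace_csv",
    "write_trace_swc",
    "run_pipeline",
]

_SIDECAR_FIELDS = ("pixel_scale", "bregma_px", "lambda_px")


def write_mask(path: str | Path, mask: DorsalImageMask) -> Path:
    """Write a binary mask as 8-bit PNG/TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    img = (np.asarray(mask.raster) != 0).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    sidecar = dict(
        pixel_scale=mask.pixel_scale,
        bregma_px=list(mask.bregma_px) if mask.bregma_px is not None else None,
        lambda_px=list(mask.lambda_px) if mask.lambda_px is not None else None,
        animal_id=mask.animal_id,
        seizing=mask.seizing,
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_mask(path: str | Path, sidecar: str | Path | None = None) -> DorsalImageMask:
    """Read a mask raster (any nonzero pixel -> 1) with its sidecar metadata.

    A missing required sidecar field raises an error naming the field.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text())
    for f in _SIDECAR_FIELDS:
        if f not in meta or meta[f] is None:
            raise ValueError(f"mask sidecar {sidecar} is missing field {f!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return DorsalImageMask(
        raster=(img != 0).astype(np.uint8),
        pixel_scale=float(meta["pixel_scale"]),
        bregma_px=tuple(meta["bregma_px"]),
        lambda_px=tuple(meta["lambda_px"]),
        animal_id=str(meta.get("animal_id", "")),
        seizing=meta.get("seizing"),
    )


def write_atlas(path: str | Path, refmap: ReferenceMap) -> Path:
    """Serialize a reference map to JSON (named polygons in mm, landmarks)."""
    doc = dict(
        bregma=list(refmap.bregma),
        lambda_=list(refmap.lambda_),
        areas=[dict(name=a.name, abbreviation=a.abbreviation,
                    polygon=[list(p) for p in a.polygon.exterior.coords],
                    domain=refmap.domains[a.abbreviation])
               for a in refmap.areas],
    )
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_atlas(path: str | Path) -> ReferenceMap:
    doc = json.loads(Path(path).read_text())
    areas = tuple(
        CorticalArea(name=a["name"], abbreviation=a["abbreviation"],
                     polygon=Polygon(a["polygon"]))
        for a in doc["areas"]
    )
    domains = {a["abbreviation"]: a["domain"] for a in doc["areas"]}
    return ReferenceMap(areas=areas, domains=domains,
                        bregma=tuple(doc["bregma"]), lambda_=tuple(doc["lambda_"]))


def read_trace(path: str | Path) -> AxonTrace:
    """Read an axon trace from SWC (radius column, x2 -> diameter) or CSV.

    Only single unbranched paths are accepted (per-axon tracing); SWC
    files with branch points raise an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".swc":
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append((int(parts[0]), float(parts[2]), float(parts[3]),
                         float(parts[4]), float(parts[5]), int(parts[6])))
        if len(rows) < 2:
            raise ValueError(f"{path}: SWC trace needs >= 2 nodes")
        parents = [r[5] for r in rows]
        ids = [r[0] for r in rows]
        children: dict[int, int] = {}
        for nid, parent in zip(ids, parents):
            if parent != -1:
                children[parent] = children.get(parent, 0) + 1
        if any(c > 1 for c in children.values()) or parents.count(-1) != 1:
            raise ValueError(f"{path}: branching SWC structure; "
                             "only single unbranched paths are supported")
        order = {nid: i for i, nid in enumerate(ids)}
        # follow the parent chain from the root
        root = ids[parents.index(-1)]
        chain = [root]
        child_of = {p: nid for nid, p in zip(ids, parents) if p != -1}
        while chain[-1] in child_of:
            chain.append(child_of[chain[-1]])
        if len(chain) != len(rows):
            raise ValueError(f"{path}: disconnected SWC structure")
        rows = [rows[order[nid]] for nid in chain]
        nodes = np.array([[r[1], r[2], r[3]] for r in rows])
        diam = np.array([2.0 * r[4] for r in rows])
        return AxonTrace(nodes=nodes, diameters=diam)
    df = pd.read_csv(path, comment="#")
    needed = {"x", "y", "z", "diameter"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: CSV trace needs columns {sorted(needed)}")
    return AxonTrace(nodes=df[["x", "y", "z"]].to_numpy(dtype=float),
                     diameters=df["diameter"].to_numpy(dtype=float))


def write_trace_csv(path: str | Path, trace: AxonTrace) -> Path:
    df = pd.DataFrame(dict(x=trace.nodes[:, 0], y=trace.nodes[:, 1],
                           z=trace.nodes[:, 2], diameter=trace.diameters))
    df.to_csv(path, index=False)
    return Path(path)


def write_trace_swc(path: str | Path, trace: AxonTrace) -> Path:
    lines = ["# id type x y z radius parent"]
    for i, (p, d) in enumerate(zip(trace.nodes, trace.diameters), start=1):
        parent = i - 1 if i > 1 else -1
        lines.append(f"{i} 2 {float(p[0])!r} {float(p[1])!r} {float(p[2])!r} "
                     f"{float(d) / 2.0!r} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline stage parameters with their standard defaults."""

    out_dir: str = "fcdq_out"
    seed: int = 0
    # cell detection
    downsample: int = 4
    count_threshold: int = 4
    margin_frames: int = 5
    histogram_bins: int = 256
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    background_factor_ps6: float = 3.0
    background_factor_gfp: float = 1.5
    # bouton detection
    min_peak_height: float = 0.2
    min_peak_prominence: float = 0.1
    min_peak_separation: float = 1.0
    # depth profile
    column_width_mm: float = 1.0
    depth_step_mm: float = 0.01
    # topography
    map_grid_scale: float = 0.02
    classification_cutoff: float = 0.5
    # synthetic cohort/stack/trace/cloud sizes for the all-synthetic run
    n_stacks: int = 3
    n_traces: int = 6
    n_cloud_points: int = 5000

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) \
                    and f.name != "seed" and v <= 0:
                raise ValueError(f"config parameter {f.name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stretch_percentiles",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib
            return cls.from_dict(tomllib.loads(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # the destination does not affect the computation
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    header = f"# config_hash={config.config_hash()}\n# seed={config.seed}\n"
    path.write_text(header + df.to_csv(index=False))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full all-synthetic pipeline and write tables, rasters and a log.

    Stages (dependency order): lesion cohort simulation + topography,
    cell-stack simulation + 3D detection/classification, axon-trace
    simulation + bouton detection, cortical-cloud simulation + depth
    profiles.  Every output table carries the config hash and seed; the
    structured log records per-stage counts.  Any stage error aborts with
    the stage name.
    """
    from . import synthio  # deferred: synthio imports the analysis modules

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **kv) -> None:
        log_lines.append(" ".join([f"stage={stage}"] + [f"{k}={v}" for k, v in kv.items()]))

    stage = "topography"
    try:
        refmap = synthio.make_reference_map()
        write_atlas(out / "atlas.json", refmap)
        cohort = synthio.CohortSimParams(seed=config.seed)
        masks, truth = synthio.simulate_lesion_cohort(
            cohort, refmap=refmap, grid_scale=config.map_grid_scale)
        grid = MapGrid.for_map(refmap, scale=config.map_grid_scale)
        records, proj_s, proj_ns = [], [], []
        for m in masks:
            proj = _topo.project_mask_to_map(m, refmap, grid=grid)
            rec = _topo.lesion_metrics(proj, refmap, grid, animal_id=m.animal_id,
                                       seizing=m.seizing)
            rec.coverage = _topo.area_coverage(proj, refmap, grid)
            records.append(rec)
            (proj_s if m.seizing else proj_ns).append(proj)
        rows = [dict(animal_id=r.animal_id, seizing=r.seizing, area_mm2=r.area,
                     frontal_edge_mm=r.frontal_edge, lsi=r.lsi, **r.coverage)
                for r in records]
        lesions = pd.DataFrame(rows)
        _write_table(out / "lesions.csv", lesions, config)
        _write_table(out / "lesions_truth.csv", truth, config)
        heat = _topo.build_group_heatmap(proj_s, proj_ns)
        tifffile.imwrite(out / "heatmap.tiff", heat.astype(np.float32))
        model = _topo.fit_seizure_logistic(lesions["frontal_edge_mm"],
                                           lesions["seizing"].astype(int))
        (out / "logistic.json").write_text(json.dumps(dict(
            beta0=model.beta0, beta1=model.beta1, lrt_p=model.lrt_p,
            halfway_point=model.halfway_point, accuracy=model.accuracy,
            separated=model.separated), indent=1))
        log(stage, masks_read=len(masks), records=len(records))

        stage = "cells"
        det_rows = []
        for si in range(config.n_stacks):
            params = synthio.CellFieldSimParams(seed=config.seed + 1000 + si)
            stack, struth = synthio.simulate_cell_stack(params)
            dets = _cyto.detect_cells_3d(
                stack, downsample=config.downsample,
                count_threshold=config.count_threshold,
                margin_frames=config.margin_frames, seed=config.seed)
            for d in dets:
                det_rows.append(dict(stack=si, x_um=d.centroid[0], y_um=d.centroid[1],
                                     z_um=d.centroid[2],
                                     effective_diameter_um=d.effective_diameter,
                                     mean_intensity=d.mean_intensity))
        cells = pd.DataFrame(det_rows)
        _write_table(out / "cells.csv", cells, config)
        log(stage, stacks=config.n_stacks, cells_detected=len(cells))

        stage = "boutons"
        brows = []
        for ti in range(config.n_traces):
            rng = np.random.default_rng(config.seed + 2000 + ti)
            n_b = int(rng.integers(3, 8))
            positions = np.sort(rng.uniform(5, 95, n_b))
            bl = tuple((float(p), float(rng.uniform(0.4, 1.0)),
                        float(rng.uniform(1.5, 3.0))) for p in positions)
            tp = synthio.TraceSimParams(boutons=bl, noise_sd=0.02,
                                        seed=config.seed + 2000 + ti)
            trace, _btruth = synthio.simulate_axon_trace(tp)
            bset = _boutons.detect_boutons(trace, _boutons.PeakParams(
                min_height=config.min_peak_height,
                min_prominence=config.min_peak_prominence,
                min_separation=config.min_peak_separation))
            for b in bset.boutons:
                brows.append(dict(trace=ti, arc_position_um=b.arc_position,
                                  diameter_um=b.peak_diameter, width_um=b.width,
                                  volume_um3=b.volume,
                                  shaft_um=bset.shaft_diameter))
        btable = pd.DataFrame(brows)
        _write_table(out / "boutons.csv", btable, config)
        log(stage, traces=config.n_traces, boutons_accepted=len(btable))

        stage = "depth"
        cp = synthio.CloudSimParams(n_cells=config.n_cloud_points, seed=config.seed + 3000)
        cloud, _ctruth = synthio.simulate_cortical_cloud(cp)
        prof = _depth.compute_depth_profile(cloud, bin_step=config.depth_step_mm,
                                            column_width=config.column_width_mm)
        _write_table(out / "depth_profile.csv", pd.DataFrame(dict(
            rel_depth=(np.arange(prof.normalized_curve.size) + 0.5)
            / prof.normalized_curve.size,
            density=prof.normalized_curve)), config)
        log(stage, points=len(cloud.positions), in_column=prof.n_in_column)
    except Exception as exc:
        log(stage, error=type(exc).__name__)
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
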