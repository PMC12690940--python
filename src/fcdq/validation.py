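"""Recovery experiments that score the pipeline against generator truth.

These routines run the full analysis path on freshly simulated data and
measure how well the known ground truth is recovered: threshold-method
agreement on bimodal pS6-like slices, exact cell-count recovery, bouton
detection precision/recall, cohort-level direction of the lesion-position
effect, and null-calibration of the logistic and PC1 tests.  They back
both the test suite and the reproduction script.
"""
from __future__ import annotations

import numpy as np

from . import boutons as bt
from . import cytoarch as cy
from . import depthprof as dp
from . import synthio as sy
from . import topography as tp
from .cohortstats import mann_whitney_u

__all__ = [
    "threshold_agreement",
    "cell_count_recovery",
    "bouton_precision_recall",
    "cohort_direction",
    "logistic_null_pvalues",
    "pc1_null_pvalues",
]


def threshold_agreement(n_slices: int = 20, seed: int = 0) -> dict:
    """Bi-Gaussian vs 3x-background threshold agreement on bimodal slices.

    Each slice is a simulated pS6 stack with two cell-intensity
    populations 6 sigma apart on the 8-bit scale and a background whose
    mean is one third of the low-population mean.  The full pipeline runs
    per slice: 3D detection, per-cell mean intensities, 256-bin histogram
    + bi-Gaussian fit (midpoint threshold) vs 3x the mean of 20 points
    drawn from the background distribution.  Returns the per-slice
    absolute relative differences in percent and their maximum.
    """
    rng = np.random.default_rng(seed)
    low, high, sd = 178.0, 187.0, 1.5  # 6 sigma separation
    background = low / 3.0
    diffs = []
    for si in range(n_slices):
        params = sy.CellFieldSimParams(
            n_cells=100, frame_shape=(320, 320), n_frames=40,
            diameter_low=14.0, diameter_high=20.0,
            intensity_low_mean=low, intensity_high_mean=high,
            intensity_sd=sd, background_mean=background,
            fraction_high=0.5, min_separation=22.0,
            seed=int(rng.integers(2 ** 31)),
        )
        stack, _truth = sy.simulate_cell_stack(params)
        dets = cy.detect_cells_3d(stack, seed=int(rng.integers(2 ** 31)))
        intensities = [d.mean_intensity for d in dets]
        model = cy.threshold_bigauss(intensities)
        bg_img = rng.normal(background, sd, size=(1, 20))
        t_bg = cy.threshold_background(bg_img, [(0, j) for j in range(20)], factor=3.0)
        diffs.append(abs(model.threshold - t_bg) / model.threshold * 100.0)
    return dict(per_slice_pct=diffs, max_pct=float(np.max(diffs)),
                median_pct=float(np.median(diffs)), n=n_slices)


def cell_count_recovery(n_stacks: int = 200, k_range: tuple[int, int] = (5, 50),
                        seed: int = 0) -> dict:
    """Exact-K recovery and centroid accuracy of 3D cell detection.

    Simulated stacks hold K = 5..50 spheres (12-16 um) whose centers are
    separated by at least 1.5x the largest diameter both in 3D and in the
    XY projection (the accumulator counting scheme assumes at most one
    cell per XY location per sub-stack).  Detected centroids are matched
    to truth by nearest neighbor.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    errors = []
    for _ in range(n_stacks):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        params = sy.CellFieldSimParams(
            n_cells=k, frame_shape=(320, 320), n_frames=40,
            diameter_low=12.0, diameter_high=16.0, fraction_high=0.5,
            min_separation=24.0, min_xy_separation=24.0,
            seed=int(rng.integers(2 ** 31)),
        )
        stack, truth = sy.simulate_cell_stack(params, with_intensity=False)
        dets = cy.detect_cells_3d(stack, seed=int(rng.integers(2 ** 31)))
        if len(dets) == k:
            exact += 1
            centers = truth[["x_um", "y_um", "z_um"]].to_numpy()
            for d in dets:
                dist = np.linalg.norm(centers - np.asarray(d.centroid), axis=1)
                errors.append(float(dist.min()))
    return dict(exact_fraction=exact / n_stacks,
                mean_centroid_error_um=float(np.mean(errors)) if errors else float("nan"),
                max_centroid_error_um=float(np.max(errors)) if errors else float("nan"),
                n=n_stacks)


def _random_bouton_layout(rng: np.random.Generator, length: float,
                          min_gap: float = 2.5,
                          height_range: tuple[float, float] = (0.3, 1.0),
                          fwhm_range: tuple[float, float] = (0.75, 1.5),
                          density: float = 0.2) -> tuple:
    """Bouton layout at the linear density observed on real axons (~0.2/um)."""
    n = max(1, int(round(density * length)))
    for _ in range(200):
        pos = np.sort(rng.uniform(3.0, length - 3.0, n))
        if n == 1 or np.min(np.diff(pos)) >= min_gap:
            break
    else:
        pos = np.arange(3.0, length - 3.0, min_gap)[:n]
    return tuple((float(p), float(rng.uniform(*height_range)),
                  float(rng.uniform(*fwhm_range))) for p in pos)


def bouton_precision_recall(n_traces: int = 200, noise_sd: float = 0.0,
                            seed: int = 0, match_tol: float = 1.0) -> dict:
    """Pooled precision/recall of bouton detection vs generator truth.

    Traces carry bumps of relative height >= 0.3, FWHM >= 3 node
    spacings and mutual separation >= 2 um at a realistic linear density;
    a detection within ``match_tol`` um of a true bump position counts as
    a hit (one per bump).
    """
    rng = np.random.default_rng(seed)
    tp_n = fp_n = fn_n = 0
    for _ in range(n_traces):
        layout = _random_bouton_layout(rng, length=60.0)
        params = sy.TraceSimParams(length=60.0, node_spacing=0.25,
                                   shaft_diameter=0.5, boutons=layout,
                                   noise_sd=noise_sd,
                                   seed=int(rng.integers(2 ** 31)))
        trace, truth = sy.simulate_axon_trace(params)
        found = bt.detect_boutons(trace)
        truth_pos = np.array([b.arc_position for b in truth.boutons])
        det_pos = np.array([b.arc_position for b in found.boutons])
        used = np.zeros(truth_pos.size, dtype=bool)
        hits = 0
        for p in det_pos:
            d = np.abs(truth_pos - p)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= match_tol:
                used[j] = True
                hits += 1
        tp_n += hits
        fp_n += det_pos.size - hits
        fn_n += truth_pos.size - hits
    precision = tp_n / (tp_n + fp_n) if tp_n + fp_n else float("nan")
    recall = tp_n / (tp_n + fn_n) if tp_n + fn_n else float("nan")
    return dict(precision=precision, recall=recall, n=n_traces)


def cohort_direction(n_reps: int = 500, seed: int = 0) -> dict:
    """Direction of the seizing vs non-seizing frontal-position difference.

    Replicated cohorts are drawn from the printed group summaries
    (seizing 7.4 [6.5-7.8] mm, n=12; non-seizing 6.1 [5.6-6.4] mm, n=14);
    each replicate compares positions by Mann-Whitney and records whether
    the seizing median exceeds the non-seizing median.
    """
    rng = np.random.default_rng(seed)
    params = sy.CohortSimParams()
    positive = 0
    pvals = []
    for _ in range(n_reps):
        truth = sy.draw_cohort_truth(params, rng=rng)
        s = truth.loc[truth.seizing, "position_drawn"].to_numpy()
        ns = truth.loc[~truth.seizing, "position_drawn"].to_numpy()
        if np.median(s) > np.median(ns):
            positive += 1
        pvals.append(mann_whitney_u(s, ns).p_raw)
    return dict(fraction_positive=positive / n_reps,
                median_p=float(np.median(pvals)), n=n_reps)


def logistic_null_pvalues(n_reps: int = 1000, n: int = 40, seed: int = 0) -> np.ndarray:
    """LRT p-values under the null (labels independent of position)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_reps:
        x = rng.normal(0.0, 1.0, n)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        model = tp.fit_seizure_logistic(x, y)
        if not model.separated:
            out.append(model.lrt_p)
    return np.array(out)


def pc1_null_pvalues(n_reps: int = 300, n_per_group: int = 10,
                     n_points: int = 2000, seed: int = 0) -> np.ndarray:
    """PC1 group-test p-values when both groups share one depth density.

    Each animal's profile is a multinomial draw of ``n_points`` cells
    from a common smooth laminar density, so any group difference is
    spurious.
    """
    rng = np.random.default_rng(seed)
    centers = (np.arange(100) + 0.5) / 100
    density = np.exp(-0.5 * ((centers - 0.4) / 0.2) ** 2) + 0.2
    density /= density.sum()
    pvals = []
    for _ in range(n_reps):
        profiles = [dp.DepthProfile.from_curve(
            rng.multinomial(n_points, density).astype(float))
            for _ in range(2 * n_per_group)]
        groups = [0] * n_per_group + [1] * n_per_group
        pvals.append(dp.compare_profiles(profiles, groups).p_value)
    return np.array(pvals)
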