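# fcdq

Quantitative analysis pipeline for a mouse model of focal cortical dysplasia
(FCD) type II — the malformation of cortical development that causes
drug-resistant focal epilepsy through mTOR-hyperactive, cytomegalic
("dysmorphic") neurons.

The package re-implements, as tested reusable library code, four
quantitative workflows used to characterize such lesions:

1. **Lesion topography** (`fcdq.topography`) — dorsal fluorescence lesion
   masks are registered onto a polygonal cortical-area map via a
   bregma/lambda landmark similarity transform; per-animal predictors are
   computed in map coordinates: lesion area *A* (mm²), frontal-edge
   position *x* (mm anterior of lambda), the lesion severity index
   LSI = √A + x, and per-area/per-domain coverage fractions.  Group
   overlap is summarized by a signed heatmap (+1/N<sub>s</sub> per seizing
   mask, −1/N<sub>ns</sub> per non-seizing mask), and seizure outcome is
   modeled by logistic regression
   p(x) = 1 / (1 + e^{−(β₀ + β₁·x)}), with a likelihood-ratio test,
   the 50% point −β₀/β₁, and in-sample accuracy at the p > 0.5 cutoff.
2. **3D cytoarchitecture** (`fcdq.cytoarch`) — neurons are counted in 3D
   from per-frame instance-segmentation masks of confocal/two-photon
   Z-stacks: per-frame centroids are accumulated on a 4×-coarser grid,
   thresholded at 4 frames of persistence, 8-connected objects give the
   count K, and k-means (k = K) refines positions.  Each neuron gets a
   moment-equivalent ellipse from its largest cross-section, an effective
   diameter √(major·minor), and a mean labeling intensity.  pS6-high
   (mTOR-hyperactive) cells are separated from baseline either by fitting
   a bi-Gaussian to the 256-bin intensity histogram (threshold = midpoint
   of the two centers) or by a background multiple (3× for pS6, 1.5× for
   GFP/NeuN), and reported as densities per mm³, fractions, and overlap
   with a reference channel.
3. **Bouton morphometry** (`fcdq.boutons`) — axon shaft caliber is the
   5th percentile of the traced diameter profile; boutons are peaks of
   the relative profile d(s)/d_shaft − 1 accepted at minimum height 0.2,
   prominence 0.1, separation 1 µm, with half-height widths and
   rotational-ellipsoid volumes V = (π/6)·d²·w; summaries report
   median (IQR) per group/side/layer.
4. **Laminar depth profiles** (`fcdq.depthprof`) — light-sheet cell
   detections are reduced to normalized depth distributions along an axis
   perpendicular to the cortical surface (convex hull facet nearest the
   lesion center of mass), binned at 0.01 mm in a 1-mm square column, and
   compared between groups via PCA of curve shapes with a Mann–Whitney
   test on PC1 scores.

Because no imaging data are publicly deposited for this study design,
`fcdq.synthio` generates every input kind with exact ground truth
(atlas, lesion cohorts matched to printed group medians/IQRs, spherical
two-population cell stacks, bouton-bearing diameter profiles, cortical
point clouds with prescribed depth densities), and `fcdq.validation`
scores the pipeline against that truth.

## Worked example

Run the all-synthetic pipeline (26 simulated animals drawn from the
seizing / non-seizing group statistics) and fit the seizure model:

```python
import pandas as pd
from fcdq import pipeio, topography as tp
from fcdq.cohortstats import mann_whitney_u, summarize

out = pipeio.run_pipeline(pipeio.RunConfig(out_dir="fcdq_out", seed=1))
df = pd.read_csv(out / "lesions.csv", comment="#")

model = tp.fit_seizure_logistic(df["frontal_edge_mm"], df["seizing"].astype(int))
print(model.summary())
```

```
Seizure logistic model
  n = 26
  beta0 = -15.9183
  beta1 = 2.3011 per mm
  LRT p = 0.0001473
  50% point = 6.918 mm
  in-sample accuracy = 84.6%
```

The slope β₁ ≈ 2.3 per mm means each millimeter of anterior lesion
displacement multiplies the seizure odds by e^2.3 ≈ 10; lesions whose
frontal edge passes ~6.9 mm anterior of lambda are more likely seizing
than not.  The group comparison behind it:

```python
s = df[df.seizing]["frontal_edge_mm"]; ns = df[~df.seizing]["frontal_edge_mm"]
r = mann_whitney_u(s, ns)
```

```
seizing   7.7 (7.1-8.1) mm n=12
non-seiz  6.3 (6.0-6.6) mm n=14
Mann-Whitney U=146 p=0.0016
```

A command-line interface mirrors the library
(`fcdq simulate|topography|cells|boutons|depth|compare|run`), e.g.

```bash
fcdq simulate --kind cohort --out masks --seed 3
fcdq topography --masks masks --atlas atlas.json --out lesions.csv --heatmap heat.tiff
fcdq compare --table lesions.csv --metric frontal_edge_mm --group seizing
```

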