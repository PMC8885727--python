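# synapse-corr

Correlative analysis of presynaptic **function** and nanoscale
**structure** at individual synapses.

Synapses vary enormously in how reliably they release neurotransmitter,
and a central question in synaptic physiology is whether that functional
diversity is written into the nanoscale organisation of the presynaptic
machinery — the voltage-gated calcium channels (e.g. Cav2.1) and active-zone
scaffolds (e.g. Bassoon) that sit in subsynaptic domains (SSDs) at the
release site. `synapse-corr` implements a complete, tested analysis chain
for experiments that measure both sides at the same boutons:

1. **Live dual-reporter imaging** — SypHy (pH-sensitive GFP on
   synaptophysin, unquenches on vesicle fusion; green, ΔG) fused to R-GECO
   (red calcium indicator; ΔR), imaged at 12.5 Hz per channel around an
   electrical stimulus.
2. **Two-colour 3D-dSTORM** of the same field after fixation — single-
   molecule localisation tables with per-camera intensities for spectral
   demixing, drift correction, Voronoi-density cluster segmentation and
   SSD colocalisation.
3. **Registration and statistics** — a landmark affine transform joins the
   two coordinate frames, responding boutons are matched one-to-one to
   their super-resolved clusters, and structure–function relations are
   tested with Spearman rank correlations and two-sample KS tests.

A fully seeded synthetic-data module generates every input with ground
truth (stimulus-locked bouton movies, two-camera emitter tables, clustered
3D point clouds, a known affine map, and a programmable structure→function
coupling), so the entire pipeline is testable without any microscope data.

## The measurements

Per bouton, on background-subtracted, 4-frame-smoothed ROI traces:

- baselines `G0`, `R0` = mean of the 15 pre-stimulus frames;
- peak changes `ΔG`, `ΔR` = max over the 15 frames from the stimulus;
- a bouton is a **calcium responder** when `ΔR > 3·SD(baseline)`, and
  analogously for detectable release on the green channel;
- normalised measures `ΔG/R = ΔG/R0`, `ΔR/R = ΔR/R0`, and the
  calcium-dependence of release `ΔG/ΔR`.

Per localisation table (one per colour), the structural chain is: photon
ratio `ρ = I_cam1/(I_cam1+I_cam2)` → two-component Gaussian-mixture
demixing with a 0.99 posterior rejection band → lateral drift correction
by phase cross-correlation of 2,000-frame bins → per-point first-rank
Voronoi density `δ_i` → keep points with `δ_i ≥ δ_d` (the global dataset
density), link within 200 nm (colour 1) / 100 nm (colour 2), accept
components with ≥ 200 / ≥ 20 molecules → convex-hull volume and density
per cluster → SSD-to-bouton association by point-in-hull overlap with a
distance-bounded orphan-assignment fallback.

## Worked example

Simulate a 20-synapse correlative experiment with positive coupling
between SSD content and release, then run the whole chain:

```python
import synapse_corr as sc
from synapse_corr.pipeline import run_correlative_pipeline

cfg = sc.PipelineConfig()
g, r, points, lm_src, lm_dst, truth = sc.simulate_correlative_dataset(
    cfg, n_synapses=20, coupling="positive", seed=4
)
res = run_correlative_pipeline(
    g, r, points, lm_src, lm_dst, truth.centres_px, cfg,
    bg_centre=truth.bg_centre,
)
```

Output of the run above:

```text
landmark RMSE: 7.37e-12 nm
responders: 20/20
matched synapses: 20
SSD count distribution: {1: 4, 2: 5, 3: 5, 4: 4, 5: 2}
Spearman dG/R vs SSD detections: r = 0.902, p = 5.60e-08 (n = 20)
KS dG/dR single vs multi SSD: D = 0.875, p = 0.015 (n = (4, 16))
```

The landmark fit is exact (noiseless landmarks), all 20 programmed
responders are detected and matched to their generating cluster, and the
programmed positive coupling between SSD detection count and the release
measure ΔG/R is recovered as a strong positive rank correlation.

The same stages are scriptable from a shell:

```bash
synapse-corr simulate --n-synapses 20 --seed 4 --out data/
synapse-corr traces --g data/g.tif --r data/r.tif --rois data/rois.csv --out responses.csv
synapse-corr register --landmarks data/landmarks.csv --out transform.yaml
```

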