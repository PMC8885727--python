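# Methods

This note documents the models and procedures implemented in
`synapse-corr`, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the design choices made where the
workflow left genuine freedom.

## Coordinate conventions

Physical coordinates are nanometres throughout; pixel indices are 0-based.
Where a pixel grid meets physical space the pixel-centre convention
`nm = (index + 0.5) · pixel_size` applies, so rendered images and
registered coordinates share an origin without half-pixel bias. Live
movies default to 433 nm pixels (4×4 camera binning) at 12.5 Hz per
channel; the dSTORM camera pixel is 97 nm and super-resolution renders
default to 10 nm pixels.

## Functional arm: trace analysis

Per bouton, the raw trace is the per-frame mean over a 5×5-pixel ROI; a
single 15×15-pixel background ROI per field (user-chosen, or by default
the darkest 15×15 region of the time-averaged image) is subtracted from
every bouton trace frame-wise. Traces are smoothed with a **trailing**
(causal) 4-frame moving average: a centred even-length window is
ill-defined, and a trailing window cannot leak post-stimulus signal into
the baseline. Partial windows at the trace start average what is
available.

Baselines `G0`, `R0` and the baseline s.d. come from the 15 frames ending
one frame before the stimulus; peak changes are the maximum of the
smoothed trace over the 15 frames starting at the stimulus frame
(inclusive), minus baseline. The responder rule is strict
(`ΔR > 3·SD`), so a perfectly flat trace (SD = 0, ΔR = 0) never
classifies as responding.

**Baseline s.d.: raw by default.** Smoothing correlates neighbouring
baseline samples, which biases the 15-sample s.d. estimate of the
smoothed trace about 20% low and roughly doubles the false-positive rate
of the 3-SD rule. The threshold therefore uses the s.d. of the raw
background-subtracted baseline by default; `baseline_sd_on_smoothed=True`
restores the alternative for sensitivity analyses.

Records with `R0 ≤ 0` are flagged invalid and excluded downstream with a
logged reason. `ΔG/ΔR` is reported only for calcium responders with
`ΔR > 0`; release failures keep their (small, noisy) `ΔG` but carry
`release_detected=False`.

## Structural arm: localisation processing

**Pairing.** Two-camera detections are merged by mutual nearest
neighbours on the same frame within one camera pixel (97 nm). Unpaired
records are dropped and counted.

**Spectral demixing.** The photon ratio `ρ = I_cam1/(I_cam1+I_cam2)` is
bimodal for a two-fluorophore sample (the camera-1-favouring dye near
0.75, the other near 0.30). A two-component 1D Gaussian mixture is fitted
to ρ; a record is assigned to a fluorophore only when its posterior
reaches 0.99, otherwise it is rejected — an explicit crosstalk bound
rather than a fixed ratio cut. A fit whose component means are closer
than **2× the pooled s.d.** raises a demixing-failure error: a unimodal
sample fitted with two components typically splits into means ~1.5 pooled
s.d. apart, while genuine two-fluorophore separations are ≥ 4σ.

**Drift.** Lateral drift is estimated by rendering 2,000-frame bins as
20 nm histograms and registering each against the first bin with
sub-pixel (10×) phase cross-correlation; bins with < 50 localisations are
skipped and interpolated over. Between bin centres the trajectory is
linear; beyond the first/last centre the end segments are **extrapolated
linearly** — holding the ends constant would leave an uncorrectable ramp
across the first and last half-bins (≈ 8 nm residual for a steady
100 nm/60 k-frame drift), whereas linear extension corrects a steady
drift up to a global constant offset. Because estimation is binned, the
recovered trajectory is assessed at bin centres against the ground-truth
bin-mean drift; within-bin motion is below the method's resolution. Only
x and y are corrected; z is untouched.

**Rendering** is a straight 2D count histogram (counts conserved
exactly), image convention `image[row=y, col=x]`, origin at the minimum
corner, recorded in the TIFF description.

## Cluster segmentation

Per colour, each point's density is its **first-rank Voronoi density**:
the inverse volume of its 3D Voronoi cell, averaged over the point and
its Delaunay neighbours with bounded cells. Cells that are unbounded or
reach beyond the convex hull of the data are boundary artefacts — they
get zero raw density, are excluded from dataset statistics, and receive
their neighbourhood average instead. (The raw inverse cell volume is
available via `first_rank_average=False`; the neighbourhood average is
the default because the ~7% of cluster points forming the convex shell
would otherwise carry zero density and be unconditionally discarded.)

The segmentation threshold compares `δ_i` against `δ_d`, the **global
dataset density** — point count divided by the volume of the data's
convex hull. Cluster points sit orders of magnitude above this average
and diffuse background below it. (The arithmetic mean of per-point
densities, dominated by cluster cores, is reported separately as
`mean_cell_density` but is not a useful threshold: using it would discard
the outer ~two-thirds of every cluster.)

Kept points are linked within 200 nm (colour 1) / 100 nm (colour 2);
connected components with ≥ 200 / ≥ 20 molecules become clusters. Cluster
volume is the 3D convex hull of the member points (deterministic; an
alpha-shape would be tighter but parameter-dependent) and density is
`n/volume`; fewer than four non-coplanar points marks a cluster
degenerate with undefined volume. Both choices — hull volume and `n/hull`
density — are the simplest deterministic readings of "cluster volume and
density of molecules"; a Voronoi-mean density variant can be derived from
the density map if needed.

**Colocalisation.** An SSD (colour-2 cluster) belongs to a synapse when
any of its points lies inside the colour-1 cluster's hull (provenance
`overlap`). SSDs that overlap nothing are attached to the nearest
colour-1 centroid within 500 nm (provenance `orphan-assigned`) — a
deterministic, recorded stand-in for the manual curation interactive
workflows apply to missed colocalisations, motivated by SSDs sitting at
the vesicle-cloud periphery. More distant SSDs are reported unassigned.
Synapses with zero SSDs are kept; the statistics stage excludes them.

## Registration, matching, statistics

Registration is 2D (live image plane vs rendered dSTORM plane; dSTORM z
is used only for clustering). The affine map `x ↦ Ax + t` is fitted to
≥ 3 non-collinear landmark pairs by least squares; the reported RMSE is
per-coordinate (√ of the mean squared residual over all 2n components).

Matching maps each calcium-responder ROI centre through the transform and
greedily assigns it, in order of increasing distance, to the nearest
unclaimed colour-1 centroid within 500 nm. A bouton whose second-best
candidate lies within 10% of the best distance is excluded and logged —
a deterministic replacement for manual "well-aligned synapses only"
curation.

`spearman` uses mid-ranks and the Pearson correlation of ranks; the
two-sided p-value is an exact enumeration over all n! permutations for
n ≤ 10 and the t-approximation (n−2 df) above. `ks_two_sample` computes
the sup-ECDF difference over pooled breakpoints with the asymptotic
Kolmogorov p-value. The report runs the standard comparison plan
(ΔG/R vs ΔR/R overall and within single-/multi-SSD groups; KS of ΔG/ΔR
between those groups; KS of SSD detections and mean SSD density between
releasing and non-releasing synapses; SSD-count distribution;
structure–function rank correlations), skips any group below 3 with a
logged reason, and applies no multiple-testing correction (p-values are
per-comparison, noted in the report footer).

## Synthetic data: what it emulates, and what it does not

`simulate_functional_movie` places Gaussian bouton spots (σ = 1.5 px) on
programmed baselines (green 10, red 100 a.u.); at the stimulus both
channels step by the programmed amplitude, hold a plateau at least as
long as the smoothing window, then decay exponentially (τ = 40 frames
green, 8 red). The spot profile is normalised so its 5×5-ROI mean is 1
and the frame keeps a strictly dark band for the background ROI, so in
the noiseless case the extracted trace equals the programmed time course
*exactly* — the basis of the exact-recovery checks. Pixel noise is i.i.d.
Gaussian. Not modelled: photon shot noise, bleaching, focus drift,
overlapping boutons, multi-stimulus protocols.

`simulate_two_camera_emitters` draws total photons lognormal (mean =
budget, σ_log = 0.5, a typical SMLM photon-count spread) and ratios
truncated-normal in [0, 1] (defaults 0.75/0.30, σ = 0.05, mimicking the
bimodal ratio histogram); it does not model physical emission spectra or
blinking kinetics.

`simulate_synapse_scene` builds, per synapse, a diffuse colour-1 cloud
(lateral σ 150 nm; axial σ 100 nm, respecting the ~1 µm usable z range of
astigmatic 3D detection) and 1–6 compact colour-2 SSDs (σ 40 nm) on the
periphery, over uniform Poisson background (default 2 points/µm³). SSDs
sit at evenly spaced, jittered angles on a ring whose radius grows with
the SSD count (150 nm base, `(3.5σ+60)/sin(π/k)` nm for k domains) so
that adjacent domains remain separated by more than the 100 nm linkage —
the geometric counterpart of multi-SSD synapses having larger clusters.
Repeat localisations of one molecule (blinking) are not modelled;
"detections" and "molecules" coincide here.

`simulate_correlative_dataset` lays out boutons in live pixel space, maps
them through a random invertible affine (scale ≈ the 433 nm live pixel,
≤ 3° rotation, ≤ 2% shear) into nm space for the point-cloud scene, emits
≥ 4 exact landmark pairs, and programs the coupling: under `positive`,
ΔG = coeff · (total SSD points) · exp(N(0, σ_log)); under `null`, ΔG is
drawn independently. Consequently, passing tests demonstrate the
pipeline's correctness on data satisfying its assumptions — well-isolated
boutons, Gaussian clusters, exact landmarks — not robustness to the full
messiness of real preparations.

## Problem sizes and numerical tolerances

The shipped checks use: 20 noiseless boutons (exactness, 1e-9 relative),
500 boutons at peak = 5× trace-noise s.d. (sensitivity ≥ 0.95, false
positives ≤ 0.05, pre-verified by a trace-level Monte-Carlo oracle),
20,000 emitters (misclassification < 0.1%, rejection < 2%), 30,000
localisations over 6,000 frames with 100 nm linear drift (endpoint within
10 nm, post-correction residual ≤ 2 nm — one sub-pixel quantum at
20 nm/10× upsampling), 15-synapse default scenes (SSD-count recovery
≥ 90%), a 20-synapse end-to-end dataset (matching ≥ 95%), a 100-synapse
positive-coupling run (r > 0, p < 0.05), and 200 null-coupling replicates
(type-I rate in [0.02, 0.09]). The type-I replicates run the functional
arm end to end (movies → traces → responder classification) and pair the
measured ΔG/R with the null-coupled ground-truth SSD counts: under the
null, independence survives any deterministic structural measurement, so
this design tests exactly the p-value calibration that matters while
keeping 200 replicates cheap; the structural arm's own fidelity is
covered by the dedicated clustering and matching checks.

## Known limitations

- Only TIFF stacks and CSV tables are read; vendor binary formats are out
  of scope, as is the astigmatic PSF fitting that produces localisation
  tables.
- Drift correction is lateral only and relative to the first usable bin.
- The convex-hull volume overestimates concave clusters; the coverage
  volume behind `δ_d` likewise uses the data's convex hull and can
  understate the density of data filling a non-convex region.
- Exact Spearman p-values stop at n = 10 (3.6M permutations); larger
  samples use the t-approximation.
- No multiple-testing correction is applied in the report.
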