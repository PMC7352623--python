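# Methods

This note records the models implemented in `tumorhab`, the defaults of the
synthetic-data generators, the numerical choices that matter, and what the
test suite does and does not establish about real data.

## Quantitative MRI models

**Diffusion.** DW-MRI signal follows the monoexponential model
S(b) = S0·exp(−ADC·b) with b ∈ {150, 500, 800} s/mm². ADC is fitted by
closed-form least squares on log-signal. Tumor voxels whose signal does not
decrease strictly monotonically across the three b-values
(S(800) < S(500) < S(150)) are removed before fitting; a slice is excluded
when strictly more than 20% of its tumor voxels were removed, and a scan is
discarded when strictly more than half of its slices were excluded. Both
inequalities are strict, matching the "greater than" convention of the
protocol they implement.

**T1.** Magnitude inversion-recovery snapshot model
S(TI) = |S0·(1 − 2e^(−TI/T1) + e^(−TR/T1))| with seven TIs (250–10,000 ms)
and TR = 12 s. For fixed T1 the amplitude is profiled out in closed form, so
the fit is a 1-D search over a dense logarithmic T1 grid (a dense variant of
multi-start initialisation) with two rounds of local grid refinement;
noiseless recovery is exact to better than 10⁻⁴ relative. T1 maps are
exposed for users who add a signal→concentration conversion; T1 is not a
clustering feature and the DCE pipeline operates on concentration curves
directly (the conversion itself is out of scope).

**Kety–Tofts.** Tissue contrast concentration is
Ct(t) = Ktrans·∫₀ᵗ Cp(u)·exp(−(Ktrans/ve)(t−u)) du, with kep = Ktrans/ve.
The arterial input function Cp is a population curve: zero before bolus
arrival, a 5 s linear rise, then a bi-exponential decay
a₁e^(−m₁τ) + a₂e^(−m₂τ) with defaults a₁ = 4.2 mM, m₁ = 2.0 min⁻¹,
a₂ = 1.6 mM, m₂ = 0.07 min⁻¹ — a fast-clearing murine bolus of a
low-molecular-weight gadolinium agent; all constants are configurable
because no published functional form is assumed. Before fitting, the AIF is
(1) scaled so that reference skeletal-muscle kinetics
(Ktrans = 0.1 min⁻¹, ve = 0.1, configurable) reproduce the measured muscle
curve — the model is linear in Cp, so the scale is a closed-form
inner-product ratio, clamped to [0.1, 10] with a warning — and (2) shifted
per voxel to the bolus-arrival time estimated by a half-logistic
enhancement fit, f(t) = A·(1−e^(−r(t−t₀)))/(1+e^(−r(t−t₀))) for t ≥ t₀,
with amplitude profiled out and (t₀, r) scanned over the frame grid and a
small rate grid. Curves without detectable enhancement (below 3× a robust
first-difference noise estimate) carry a no-arrival flag.

Fitted parameters are bounded to the physiological ranges Ktrans ∈ [0, 5]
min⁻¹ and ve ∈ (0, 1]; kep values outside the open interval (0, 5) min⁻¹
are removed. A voxel enters habitat clustering only when all four of
Ktrans, ve, kep, ADC are valid.

### Numerical evaluation of the convolution

The convolution is computed by the exact exponential-kernel recursion for
piecewise-linear Cp on an internally supersampled grid (16 sub-steps per
12.8 s frame), then sampled at the frames. A plain trapezoid recursion at
the 12.8 s frame spacing is biased by a few tenths of a percent near the
bolus peak; the supersampled recursion matches a 0.05 s brute-force
quadrature to well under 0.5% of peak, which the suite asserts.

### Solvers

`fit_kety_tofts` fits one curve by bounded trust-region least squares with
three Ktrans multi-starts (0.01/0.1/1 min⁻¹, ve start 0.3; ties broken by
residual then by smaller Ktrans). Whole maps use `fit_kety_tofts_map`, a
vectorised solver for the same objective: Ktrans is linear in the model at
fixed kep, so each voxel reduces to a 1-D profile over a shared 600-point
logarithmic kep grid, refined parabolically in log-kep; voxels pushed past
ve = 1 are refit on the ve = 1 boundary (one-parameter model with
kep = Ktrans). The two routes agree to fitting tolerance on noisy curves
(asserted in the suite), and the noiseless map round trip is exact to
better than 10⁻³ relative.

Identifiability: voxels with very small kep (slow washout relative to the
20 min acquisition) have a flat likelihood ridge toward kep → 0, ve → 1; at
realistic noise some low-Ktrans voxels are therefore returned on the ve = 1
boundary. This is a property of the model and acquisition, not of the
solver, and it leaves habitat assignment intact (such voxels remain far
from the other habitats in feature space).

## Habitat discovery

Valid voxel vectors (Ktrans, ve, kep, ADC) are pooled across tumors and
timepoints, z-scored per feature over the pooled cohort, and clustered by
agglomerative Ward linkage under Euclidean distance
(`scipy.cluster.hierarchy`). The number of clusters is selected by the
Tibshirani gap statistic: Gap(k) = E*[log Wₖ] − log Wₖ with Wₖ the pooled
within-cluster sum of squared distances to centroids and the reference
expectation over B uniform draws on the per-feature bounding box. The
default selection is the one-standard-error rule (smallest k with
Gap(k) ≥ Gap(k+1) − s(k+1), falling back to the argmax when it never
fires); the plain argmax is also reported, and both the gap curve and the
dendrogram are exposed so users can inspect branch heights alongside the
gap, as the underlying analysis procedure prescribes.

Cohorts larger than 50,000 rows are clustered on a seeded subsample with
nearest-centroid completion. Independently, when a `gap_subsample` is set,
the gap statistic itself is computed on a seeded subsample (the linkage
used for the final cut still covers all rows); model selection on a
subsample is standard practice for hierarchical methods whose linkage is
quadratic in n.

Clusters become physiological habitats through fixed thresholds on their
centroids in original units: high-vascularity iff mean Ktrans > 0.1 min⁻¹
OR mean kep > 0.5 min⁻¹; high-cellularity iff mean ADC < 10⁻³ mm²/s OR
mean ve < 0.3, except that when the ADC and ve indicators disagree, ve
decides — a low-ADC core with near-unity ve is necrotic, not cell-dense
(this is exactly the triple-negative cohort case, where all three clusters
sit below the ADC threshold and ve separates the necrotic core). Boundary
equality labels the low side. All four label combinations are
representable, so the labeller is total even though HV-LC does not arise
under the defaults. Distinct clusters may share a physiological label;
composition and validation aggregate them, so discovering finer clusters
than habitats does not distort habitat-level results.

## Spatial analysis

The multiregional spatial interaction (MSI) matrix tallies habitat labels
over adjacent voxel pairs — by default 8-neighbour within slice, because
slices (1 mm) are much thicker than the in-plane spacing (0.4375 mm); a
6-connected 3-D option exists. Every unordered labeled pair increments its
cell (cross-label pairs split ½/½ across the symmetric pair), normalized by
the total pair count, so the matrix is symmetric, non-negative, and sums to
one. The scalar summary is the trace — the fraction of same-label
adjacencies — and significance of spatial colocalization comes from a
one-sided permutation test over labelings of the labeled positions, with
add-one smoothing: p = (1 + #{permuted ≥ observed})/(n_perm + 1), default
n_perm = 1000 (at least 100).

## Composition and statistics

Habitat composition is the percent of assigned voxels (or section pixels)
per habitat; voxels removed by quality filters leave the denominator, so
percents always sum to 100. Tumors strictly larger than 500 mm³ at baseline
are excluded from treatment-response analysis; tumors lacking a baseline
record are retained but flagged. Within-group changes from baseline and
two-group contrasts use the two-sided Wilcoxon rank-sum test (exact null
for arm sizes ≤ 10 without ties, normal approximation otherwise — and a
paired signed-rank alternative is a documented option for paired designs,
though the unpaired test is the default to match the procedure being
reimplemented); three or more groups use one-way ANOVA with Tukey's HSD.
No multiplicity correction is applied across habitats or timepoints, by
design of the reimplemented analysis. Error bands, where computed, use
t-quantiles. Null calibration (type-I error 0.05 ± 0.02 over 500 simulated
null cohorts for both test paths) and power (≥ 80% for a 20-percentage-
point LV-HC shift at n = 10/arm, SD 8 pp) are asserted in the suite.

## Histology pipeline

H&E sections are segmented by seeded k-means (k = 4) in RGB space, with
clusters assigned to nuclei / viable eosin tissue / pale necrosis /
background by nearest reference stain colour. CD31 and Ki-67 images are
thresholded by Otsu's method on a 256-bin histogram (positives bright, as
in an optical-density or deconvolved-stain channel). Tissue masks remove
low-saturation (gray/white) background with morphological cleanup and an
optional ROI intersection. Stains from adjacent sections are aligned by
rigid registration: a 1° rotation grid (refined to 0.1°) with FFT
cross-correlation translation at each angle, scored by Dice overlap, with a
warning below 0.5.

Density maps assign each pixel the number of 8-connected stain-positive
components intersecting the 150 µm × 150 µm window centred on it (counts:
nuclei, Ki-67+, vessels) or the percent positive area in that window
(necrosis), windows truncated at borders with area renormalization.
Components intersecting — not contained in — the window are counted, so
large vessels are never missed. Two exact implementations exist: a dense
map (per-component box dilation; integral images for percent-area) and a
sparse evaluator at selected centres; nearest-neighbour downsampling of the
dense map equals sparse evaluation at the sampled pixels (asserted), which
is what the pipeline uses on large sections. The downsampling factor is
per-axis (default 0.01; 0.1 available by configuration). Histological
habitats reuse the pooling/scaling/clustering machinery on
(nuclei, necrosis, Ki-67, vessels) pixel vectors; cluster means label
habitats HV iff vessels/unit > 3 and HC iff nuclei/unit > 100 (strict).
Tumors missing any of the three stains are excluded with a log entry.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
under which every downstream claim is checked.

**Geometry.** Tumors are ellipsoids on the acquisition grid (0.4375 ×
0.4375 × 1 mm voxels from the 28 mm / 64-matrix protocol), ~275 mm³ by
default, partitioned into three contiguous habitats. The default "rim"
morphology places HV-HC as the outer shell, LV-HC as the intermediate
shell, and LV-LC as the core — the enhancing-rim / necrotic-core
arrangement; a smooth angular wobble (8%) keeps shells non-spherical.
Realized fractions are exact to voxel rounding. A "blobs" morphology grows
habitats from random seeds under volume budgets.

**Parameter fields.** Per-habitat truncated-normal draws with means from
the published habitat-wise cluster means of the HER2+ (default) and
triple-negative tables. The spreads are free parameters (no inter-voxel
variances are published); they were calibrated once so that the pooled,
z-scored voxel distribution reproduces the structure those cohorts report —
three separated, gap-statistic-selectable habitats — while remaining
overlapping: within-habitat coefficients of variation near 6–8% before
measurement noise, which adds comparable dispersion to the fitted maps.
Within a habitat, Ktrans and ve draws are correlated (ρ = 0.7): both track
local tissue viability and stromal access, and the correlation keeps the
derived kep = Ktrans/ve dispersion physiological rather than
ratio-inflated. Default T1 means 1.9–2.2 s (7T-typical) exercise the IR fit
only.

**Signals.** Forward models above, plus additive Gaussian noise on
magnitude signals (Rician effects are negligible at the simulated SNR):
DWI σ = 15 at S0 = 1000 (1.5%), DCE σ = 0.01 mM (~3% of a typical peak
tissue concentration), muscle-curve σ = 0.002 mM.

**Histology.** Stain objects are compact seeds (nuclei/Ki-67 radius 1.5 µm,
vessels 4 µm) placed by per-habitat point processes whose intensity matches
the published counts per 150 µm unit: nuclei and Ki-67 as Matérn-II
hard-core processes (hard core 4 µm, proposal intensity solved from the
thinning identity so the *retained* intensity hits the target — a plain
Poisson process at realistic nuclear density would merge under
connected-component counting and undercount); vessels on a jittered grid
(spacing 1/√intensity, ±35% jitter), reflecting the Krogh-type regularity
of capillary spacing set by oxygen diffusion distance. Necrosis is a
thresholded Gaussian random field with ~8 µm correlation length — fine
eosinophilic speckle — thresholded per habitat at the quantile giving the
target percent area, so a 150 µm window averages many patches. Renderings
(H&E RGB, bright-positive CD31/Ki-67 channels) use a fixed palette and
exercise the segmentation operators.

**Cohorts.** Baseline habitat mixtures are Dirichlet draws (α₀ = 35) around
(36, 37, 27)% for (HV-HC, LV-HC, LV-LC); volumes log-normal around 275 mm³
(σ = 0.3). Treated groups shift composition LV-HC → HV-HC by −5 pp at the
first post-treatment imaging and −20 pp at the endpoint (the response
direction of the reimplemented study); controls are exchangeable with
treated at baseline by construction. Endpoint histology shares the central
geometry slice with the MRI truth, which is what couples the modalities.
Cohort sections default to 2 µm pixels (the stand-alone section simulator
defaults to 0.5 µm, a native 20× scan): the density targets are per-window
and resolution-free, and 2 µm keeps object placement tractable at cohort
scale while preserving disjoint objects under the hard-core distances.

**Reduced repeated-cohort paths.** Experiments repeated hundreds of times
(null calibration, power, the 100-cohort MRI↔histology correlation check)
use reduced generator paths: ground-truth parameter fields stand in for
fitted maps, and per-pixel stain-density draws (Poisson window counts
around the habitat's table density, sharing the habitat geometry slice)
stand in for full section rendering. The full signal→fit→discover→label
path is exercised once per suite run in the end-to-end check, and the full
section→density→cluster path in the histology cluster-number check.

## Problem sizes

Default analyses run at desk scale: cohorts of 6–20 tumors on 36³-ish
grids (~1,000–1,500 tumor voxels each, the realistic count for a 275 mm³
tumor at this resolution), 5,000 pooled voxels/pixels with B = 20 gap
references for cluster-number selection, 1,000 permutations for MSI tests,
and 100–500 replicates for calibration experiments.

## What passing tests show — and do not show

The suite establishes internal correctness: exact recovery on noiseless
phantoms, agreement with independent brute-force oracles (fine-grid
convolution, dense grid searches, exhaustive Ward enumeration at n = 6,
edge enumeration for MSI, exact rank-sum enumeration), calibrated error
rates, and faithful implementation of the filtering and labelling rules.
It does not establish that real tumors have three habitats, that the
printed thresholds are optimal, or that the synthetic noise model captures
scanner artifacts (motion, B0/B1 inhomogeneity, partial volume), none of
which are simulated.

## Known limitations

* **Gap statistic on count-valued features.** For stain-density vectors,
  the per-window Poisson/discreteness noise floor of the low-count features
  (vessels ≈ 5.5/unit, Ki-67 ≈ 31/unit) is irreducible relative to their
  between-habitat contrast. In that regime the pooled within-cluster
  dispersion keeps falling faster than the uniform-reference dispersion
  beyond the true k, so gap-based selection (either rule, any reference,
  including the reference R implementation of the gap statistic) tends to
  certify finer splits of the physiological habitats — typically k = 3 or
  4 depending on the draw — even though the extra clusters are pure
  sub-clusters that the physiological labelling step merges back into the
  same three habitats. Habitat-level results (labels, composition,
  correlation) are insensitive to this; the selected k itself is not a
  stable statistic for such data. The dendrogram and full gap curve are
  reported so the branch-height criterion can be weighed alongside the gap,
  as the original procedure intends.
* kep identifiability degrades as kep → 0 relative to the acquisition
  length (ve = 1 boundary solutions); flagged but not resolved.
* The MSI construction (connectivity, normalization) follows this
  package's stated contract; alternative adjacency conventions are
  configurable.
* Central-slice matching to histology is an automated max-area surrogate
  with a manual override; true section matching is visual and manual.
* No spatial MRI↔histology registration is attempted (composition-level
  validation only), and no motion/field-inhomogeneity correction is
  modelled.
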