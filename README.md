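# tumorhab

Physiological **tumor habitat imaging** from quantitative MRI and histology,
for preclinical (xenograft) breast-cancer studies.

Solid tumors are not well-mixed: perfusion and cellularity vary regionally,
producing physiologically distinct subregions — *habitats* — such as an
enhancing, cell-dense rim and a poorly perfused necrotic core. `tumorhab`
reimplements a complete habitat-imaging analysis as a tested, reusable
pipeline:

1. **Quantitative map fitting.** Voxel-wise ADC from DW-MRI
   (S(b) = S₀e^(−ADC·b), with strict monotonic-decay, slice, and scan
   quality filters), T1 from magnitude inversion recovery
   (S(TI) = |S₀(1 − 2e^(−TI/T1) + e^(−TR/T1))|), and Ktrans/vₑ from DCE-MRI
   concentration curves via the standard Kety–Tofts model
   Ct(t) = Ktrans·∫₀ᵗ Cp(u)e^(−(Ktrans/vₑ)(t−u))du, with a population AIF
   calibrated to skeletal muscle and shifted per voxel to the fitted
   half-logistic bolus-arrival time; kₑₚ = Ktrans/vₑ with physiological-range
   validity (Ktrans ∈ [0,5] min⁻¹, vₑ ∈ [0,1], 0 < kₑₚ < 5 min⁻¹).
2. **Habitat discovery.** Valid voxel vectors (Ktrans, vₑ, kₑₚ, ADC) pooled
   across tumors and timepoints, z-scored, clustered by Ward/Euclidean
   agglomerative linkage with gap-statistic cluster-number selection, and
   labelled high/low **v**ascularity × **c**ellularity by fixed thresholds
   (HV iff Ktrans > 0.1 min⁻¹ or kₑₚ > 0.5 min⁻¹; HC iff ADC < 10⁻³ mm²/s or
   vₑ < 0.3, vₑ deciding when the two disagree).
3. **Spatial and longitudinal analysis.** Multiregional spatial interaction
   (MSI) matrices with a label-permutation colocalization test; percent
   tumor volume per habitat over time; Wilcoxon rank-sum and ANOVA+Tukey
   group comparisons with baseline exclusion of tumors > 500 mm³.
4. **Histology validation.** Stained-section segmentation (k-means H&E,
   Otsu CD31/Ki-67), rigid co-registration, 150 µm × 150 µm neighbourhood
   stain-density maps, histological habitat discovery with the same
   clustering machinery (HV iff vessels/unit > 3, HC iff nuclei/unit > 100),
   and per-habitat Pearson correlation of central-slice MRI composition
   against section composition.
5. **Synthetic data.** A first-class generator producing coupled
   multiparametric MRI and histology with known ground truth — contiguous
   rim/shell/core habitat geometries, per-habitat parameter distributions,
   forward-simulated signal series, hard-core/jittered-grid stain point
   processes, and longitudinal treatment effects — so the entire pipeline
   is testable without any animal data.

The clustering core is a scikit-learn estimator (`HabitatClusterer`, with
`fit`/`predict` and fitted attributes), so it composes with sklearn
pipelines and model selection.

## Worked example

```python
import numpy as np
from tumorhab.kinetics import AIFModel
from tumorhab.qmri import fit_parameter_maps
from tumorhab.synth import AcquisitionGrid, generate_cohort
from tumorhab.habitats import discover_mri_habitats
from tumorhab.composition import percent_tumor_volume
from tumorhab.spatial import msi_permutation_test

grid = AcquisitionGrid()
cohort = generate_cohort(n_per_group=3, days=(0, 4), shape=(36, 36, 12),
                         volume_mean_mm3=200.0, include_histology=False, seed=7)
aif = AIFModel(arrival_s=grid.precontrast_s)
param_sets = []
for tumor in cohort.tumors:
    for day, scan in tumor.scans.items():
        param_sets.append(fit_parameter_maps(
            scan.dwi, scan.dce, scan.roi, scan.muscle_curve, aif,
            t_s=grid.dce_times_s,
            provenance={"tumor": tumor.tumor_id, "timepoint": day}))

model, maps = discover_mri_habitats(param_sets, n_refs=20, random_state=8)
print(f"selected k = {model.k}")
for lab, c in zip(model.habitat_labels, model.centroids):
    print(f"  {lab}: Ktrans={c[0]:.3f}/min  ve={c[1]:.2f}  "
          f"kep={c[2]:.2f}/min  ADC={c[3]:.2e} mm^2/s")
names = {i + 1: lab for i, lab in enumerate(model.habitat_labels)}
for tid in ("control-00", "treated-00"):
    for day in (0, 4):
        pct = percent_tumor_volume(maps[(tid, day)], habitat_names=names)
        print(tid, "day", day,
              "  ".join(f"{k} {v:5.1f}%" for k, v in sorted(pct.items())))
p, trace, _ = msi_permutation_test(maps[("treated-00", 4)], seed=9)
print(f"MSI trace = {trace:.3f}, permutation p = {p:.4g}")
```

prints

```
selected k = 7
  LV-LC: Ktrans=0.034/min  ve=0.99  kep=0.03/min  ADC=1.30e-03 mm^2/s
  LV-LC: Ktrans=0.035/min  ve=0.99  kep=0.04/min  ADC=1.16e-03 mm^2/s
  LV-HC: Ktrans=0.048/min  ve=0.18  kep=0.27/min  ADC=5.42e-04 mm^2/s
  LV-HC: Ktrans=0.050/min  ve=0.18  kep=0.28/min  ADC=6.47e-04 mm^2/s
  HV-HC: Ktrans=0.196/min  ve=0.27  kep=0.74/min  ADC=6.77e-04 mm^2/s
  HV-HC: Ktrans=0.176/min  ve=0.28  kep=0.64/min  ADC=7.59e-04 mm^2/s
  HV-HC: Ktrans=0.170/min  ve=0.27  kep=0.63/min  ADC=6.57e-04 mm^2/s
control-00 day 0: HV-HC  45.3%  LV-HC  32.9%  LV-LC  21.8%
control-00 day 4: HV-HC  45.3%  LV-HC  33.0%  LV-LC  21.7%
treated-00 day 0: HV-HC  31.9%  LV-HC  53.2%  LV-LC  15.0%
treated-00 day 4: HV-HC  49.7%  LV-HC  33.1%  LV-LC  17.2%
MSI trace = 0.387, permutation p = 0.000999
```

Reading this: on fitted (noisy) maps the gap statistic certified seven
clusters, but every cluster is a pure sub-cluster of one physiological
habitat, and the threshold labelling merges them into the three habitats —
high-vascularity high-cellularity (HV-HC) rim, low-vascularity
high-cellularity (LV-HC) shell, and low-vascularity low-cellularity (LV-LC)
core. The treated tumor shows the simulated response (LV-HC falling from
53% to 33% of tumor volume with a matching HV-HC rise by day 4) while the
control is stable, and the permutation test confirms the habitat map is far
more spatially coherent than a random relabelling (p = 1/1001, the smallest
attainable value at 1000 permutations).

A command-line interface runs the pipeline end to end into a reproducible
run directory (NIfTI maps, TIFF sections, CSV tables, JSON models, manifest
with seeds and checksums):

```bash
tumorhab init-config --out config.yaml
tumorhab all --config config.yaml --out runs/demo --seed 0
```

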