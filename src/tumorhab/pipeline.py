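"""End-to-end pipeline binding the analysis stages.

``run_pipeline`` executes simulate -> fit -> discover -> spatial ->
composition -> histology -> validate on a synthetic cohort, writing each
stage's outputs (NIfTI volumes, TIFF sections, CSV tables, JSON models)
into one run directory together with a manifest of seeds, stage timings,
and per-file checksums.  A stage failure keeps earlier outputs on disk and
re-raises, so a CLI wrapper exits non-zero.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, defaults
from .composition import (compare_between_groups, composition_table,
                          exclude_large_tumors, percent_tumor_volume)
from .config import RunConfig
from .habitats import discover_mri_habitats
from .histology import discover_histology_habitats, stack_from_masks
from .io import file_sha256, save_json, save_nifti, save_tiff
from .kinetics import AIFModel
from .qmri import fit_parameter_maps
from .spatial import msi_matrix, msi_permutation_test, msi_statistic
from .synth import AcquisitionGrid, generate_cohort
from .validation import correlate_habitats, select_central_slice

__all__ = ["run_pipeline"]


def _grid_from_config(cfg: RunConfig) -> AcquisitionGrid:
    return AcquisitionGrid(
        b_values=tuple(cfg.b_values),
        inversion_times_ms=tuple(cfg.inversion_times_ms),
        tr_ms=cfg.ir_tr_ms, dce_dt_s=cfg.dce_dt_s,
        dce_duration_s=cfg.dce_duration_s, precontrast_s=cfg.precontrast_s)


def run_pipeline(config: RunConfig, outdir, stages=None) -> dict:
    """Run the pipeline; returns the manifest dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": [],
                "files": {}}
    state: dict = {"config": config}
    order = ["simulate", "fit", "discover", "spatial", "composition",
             "histology", "validate"]
    stages = order if stages is None else [s for s in order if s in stages]
    config.to_yaml(outdir / "config.yaml")
    try:
        for name in stages:
            t0 = time.perf_counter()
            _STAGES[name](state, outdir)
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)})
    finally:
        for f in sorted(outdir.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][str(f.relative_to(outdir))] = file_sha256(f)
        save_json(outdir / "manifest.json", manifest)
    return manifest


def _stage_simulate(state, outdir):
    cfg: RunConfig = state["config"]
    cohort = generate_cohort(
        n_per_group=cfg.n_per_group, groups=tuple(cfg.groups),
        days=tuple(cfg.days), grid=_grid_from_config(cfg),
        shape=tuple(cfg.shape), volume_mean_mm3=cfg.volume_mean_mm3,
        histology_pixel_um=cfg.histology_pixel_um, seed=cfg.seed)
    state["cohort"] = cohort
    d = outdir / "simulate"
    d.mkdir(exist_ok=True)
    for tumor in cohort.tumors:
        for day, scan in tumor.scans.items():
            stem = f"{tumor.tumor_id}_day{day}"
            save_nifti(d / f"{stem}_dwi.nii", scan.dwi, scan.geometry.voxel_size_mm)
            save_nifti(d / f"{stem}_dce.nii", scan.dce, scan.geometry.voxel_size_mm)
            save_nifti(d / f"{stem}_labels.nii",
                       scan.geometry.label_volume.astype(np.int16),
                       scan.geometry.voxel_size_mm)
        if tumor.histology is not None:
            save_tiff(d / f"{tumor.tumor_id}_hne.tiff", tumor.histology.hne_rgb)
    truth_rows = [
        {"tumor": t.tumor_id, "group": t.group, "day": day,
         "volume_mm3": t.volume_mm3,
         **{f"frac_{n}": f for n, f in zip(s.geometry.habitat_names, s.fractions)}}
        for t in cohort.tumors for day, s in t.scans.items()]
    pd.DataFrame(truth_rows).to_csv(d / "truth.csv", index=False)


def _stage_fit(state, outdir):
    cfg: RunConfig = state["config"]
    cohort = state["cohort"]
    grid = cohort.grid
    aif = AIFModel(arrival_s=grid.precontrast_s)
    d = outdir / "fit"
    d.mkdir(exist_ok=True)
    param_sets = []
    for tumor in cohort.tumors:
        for day, scan in tumor.scans.items():
            ps = fit_parameter_maps(
                scan.dwi, scan.dce, scan.roi, scan.muscle_curve, aif,
                b_values=grid.b_values, t_s=grid.dce_times_s,
                provenance={"tumor": tumor.tumor_id, "timepoint": day,
                            "group": tumor.group,
                            "volume_mm3": tumor.volume_mm3})
            param_sets.append(ps)
            for p, m in ps.maps.items():
                save_nifti(d / f"{tumor.tumor_id}_day{day}_{p}.nii", m,
                           scan.geometry.voxel_size_mm)
    state["param_sets"] = param_sets


def _stage_discover(state, outdir):
    cfg: RunConfig = state["config"]
    model, volumes = discover_mri_habitats(
        state["param_sets"], k_range=tuple(cfg.k_range),
        n_refs=cfg.gap_n_refs, selection=cfg.gap_selection,
        random_state=cfg.seed + 1)
    state["habitat_model"] = model
    state["habitat_maps"] = volumes
    d = outdir / "discover"
    d.mkdir(exist_ok=True)
    save_json(d / "habitat_model.json", model.to_dict())
    for (tumor, day), vol in volumes.items():
        save_nifti(d / f"{tumor}_day{day}_habitats.nii", vol.astype(np.int16))


def _stage_spatial(state, outdir):
    cfg: RunConfig = state["config"]
    results = {}
    for i, ((tumor, day), vol) in enumerate(state["habitat_maps"].items()):
        msi = msi_matrix(vol)
        p, trace, _ = msi_permutation_test(vol, n_perm=cfg.msi_n_perm,
                                           seed=cfg.seed + 100 + i)
        results[f"{tumor}_day{day}"] = {
            "matrix": msi.matrix.tolist(), "trace": trace, "p": p}
    d = outdir / "spatial"
    d.mkdir(exist_ok=True)
    save_json(d / "msi.json", results)
    state["msi"] = results


def _stage_composition(state, outdir):
    cfg: RunConfig = state["config"]
    cohort = state["cohort"]
    model = state["habitat_model"]
    names = {i + 1: lab for i, lab in enumerate(model.habitat_labels)}
    by_tumor = {t.tumor_id: t for t in cohort.tumors}
    rows = []
    for (tumor, day), vol in state["habitat_maps"].items():
        pct = percent_tumor_volume(vol, habitat_names=names)
        t = by_tumor[tumor]
        for hab, p in pct.items():
            rows.append({"tumor": tumor, "day": day, "group": t.group,
                         "habitat": hab, "percent": p,
                         "volume_mm3": t.volume_mm3})
    table = composition_table(rows)
    table, excluded = exclude_large_tumors(table, cfg.volume_exclusion_mm3)
    tests = {}
    endpoint = max(cohort.days)
    for hab in sorted(table["habitat"].unique()):
        try:
            tests[hab] = compare_between_groups(table, hab, endpoint)
        except ValueError as err:
            tests[hab] = {"error": str(err)}
    d = outdir / "composition"
    d.mkdir(exist_ok=True)
    table.to_csv(d / "composition.csv", index=False)
    save_json(d / "tests.json", {"excluded": [str(e) for e in excluded],
                                 "between_groups_endpoint": _stringify(tests)})
    state["composition"] = table


def _stage_histology(state, outdir):
    cfg: RunConfig = state["config"]
    cohort = state["cohort"]
    stacks = {}
    for tumor in cohort.tumors:
        if tumor.histology is None:
            continue
        sec = tumor.histology
        stacks[tumor.tumor_id] = stack_from_masks(
            sec.masks, sec.tissue_mask, sec.pixel_size_um,
            downsample_factor=cfg.downsample_factor,
            window_um=cfg.density_window_um)
    model, maps, comp = discover_histology_habitats(
        stacks, downsample_factor=None, k_range=tuple(cfg.k_range),
        n_refs=cfg.gap_n_refs, selection=cfg.gap_selection,
        random_state=cfg.seed + 2, max_pooled_pixels=cfg.max_pooled)
    d = outdir / "histology"
    d.mkdir(exist_ok=True)
    save_json(d / "histology_model.json", model.to_dict())
    comp.to_csv(d / "histology_composition.csv", index=False)
    state["histology_model"] = model
    state["histology_comp"] = comp


def _stage_validate(state, outdir):
    cohort = state["cohort"]
    model = state["habitat_model"]
    names = {i + 1: lab for i, lab in enumerate(model.habitat_labels)}
    endpoint = max(cohort.days)
    rows = []
    hist = state["histology_comp"]
    for tumor in cohort.tumors:
        key = (tumor.tumor_id, endpoint)
        if key not in state["habitat_maps"] or tumor.histology is None:
            continue
        vol = state["habitat_maps"][key]
        roi = tumor.scans[endpoint].roi
        s = select_central_slice(roi)
        sl = vol[:, :, s]
        if (sl > 0).sum() == 0:
            continue
        mri_pct = percent_tumor_volume(sl, habitat_names=names)
        hsub = hist[hist["tumor"] == tumor.tumor_id]
        for hab in set(mri_pct) | set(hsub["habitat"]):
            rows.append({
                "tumor": tumor.tumor_id, "habitat": hab,
                "mri_percent": mri_pct.get(hab, 0.0),
                "histology_percent": float(
                    hsub[hsub["habitat"] == hab]["percent"].sum()),
            })
    paired = pd.DataFrame(rows)
    results = {}
    for hab in sorted(paired["habitat"].unique()) if len(paired) else []:
        try:
            res = correlate_habitats(paired, hab)
            results[hab] = {"r": res.r, "r2": res.r2, "p": res.p, "n": res.n}
        except ValueError as err:
            results[hab] = {"error": str(err)}
    d = outdir / "validate"
    d.mkdir(exist_ok=True)
    paired.to_csv(d / "paired_composition.csv", index=False)
    save_json(d / "correlations.json", results)


def _stringify(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify(v) for k, v in obj.items()}
    return obj


_STAGES = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "discover": _stage_discover,
    "spatial": _stage_spatial,
    "composition": _stage_composition,
    "histology": _stage_histology,
    "validate": _stage_validate,
}
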