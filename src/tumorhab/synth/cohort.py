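"""Synthetic study cohorts: longitudinal MRI with treatment effects and
coupled endpoint histology.

Each tumor gets a baseline habitat mixture drawn from a Dirichlet around
the cohort baseline composition; treated groups shift composition at later
timepoints per the effect specification (the characteristic response is an
LV-HC -> HV-HC shift).  Tumor volumes are log-normal around 275 mm^3, the
size at which xenografts enter such studies.  Every scan carries simulated
DW-MRI and DCE series, the ground-truth parameter fields, a muscle
calibration curve, and bolus arrival truth; the endpoint carries a
histology section simulated from the same habitat geometry slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import defaults
from ..kinetics import AIFModel
from .geometry import HabitatGeometry, generate_habitat_geometry
from .histology import SyntheticSection, sample_density_features, simulate_histology
from .mri import (AcquisitionGrid, sample_parameter_fields, simulate_dce,
                  simulate_dwi, simulate_muscle_curve)
from .tables import HABITAT_NAMES, HabitatParameterTable, default_table

__all__ = ["NoiseModel", "TumorScan", "Tumor", "Cohort", "default_effect",
           "generate_cohort", "simulate_paired_compositions"]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise levels for the simulated series."""

    dwi_sd: float = 15.0       # on S0 = 1000 signal units (1.5%)
    dce_sd: float = 0.01       # mM, ~3% of a typical peak tissue concentration
    muscle_sd: float = 0.002   # mM, muscle ROI average is low-noise
    ir_sd: float = 10.0


@dataclass
class TumorScan:
    day: int
    geometry: HabitatGeometry
    truth: dict[str, np.ndarray]
    dwi: np.ndarray
    dce: np.ndarray
    muscle_curve: np.ndarray
    arrival_s: float
    fractions: np.ndarray

    @property
    def roi(self) -> np.ndarray:
        return self.geometry.tumor_mask


@dataclass
class Tumor:
    tumor_id: str
    group: str
    volume_mm3: float
    scans: dict[int, TumorScan]
    histology: SyntheticSection | None = None


@dataclass
class Cohort:
    tumors: list[Tumor]
    grid: AcquisitionGrid
    table: HabitatParameterTable
    noise: NoiseModel
    seed: int | None

    @property
    def days(self) -> tuple[int, ...]:
        days = sorted({d for t in self.tumors for d in t.scans})
        return tuple(days)


def default_effect(days=(0, 1, 4)) -> dict:
    """Treated-group composition shifts (percentage points) by day.

    The response direction is a decrease of the LV-HC fraction with a
    matching increase of HV-HC, partial at the first post-treatment imaging
    and full (~20 pp) at the endpoint.
    """
    last = max(days)
    mid = [d for d in days if 0 < d < last]
    effect: dict[int, dict[str, float]] = {}
    if mid:
        effect[mid[0]] = {"LV-HC": -5.0, "HV-HC": +5.0}
    effect[last] = {"LV-HC": -20.0, "HV-HC": +20.0}
    return {"treated": effect}


BASELINE_FRACTIONS = {"HV-HC": 0.36, "LV-HC": 0.37, "LV-LC": 0.27}


def _draw_fractions(base: np.ndarray, alpha0: float, rng) -> np.ndarray:
    return rng.dirichlet(alpha0 * base)


def _apply_effect(fractions: np.ndarray, names, deltas: dict[str, float],
                  rng, jitter_sd: float = 0.02) -> np.ndarray:
    f = fractions.copy()
    for name, dpp in deltas.items():
        f[list(names).index(name)] += dpp / 100.0
    f += rng.normal(0.0, jitter_sd, size=f.shape)
    f = np.clip(f, 0.01, None)
    return f / f.sum()


def generate_cohort(
    n_per_group: int = 10,
    groups=("control", "treated"),
    days=(0, 1, 4),
    effect: dict | None = None,
    table: HabitatParameterTable | None = None,
    grid: AcquisitionGrid | None = None,
    noise: NoiseModel | None = None,
    shape=(36, 36, 12),
    volume_mean_mm3: float = 275.0,
    volume_sigma: float = 0.3,
    alpha0: float = 35.0,
    morphology: str = "rim",
    histology_pixel_um: float = 2.0,
    include_histology: bool = True,
    seed: int | None = None,
) -> Cohort:
    """Simulate a full longitudinal study.

    ``effect`` maps group -> day -> {habitat name: shift in percentage
    points}; omitted groups/days have no shift, so baseline composition is
    exchangeable across groups.  ``histology_pixel_um`` controls the
    endpoint section resolution (coarser than a native 20x scan by default
    to keep cohorts tractable; the density targets are resolution-free).
    """
    if not days:
        raise ValueError("timepoints must be non-empty")
    if n_per_group < 0:
        raise ValueError("n_per_group must be non-negative")
    table = table or default_table()
    grid = grid or AcquisitionGrid()
    noise = noise or NoiseModel()
    effect = default_effect(days) if effect is None else effect
    rng = np.random.default_rng(seed)
    names = table.names
    base = np.array([BASELINE_FRACTIONS.get(n, 1.0 / len(names)) for n in names])
    base = base / base.sum()
    aif = AIFModel(arrival_s=grid.precontrast_s)

    tumors: list[Tumor] = []
    endpoint = max(days)
    for group in groups:
        for i in range(n_per_group):
            tid = f"{group}-{i:02d}"
            vol = float(volume_mean_mm3 * np.exp(rng.normal(0.0, volume_sigma)))
            frac0 = _draw_fractions(base, alpha0, rng)
            scans: dict[int, TumorScan] = {}
            for day in days:
                deltas = effect.get(group, {}).get(day, {})
                frac = frac0 if day == min(days) else _apply_effect(
                    frac0, names, deltas, rng)
                geom = generate_habitat_geometry(
                    shape=shape, fractions=frac, morphology=morphology,
                    volume_mm3=vol, seed=int(rng.integers(2**31 - 1)),
                    habitat_names=names)
                truth = sample_parameter_fields(
                    geom, table, seed=int(rng.integers(2**31 - 1)))
                dwi = simulate_dwi(truth["adc"], grid.b_values,
                                   noise_sd=noise.dwi_sd,
                                   seed=int(rng.integers(2**31 - 1)),
                                   mask=geom.tumor_mask)
                dce = simulate_dce(
                    truth["ktrans"] * geom.tumor_mask, truth["ve"], aif, grid,
                    noise_sd=noise.dce_sd, seed=int(rng.integers(2**31 - 1)))
                muscle = simulate_muscle_curve(
                    aif, grid, noise_sd=noise.muscle_sd,
                    seed=int(rng.integers(2**31 - 1)))
                scans[day] = TumorScan(
                    day=day, geometry=geom, truth=truth, dwi=dwi, dce=dce,
                    muscle_curve=muscle, arrival_s=grid.precontrast_s,
                    fractions=frac)
            histo = None
            if include_histology and endpoint in scans:
                geom = scans[endpoint].geometry
                histo = simulate_histology(
                    geom.slice_labels(), table, pixel_size_um=histology_pixel_um,
                    seed=int(rng.integers(2**31 - 1)),
                    voxel_size_mm=geom.voxel_size_mm)
            tumors.append(Tumor(tumor_id=tid, group=group, volume_mm3=vol,
                                scans=scans, histology=histo))
    return Cohort(tumors=tumors, grid=grid, table=table, noise=noise, seed=seed)


def simulate_paired_compositions(
    n_tumors: int = 6,
    table: HabitatParameterTable | None = None,
    shape=(24, 24, 8),
    n_hist_pixels: int = 250,
    alpha0: float = 8.0,
    seed: int | None = None,
):
    """Reduced-scale coupled MRI/histology compositions for repeated-cohort
    validation experiments.

    For each tumor the two modalities share one habitat geometry; the MRI
    side pools ground-truth parameter fields of the central slice and the
    histology side draws stain-density vectors at random slice pixels
    (Poisson window counts around the table densities).  Each side is
    clustered (Ward, k = number of table habitats), clusters are labelled
    physiologically, and percent composition per habitat is returned as a
    paired table suitable for :func:`tumorhab.validation.correlate_habitats`.
    A low Dirichlet concentration spreads composition widely across tumors,
    giving the correlation signal its dynamic range.
    """
    import pandas as pd

    from ..habitats import HabitatClusterer, label_habitats_mri
    from ..histology import STAIN_ORDER, label_habitats_histology
    from ..qmri.maps import PARAM_NAMES

    table = table or default_table()
    rng = np.random.default_rng(seed)
    names = table.names
    base = np.array([BASELINE_FRACTIONS.get(n, 1.0 / len(names)) for n in names])
    base = base / base.sum()

    mri_feats, mri_tumor = [], []
    hist_feats, hist_tumor = [], []
    for t in range(n_tumors):
        frac = _draw_fractions(base, alpha0, rng)
        geom = generate_habitat_geometry(
            shape=shape, fractions=frac, volume_mm3=None,
            seed=int(rng.integers(2**31 - 1)), habitat_names=names)
        sl = geom.slice_labels()
        truth = sample_parameter_fields(geom, table,
                                        seed=int(rng.integers(2**31 - 1)))
        central = geom.central_slice_index()
        sel = sl > 0
        X = np.column_stack([truth[p][:, :, central][sel] for p in PARAM_NAMES])
        mri_feats.append(X)
        mri_tumor.append(np.full(X.shape[0], t))
        F, _ = sample_density_features(sl, table, n_hist_pixels,
                                       seed=int(rng.integers(2**31 - 1)))
        hist_feats.append(F)
        hist_tumor.append(np.full(F.shape[0], t))

    rows = []
    k = table.n_habitats
    for feats, tumor_ids, kind, labeller, order in (
        (mri_feats, mri_tumor, "mri", label_habitats_mri, PARAM_NAMES),
        (hist_feats, hist_tumor, "histology",
         lambda c: label_habitats_histology([dict(zip(STAIN_ORDER, r)) for r in c]),
         STAIN_ORDER),
    ):
        X = np.vstack(feats)
        tid = np.concatenate(tumor_ids)
        means, sds = X.mean(axis=0), X.std(axis=0, ddof=0)
        cl = HabitatClusterer(k=k, random_state=int(rng.integers(2**31 - 1)))
        cl.fit((X - means) / sds)
        cent = cl.centroids_ * sds + means
        labels = (label_habitats_mri(cent, order) if kind == "mri"
                  else labeller(cent))
        for t in range(n_tumors):
            sel = tid == t
            for c in range(k):
                pct = 100.0 * np.mean(cl.labels_[sel] == c)
                rows.append({"tumor": t, "modality": kind,
                             "habitat": labels[c], "percent": pct})
    df = pd.DataFrame(rows)
    pivot = df.pivot_table(index=["tumor", "habitat"], columns="modality",
                           values="percent", aggfunc="sum").reset_index()
    pivot = pivot.rename(columns={"mri": "mri_percent",
                                  "histology": "histology_percent"})
    pivot["mri_percent"] = pivot["mri_percent"].fillna(0.0)
    pivot["histology_percent"] = pivot["histology_percent"].fillna(0.0)
    return pivot
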