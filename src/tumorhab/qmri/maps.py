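"""Parameter map container and the per-scan fitting orchestrator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import defaults
from ..kinetics import AIFModel
from .adc import fit_adc, apply_dwi_slice_scan_filters, FilterReport
from .dce import calibrate_aif, compute_kep, estimate_arrival_map, fit_kety_tofts_map

__all__ = ["ParameterMapSet", "fit_parameter_maps"]

PARAM_NAMES = ("ktrans", "ve", "kep", "adc")


@dataclass
class ParameterMapSet:
    """Voxel maps of Ktrans, ve, kep, ADC with per-parameter validity.

    A voxel enters habitat clustering only when all four parameters are
    valid (``valid_all``).  ``provenance`` identifies the tumor/timepoint.
    """

    maps: dict[str, np.ndarray]
    validity: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)
    filter_report: FilterReport | None = None

    def __post_init__(self):
        for p in PARAM_NAMES:
            if p not in self.maps or p not in self.validity:
                raise ValueError(f"missing parameter {p!r}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError("all maps must share a shape")
        kt, ve, kep, adc = (self.maps[p] for p in PARAM_NAMES)
        v = self.valid_all
        lo, hi = defaults.KTRANS_BOUNDS
        if np.any((kt[v] < lo) | (kt[v] > hi)):
            raise ValueError("Ktrans outside physiological bounds where valid")
        if np.any((ve[v] < 0) | (ve[v] > 1)):
            raise ValueError("ve outside [0, 1] where valid")
        if np.any((kep[v] <= defaults.KEP_BOUNDS[0]) | (kep[v] >= defaults.KEP_BOUNDS[1])):
            raise ValueError("kep outside (0, 5) where valid")
        if np.any(adc[v] <= defaults.ADC_LOWER):
            raise ValueError("ADC must be positive where valid")

    @property
    def shape(self):
        return self.maps["ktrans"].shape

    @property
    def valid_all(self) -> np.ndarray:
        v = np.ones(self.maps["ktrans"].shape, dtype=bool)
        for p in PARAM_NAMES:
            v &= self.validity[p]
        return v


def fit_parameter_maps(
    dwi_series: np.ndarray,
    dce_series: np.ndarray,
    roi_mask: np.ndarray,
    muscle_curve: np.ndarray,
    base_aif: AIFModel | None = None,
    b_values=defaults.B_VALUES,
    t_s: np.ndarray | None = None,
    provenance: dict | None = None,
    supersample: int = 16,
) -> ParameterMapSet:
    """Full per-scan fit: ADC (+ slice/scan filters), AIF calibration,
    per-voxel bolus arrival, Kety-Tofts maps, and kep validity."""
    roi = np.asarray(roi_mask, bool)
    base_aif = base_aif or AIFModel()
    if t_s is None:
        t_s = np.arange(dce_series.shape[-1]) * defaults.DCE_DT_S

    adc_fit = fit_adc(dwi_series, b_values, mask=roi)
    report = apply_dwi_slice_scan_filters(adc_fit.removed_mask, roi)
    adc_valid = adc_fit.valid_mask.copy()
    for s in report.excluded_slices:
        adc_valid[:, :, s] = False

    aif = calibrate_aif(base_aif, muscle_curve, t_s)

    curves = dce_series[roi]
    arrival = estimate_arrival_map(curves, t_s)
    fit = fit_kety_tofts_map(curves, aif, arrival_s=arrival, t_s=t_s,
                             supersample=supersample)

    shape = roi.shape
    ktrans = np.zeros(shape)
    ve = np.zeros(shape)
    ktrans[roi] = fit["ktrans"]
    ve[roi] = np.where(np.isnan(fit["ve"]), 0.0, fit["ve"])
    pk_valid = np.zeros(shape, dtype=bool)
    pk_valid[roi] = fit["identifiable"] & ~np.isnan(arrival)

    kep, kep_valid = compute_kep(ktrans, ve)
    validity = {
        "adc": adc_valid,
        "ktrans": pk_valid,
        "ve": pk_valid,
        "kep": pk_valid & kep_valid,
    }
    if not report.scan_valid:
        validity = {k: np.zeros(shape, dtype=bool) for k in validity}
    maps = {"ktrans": ktrans, "ve": ve, "kep": kep, "adc": adc_fit.adc_map}
    return ParameterMapSet(maps=maps, validity=validity,
                           provenance=provenance or {}, filter_report=report)
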