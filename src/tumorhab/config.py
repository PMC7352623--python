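"""Run configuration: every analysis threshold in one serializable object.

A run is fully reproducible from a config plus a seed.  The YAML round trip
(serialize -> parse -> serialize) is idempotent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import defaults

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # cohort
    n_per_group: int = 3
    groups: tuple[str, ...] = ("control", "treated")
    days: tuple[int, ...] = (0, 1, 4)
    shape: tuple[int, int, int] = (36, 36, 12)
    volume_mean_mm3: float = 275.0
    histology_pixel_um: float = 2.0
    # acquisition
    b_values: tuple[float, ...] = defaults.B_VALUES
    inversion_times_ms: tuple[float, ...] = defaults.INVERSION_TIMES_MS
    ir_tr_ms: float = defaults.IR_TR_MS
    dce_dt_s: float = defaults.DCE_DT_S
    dce_duration_s: float = defaults.DCE_DURATION_S
    precontrast_s: float = defaults.PRECONTRAST_S
    # filters and validity
    slice_threshold: float = defaults.DWI_SLICE_REMOVAL_THRESHOLD
    scan_threshold: float = defaults.DWI_SCAN_REMOVAL_THRESHOLD
    ktrans_bounds: tuple[float, float] = defaults.KTRANS_BOUNDS
    ve_bounds: tuple[float, float] = defaults.VE_BOUNDS
    kep_bounds: tuple[float, float] = defaults.KEP_BOUNDS
    # habitat labelling
    hv_ktrans: float = defaults.HV_KTRANS_THRESHOLD
    hv_kep: float = defaults.HV_KEP_THRESHOLD
    hc_adc: float = defaults.HC_ADC_THRESHOLD
    hc_ve: float = defaults.HC_VE_THRESHOLD
    hv_vessels: float = defaults.HV_VESSEL_THRESHOLD
    hc_nuclei: float = defaults.HC_NUCLEI_THRESHOLD
    # histology
    density_window_um: float = defaults.DENSITY_WINDOW_UM
    downsample_factor: float = 0.05
    # clustering
    k_range: tuple[int, int] = defaults.K_RANGE
    gap_n_refs: int = 20
    gap_selection: str = "1se"
    max_pooled: int = 50_000
    # spatial / composition
    msi_n_perm: int = defaults.MSI_N_PERM
    volume_exclusion_mm3: float = defaults.VOLUME_EXCLUSION_MM3
    # reproducibility
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_tuples_to_lists(asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists():
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(str(source))
        kwargs = {}
        for key, val in data.items():
            default = getattr(cls, "__dataclass_fields__")[key].default
            if isinstance(default, tuple) or (isinstance(val, list)):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj
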