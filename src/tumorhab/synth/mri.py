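"""Forward simulation of DW-, IR-, and DCE-MRI series from ground-truth maps.

Signal models:

* DW-MRI:  S(b)  = S0 * exp(-ADC * b)
* IR:      S(TI) = |S0 * (1 - 2*exp(-TI/T1) + exp(-TR/T1))|
* DCE:     Ct(t) = Ktrans * conv(Cp, exp(-kep*t))  (Kety-Tofts)

Noise is additive Gaussian on the magnitude signal (the SNR regimes
simulated here make the Rician correction negligible), with configurable
standard deviation; every generator takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .. import defaults
from ..kinetics import AIFModel, kety_tofts_basis
from .geometry import HabitatGeometry
from .tables import HabitatParameterTable, MRI_PARAMS, PARAM_BOUNDS

__all__ = [
    "AcquisitionGrid",
    "sample_parameter_fields",
    "simulate_dwi",
    "simulate_ir",
    "simulate_dce",
    "simulate_muscle_curve",
]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Acquisition timing: diffusion b-values, IR inversion times, DCE grid."""

    b_values: tuple[float, ...] = defaults.B_VALUES
    inversion_times_ms: tuple[float, ...] = defaults.INVERSION_TIMES_MS
    tr_ms: float = defaults.IR_TR_MS
    dce_dt_s: float = defaults.DCE_DT_S
    dce_duration_s: float = defaults.DCE_DURATION_S
    precontrast_s: float = defaults.PRECONTRAST_S

    def __post_init__(self):
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if np.any(np.diff(self.inversion_times_ms) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if self.dce_dt_s <= 0 or self.dce_duration_s <= 0:
            raise ValueError("DCE grid must be positive")

    @property
    def dce_times_s(self) -> np.ndarray:
        n = int(round(self.dce_duration_s / self.dce_dt_s))
        return np.arange(n) * self.dce_dt_s

    @property
    def n_frames(self) -> int:
        return self.dce_times_s.shape[0]


def _truncnorm_draw(mean, sd, bounds, size, rng):
    lo, hi = bounds
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_parameter_fields(
    geometry: HabitatGeometry,
    table: HabitatParameterTable,
    seed: int | None = None,
    ktrans_ve_correlation: float = 0.7,
) -> dict[str, np.ndarray]:
    """Draw per-voxel ground-truth maps from per-habitat truncated normals.

    Returns maps for 'ktrans', 've', 'adc', 't1' plus the derived 'kep'
    (= Ktrans/ve); background voxels are zero.  Within a habitat, Ktrans and
    ve are positively correlated (both track local tissue viability and
    stromal access), which keeps the derived kep = Ktrans/ve dispersion
    physiological rather than ratio-inflated; draws >2 sd from a bound are
    exact truncated normals, near a bound they are clipped.
    """
    ids = set(np.unique(geometry.label_volume)) - {0}
    missing = ids - set(table.mri)
    if missing:
        raise ValueError(f"parameter table missing habitats {sorted(missing)}")
    for h in ids:
        for p in MRI_PARAMS:
            if table.mri[h][p].sd < 0:
                raise ValueError("spread must be non-negative")
    rho = ktrans_ve_correlation
    rng = np.random.default_rng(seed)
    maps = {p: np.zeros(geometry.label_volume.shape, dtype=float) for p in MRI_PARAMS}
    for h in sorted(ids):
        sel = geometry.label_volume == h
        n = int(sel.sum())
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
        for p, z in (("ktrans", z1), ("ve", z2)):
            st = table.mri[h][p]
            lo, hi = PARAM_BOUNDS[p]
            maps[p][sel] = np.clip(st.mean + st.sd * z, lo, hi)
        for p in ("adc", "t1"):
            st = table.mri[h][p]
            maps[p][sel] = _truncnorm_draw(st.mean, st.sd, PARAM_BOUNDS[p], n, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(maps["ve"] > 0, maps["ktrans"] / maps["ve"], 0.0)
    maps["kep"] = kep
    return maps


def _add_noise(signal, noise_sd, rng):
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return signal
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


def simulate_dwi(
    adc_map: np.ndarray,
    b_values=defaults.B_VALUES,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Diffusion-weighted series, shape adc_map.shape + (len(b_values),)."""
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    adc = np.asarray(adc_map, dtype=float)
    signal = s0 * np.exp(-adc[..., None] * b)
    if mask is not None:
        signal = signal * np.asarray(mask, bool)[..., None]
    return _add_noise(signal, noise_sd, np.random.default_rng(seed))


def simulate_ir(
    t1_map: np.ndarray,
    inversion_times_ms=defaults.INVERSION_TIMES_MS,
    tr_ms: float = defaults.IR_TR_MS,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Magnitude inversion-recovery series, shape t1_map.shape + (n_TI,)."""
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    ti_s = np.asarray(inversion_times_ms, dtype=float) / 1000.0
    tr_s = tr_ms / 1000.0
    t1 = np.asarray(t1_map, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        inv_t1 = np.where(t1 > 0, 1.0 / np.where(t1 > 0, t1, 1.0), np.inf)
    signal = s0 * (1.0 - 2.0 * np.exp(-ti_s * inv_t1[..., None])
                   + np.exp(-tr_s * inv_t1)[..., None])
    signal = np.abs(signal)
    signal = np.where((t1 > 0)[..., None], signal, 0.0)
    if mask is not None:
        signal = signal * np.asarray(mask, bool)[..., None]
    return np.abs(_add_noise(signal, noise_sd, np.random.default_rng(seed)))


def simulate_dce(
    ktrans_map: np.ndarray,
    ve_map: np.ndarray,
    aif: AIFModel | None = None,
    grid: AcquisitionGrid | None = None,
    arrival_s: float | np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    supersample: int = 16,
) -> np.ndarray:
    """Tissue concentration series Ct(t), shape map.shape + (n_frames,).

    ``arrival_s`` may be a scalar or a per-voxel map of bolus arrival times;
    arrival values are snapped to the internal fine grid.  Voxels with
    Ktrans = 0 produce identically zero curves.
    """
    grid = grid or AcquisitionGrid()
    aif = aif or AIFModel(arrival_s=grid.precontrast_s)
    ktrans = np.asarray(ktrans_map, dtype=float)
    ve = np.asarray(ve_map, dtype=float)
    if np.any(ktrans < 0):
        raise ValueError("Ktrans must be non-negative")
    active = ktrans > 0
    if np.any(ve[active] <= 0):
        raise ValueError("ve must be positive wherever Ktrans > 0")
    t_s = grid.dce_times_s
    out = np.zeros(ktrans.shape + (t_s.shape[0],), dtype=float)
    if np.any(active):
        if arrival_s is None:
            arrival = np.full(ktrans.shape, aif.arrival_s, dtype=float)
        else:
            arrival = np.broadcast_to(np.asarray(arrival_s, dtype=float), ktrans.shape)
        fine_dt = grid.dce_dt_s / supersample
        arr_q = np.round(arrival / fine_dt) * fine_dt
        kep = np.zeros_like(ktrans)
        kep[active] = ktrans[active] / ve[active]
        for a in np.unique(arr_q[active]):
            sel = active & (arr_q == a)
            basis = _per_voxel_curves(kep[sel], t_s, aif, a, supersample)
            out[sel] = ktrans[sel][:, None] * basis
    return _add_noise(out, noise_sd, np.random.default_rng(seed))


def _per_voxel_curves(kep_values, t_s, aif, arrival_s, supersample):
    return kety_tofts_basis(kep_values, t_s, aif, arrival_s, supersample)


def simulate_muscle_curve(
    aif: AIFModel | None = None,
    grid: AcquisitionGrid | None = None,
    ktrans_ref: float = 0.1,
    ve_ref: float = 0.1,
    scale_true: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Mean skeletal-muscle concentration curve for AIF calibration.

    Generated from the reference muscle Kety-Tofts parameters with the AIF
    scaled by ``scale_true``; the calibration op recovers that scale.
    """
    grid = grid or AcquisitionGrid()
    base = aif or AIFModel(arrival_s=grid.precontrast_s)
    scaled = AIFModel(base=base.base, scale=base.scale * scale_true,
                      arrival_s=base.arrival_s)
    from ..kinetics import kety_tofts_curve

    curve = kety_tofts_curve(ktrans_ref, ve_ref, grid.dce_times_s, scaled)
    return _add_noise(curve, noise_sd, np.random.default_rng(seed))
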