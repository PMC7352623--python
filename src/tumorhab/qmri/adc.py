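"""ADC mapping from multi-b-value DW-MRI with monotonicity and slice filters.

The monoexponential decay S(b) = S0*exp(-ADC*b) is fitted by closed-form
least squares on log-signal.  Tumor voxels whose signal does not decrease
strictly monotonically across b-values (S(b800) < S(b500) < S(b150)) are
removed before fitting; a slice is excluded when strictly more than 20% of
its tumor voxels were removed, and a whole scan is invalid when strictly
more than half of its slices were excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import defaults

__all__ = ["ADCFitResult", "FilterReport", "fit_adc", "apply_dwi_slice_scan_filters"]


@dataclass
class FilterReport:
    """Outcome of the DWI slice/scan quality filters."""

    fraction_removed: float
    slice_fractions: dict[int, float]
    excluded_slices: tuple[int, ...]
    scan_valid: bool

    def __post_init__(self):
        if not (0.0 <= self.fraction_removed <= 1.0):
            raise ValueError("fraction_removed must lie in [0, 1]")


@dataclass
class ADCFitResult:
    adc_map: np.ndarray
    removed_mask: np.ndarray   # voxels failing the monotonicity filter
    valid_mask: np.ndarray     # fitted voxels (mask minus removed)


def fit_adc(dwi_series: np.ndarray, b_values=defaults.B_VALUES,
            mask: np.ndarray | None = None) -> ADCFitResult:
    """Fit ADC voxel-wise; series shape is spatial + (n_b,).

    Non-monotone voxels are flagged removed and excluded from fitting; an
    all-removed mask yields an empty (all-invalid) map rather than an error.
    """
    dwi = np.asarray(dwi_series, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if b.shape[0] < 2:
        raise ValueError("at least two b-values are required")
    if dwi.shape[-1] != b.shape[0]:
        raise ValueError("series last axis must match b-values")
    spatial = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, bool)

    diffs = np.diff(dwi, axis=-1)
    monotone = np.all(diffs < 0, axis=-1)
    positive = np.all(dwi > 0, axis=-1)
    removed = mask & ~(monotone & positive)
    valid = mask & ~removed

    adc = np.zeros(spatial, dtype=float)
    if valid.any():
        logs = np.log(dwi[valid])
        # slope of log-signal vs b is -ADC (closed-form simple regression)
        bc = b - b.mean()
        slope = (logs * bc).sum(axis=-1) / (bc ** 2).sum()
        adc[valid] = -slope
    return ADCFitResult(adc_map=adc, removed_mask=removed, valid_mask=valid)


def apply_dwi_slice_scan_filters(
    removed_mask: np.ndarray,
    roi_mask: np.ndarray,
    slice_axis: int = 2,
    slice_threshold: float = defaults.DWI_SLICE_REMOVAL_THRESHOLD,
    scan_threshold: float = defaults.DWI_SCAN_REMOVAL_THRESHOLD,
) -> FilterReport:
    """Slice and scan exclusion from the per-voxel removal mask.

    A slice is excluded iff its removed fraction is strictly greater than
    ``slice_threshold``; the scan is invalid iff the excluded-slice fraction
    is strictly greater than ``scan_threshold``.  Slices with no tumor ROI
    do not participate.
    """
    removed = np.asarray(removed_mask, bool)
    roi = np.asarray(roi_mask, bool)
    if removed.shape != roi.shape:
        raise ValueError("removal mask and ROI must share a shape")
    n_total = roi.sum()
    fraction_removed = float((removed & roi).sum() / n_total) if n_total else 0.0

    slice_fractions: dict[int, float] = {}
    excluded = []
    n_slices = roi.shape[slice_axis]
    tumor_slices = 0
    for s in range(n_slices):
        roi_s = np.take(roi, s, axis=slice_axis)
        n = roi_s.sum()
        if n == 0:
            continue
        tumor_slices += 1
        frac = float((np.take(removed, s, axis=slice_axis) & roi_s).sum() / n)
        slice_fractions[s] = frac
        if frac > slice_threshold:
            excluded.append(s)
    scan_valid = True
    if tumor_slices and len(excluded) / tumor_slices > scan_threshold:
        scan_valid = False
    return FilterReport(
        fraction_removed=fraction_removed,
        slice_fractions=slice_fractions,
        excluded_slices=tuple(excluded),
        scan_valid=scan_valid,
    )
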