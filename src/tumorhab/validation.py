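"""Validation of MRI habitats against histology habitats.

Endpoint MRI habitat composition on the central tumor slice is correlated
(Pearson, per habitat, across tumors) with histological habitat composition
of the matched section.  Central-slice selection is automated as the slice
of maximal ROI area (ties to the lowest index), with a manual override for
cases where the cut plane is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["select_central_slice", "correlate_habitats", "CorrelationResult"]


def select_central_slice(roi_mask: np.ndarray, axis: int = 2,
                         override: int | None = None) -> int:
    """Index of the slice with maximal ROI area along ``axis``."""
    roi = np.asarray(roi_mask, bool)
    if override is not None:
        return int(override)
    areas = roi.sum(axis=tuple(i for i in range(roi.ndim) if i != axis))
    if areas.max() == 0:
        raise ValueError("ROI is empty")
    return int(np.argmax(areas))  # argmax ties break to the lowest index


@dataclass
class CorrelationResult:
    habitat: str
    r: float
    r2: float
    p: float
    n: int


def correlate_habitats(paired: pd.DataFrame, habitat) -> CorrelationResult:
    """Pearson correlation between MRI and histology percents of a habitat.

    ``paired`` needs columns 'tumor', 'habitat', 'mri_percent',
    'histology_percent' with one row per tumor for each habitat.  Requires
    at least three tumors and non-degenerate variance on both sides.
    """
    sub = paired[paired["habitat"] == habitat]
    x = sub["mri_percent"].to_numpy(dtype=float)
    y = sub["histology_percent"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least three tumor pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one side: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(habitat=str(habitat), r=r, r2=r * r,
                             p=float(res.pvalue), n=int(x.size))
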