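"""Per-habitat ground-truth parameter tables for the synthetic generators.

Each table gives, for every habitat, the mean and spread of the quantitative
MRI parameters (Ktrans in 1/min, ve dimensionless, ADC in mm^2/s, T1 in s)
and the endpoint histology stain densities (nuclei / vessel / Ki-67+ counts
per 150 um x 150 um unit, necrosis percent-area per unit).

MRI and stain-density means follow the habitat-wise values reported for
HER2+ (BT-474-like) and triple-negative (MDA-MB-231-like) xenograft cohorts;
spreads are free parameters of the generator (inter-voxel variance is not
published); they are calibrated once so that the pooled, z-scored voxel
distribution reproduces the structure the source cohorts report -- three
separated, gap-statistic-selectable habitats -- while remaining overlapping
(within-habitat coefficients of variation near 8%, before measurement
noise, which adds comparable dispersion to fitted maps).  T1 values near 2 s are typical at 7T and exercise the
inversion-recovery fit only; T1 is not a clustering feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MRI_PARAMS = ("ktrans", "ve", "adc", "t1")
STAIN_PARAMS = ("nuclei", "necrosis", "ki67", "vessels")

# Physiological truncation bounds for sampled parameter fields.
PARAM_BOUNDS = {
    "ktrans": (1e-4, 5.0),
    "ve": (0.01, 1.0),
    "adc": (5e-5, 3.5e-3),
    "t1": (0.2, 5.0),
}

HABITAT_NAMES = ("HV-HC", "LV-HC", "LV-LC")


@dataclass(frozen=True)
class ParamStats:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("spread must be non-negative")


@dataclass
class HabitatParameterTable:
    """Ground-truth distributions per habitat id (1..H)."""

    mri: dict[int, dict[str, ParamStats]]
    histology: dict[int, dict[str, float]]
    names: tuple[str, ...] = HABITAT_NAMES

    def __post_init__(self):
        for h, params in self.mri.items():
            for key in MRI_PARAMS:
                if key not in params:
                    raise ValueError(f"habitat {h} missing MRI parameter {key!r}")
            lo, hi = PARAM_BOUNDS["ktrans"]
            if not (0.0 <= params["ktrans"].mean <= 5.0):
                raise ValueError("Ktrans mean outside [0, 5] 1/min")
            if not (0.0 <= params["ve"].mean <= 1.0):
                raise ValueError("ve mean outside [0, 1]")
            if params["adc"].mean <= 0:
                raise ValueError("ADC mean must be positive")
        for h, dens in self.histology.items():
            for key in STAIN_PARAMS:
                if key not in dens:
                    raise ValueError(f"habitat {h} missing stain density {key!r}")
                if dens[key] < 0:
                    raise ValueError("stain densities must be non-negative")

    @property
    def habitat_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.mri))

    @property
    def n_habitats(self) -> int:
        return len(self.mri)

    def mri_mean(self, habitat: int, param: str) -> float:
        return self.mri[habitat][param].mean


def bt474_table() -> HabitatParameterTable:
    """HER2+ cohort defaults.

    Habitat 1 is the well-perfused, cell-dense rim (HV-HC), habitat 2 the
    poorly perfused but cell-dense intermediate shell (LV-HC), habitat 3 the
    necrotic low-cellularity core (LV-LC).
    """
    mri = {
        1: {"ktrans": ParamStats(0.18, 0.012), "ve": ParamStats(0.27, 0.022),
            "adc": ParamStats(6.9e-4, 0.45e-4), "t1": ParamStats(1.9, 0.15)},
        2: {"ktrans": ParamStats(0.05, 0.008), "ve": ParamStats(0.18, 0.018),
            "adc": ParamStats(6.2e-4, 0.45e-4), "t1": ParamStats(2.0, 0.15)},
        3: {"ktrans": ParamStats(0.04, 0.008), "ve": ParamStats(0.78, 0.04),
            "adc": ParamStats(1.2e-3, 0.5e-4), "t1": ParamStats(2.2, 0.15)},
    }
    histology = {
        1: {"nuclei": 142.3, "necrosis": 9.4, "ki67": 31.0, "vessels": 5.5},
        2: {"nuclei": 109.5, "necrosis": 10.9, "ki67": 6.6, "vessels": 2.2},
        3: {"nuclei": 17.8, "necrosis": 48.1, "ki67": 0.5, "vessels": 0.7},
    }
    return HabitatParameterTable(mri=mri, histology=histology)


def mda_mb_231_table() -> HabitatParameterTable:
    """Triple-negative cohort defaults.

    Distinctive feature: the low-cellularity core has *low* ADC (5.7e-4) but
    very high ve (0.99), so the ADC and ve cellularity indicators disagree
    and ve decides the label.
    """
    mri = {
        1: {"ktrans": ParamStats(0.13, 0.009), "ve": ParamStats(0.27, 0.022),
            "adc": ParamStats(6.9e-4, 0.45e-4), "t1": ParamStats(1.9, 0.15)},
        2: {"ktrans": ParamStats(0.04, 0.006), "ve": ParamStats(0.17, 0.016),
            "adc": ParamStats(5.1e-4, 0.4e-4), "t1": ParamStats(2.0, 0.15)},
        3: {"ktrans": ParamStats(0.01, 0.003), "ve": ParamStats(0.99, 0.02),
            "adc": ParamStats(5.7e-4, 0.4e-4), "t1": ParamStats(2.2, 0.15)},
    }
    histology = {
        1: {"nuclei": 249.9, "necrosis": 4.3, "ki67": 23.7, "vessels": 3.9},
        2: {"nuclei": 220.8, "necrosis": 3.6, "ki67": 8.5, "vessels": 0.58},
        3: {"nuclei": 60.1, "necrosis": 21.1, "ki67": 0.9, "vessels": 0.28},
    }
    return HabitatParameterTable(mri=mri, histology=histology)


def default_table() -> HabitatParameterTable:
    return bt474_table()
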