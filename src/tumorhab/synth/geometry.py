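"""Habitat geometry phantoms.

A tumor is an ellipsoid of voxels partitioned into H spatially contiguous
habitats.  The default "rim" morphology places habitat 1 as an outer shell,
habitat 2 as an intermediate shell, and habitat 3 as the core, matching the
enhancing-rim / necrotic-core arrangement commonly seen in xenografts.  A
"blobs" morphology grows habitats from random seed voxels with volume
budgets, for phantoms without radial symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .. import defaults
from .tables import HABITAT_NAMES

__all__ = ["HabitatGeometry", "generate_habitat_geometry"]


@dataclass
class HabitatGeometry:
    """Integer habitat label volume (0 = background, 1..H = habitat id)."""

    label_volume: np.ndarray
    voxel_size_mm: tuple[float, float, float] = defaults.VOXEL_SIZE_MM
    habitat_names: tuple[str, ...] = HABITAT_NAMES

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.dtype.kind not in "iu":
            raise ValueError("label volume must be integer")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.label_volume > 0

    @property
    def n_habitats(self) -> int:
        return int(self.label_volume.max())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def volume_mm3(self) -> float:
        return float(self.tumor_mask.sum()) * self.voxel_volume_mm3

    def fractions(self) -> np.ndarray:
        """Realized per-habitat volume fractions (sums to 1)."""
        n = self.tumor_mask.sum()
        counts = np.bincount(self.label_volume.ravel(), minlength=self.n_habitats + 1)[1:]
        return counts / max(n, 1)

    def central_slice_index(self, axis: int = 2) -> int:
        areas = self.tumor_mask.sum(axis=tuple(i for i in range(3) if i != axis))
        return int(np.argmax(areas))

    def slice_labels(self, index: int | None = None, axis: int = 2) -> np.ndarray:
        if index is None:
            index = self.central_slice_index(axis)
        return np.take(self.label_volume, index, axis=axis)


def _ellipsoid_radius(shape, voxel_size, radii_mm, rng, wobble):
    """Normalized ellipsoidal radius of every voxel, optionally perturbed by a
    smooth random field so shells are not perfectly spherical."""
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel_size)],
        indexing="ij",
    )
    r = np.sqrt(sum((g / rad) ** 2 for g, rad in zip(grids, radii_mm)))
    if wobble > 0:
        noise = rng.standard_normal(shape)
        noise = ndimage.gaussian_filter(noise, sigma=[max(2, s // 8) for s in shape])
        noise /= max(np.abs(noise).max(), 1e-12)
        r = r * (1.0 + wobble * noise)
    return r


def generate_habitat_geometry(
    shape: tuple[int, int, int] = (defaults.MATRIX, defaults.MATRIX, defaults.N_SLICES),
    fractions=(0.36, 0.37, 0.27),
    morphology: str = "rim",
    seed: int | None = None,
    voxel_size_mm: tuple[float, float, float] = defaults.VOXEL_SIZE_MM,
    volume_mm3: float | None = None,
    habitat_names: tuple[str, ...] | None = None,
    wobble: float = 0.08,
) -> HabitatGeometry:
    """Generate an ellipsoidal tumor partitioned into contiguous habitats.

    Parameters
    ----------
    shape : voxel grid dimensions (each >= 8).
    fractions : target volume fraction per habitat; must be non-negative and
        sum to 1.  Realized fractions are exact up to voxel rounding.
    morphology : "rim" (concentric shells, habitat 1 outermost) or "blobs"
        (seeded region growth with volume budgets).
    volume_mm3 : target tumor volume; defaults to an ellipsoid filling ~80%
        of each axis of the grid.
    wobble : relative amplitude of the smooth boundary perturbation.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError("shape must be 3-D with at least 8 voxels per axis")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    names = tuple(habitat_names) if habitat_names is not None else HABITAT_NAMES[: len(fractions)]

    extent_mm = [n * v for n, v in zip(shape, voxel_size_mm)]
    radii = np.array([0.4 * e for e in extent_mm])
    if volume_mm3 is not None:
        base_vol = 4.0 / 3.0 * np.pi * np.prod(radii)
        radii = radii * (volume_mm3 / base_vol) ** (1.0 / 3.0)
        if np.any(2 * radii > extent_mm):
            raise ValueError("requested volume does not fit in the grid")

    r = _ellipsoid_radius(shape, voxel_size_mm, radii, rng, wobble)
    tumor = r <= 1.0
    n_tumor = int(tumor.sum())
    if n_tumor < len(fractions):
        raise ValueError("tumor too small for the requested habitat count")

    labels = np.zeros(shape, dtype=np.int16)
    counts = np.floor(fractions * n_tumor).astype(int)
    # Distribute rounding remainder to the largest fractions.
    for i in np.argsort(-(fractions * n_tumor - counts))[: n_tumor - counts.sum()]:
        counts[i] += 1

    if morphology == "rim":
        flat_idx = np.flatnonzero(tumor.ravel())
        order = np.argsort(-r.ravel()[flat_idx], kind="stable")  # outermost first
        start = 0
        for h, c in enumerate(counts, start=1):
            sel = flat_idx[order[start: start + c]]
            labels.ravel()[sel] = h
            start += c
    elif morphology == "blobs":
        labels = _grow_blobs(tumor, counts, rng)
    else:
        raise ValueError(f"unknown morphology {morphology!r}")
    return HabitatGeometry(labels, tuple(voxel_size_mm), names)


def _grow_blobs(tumor: np.ndarray, counts: np.ndarray, rng) -> np.ndarray:
    """Capacity-constrained nearest-seed assignment inside the tumor mask."""
    coords = np.argwhere(tumor)
    n = coords.shape[0]
    h = len(counts)
    seed_idx = rng.choice(n, size=h, replace=False)
    seeds = coords[seed_idx].astype(float)
    d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    assigned = np.full(n, -1, dtype=int)
    remaining = counts.copy()
    # Greedy fill: voxels in order of distance to their nearest open habitat.
    order = np.argsort(d.min(axis=1), kind="stable")
    for vi in order:
        for hi in np.argsort(d[vi], kind="stable"):
            if remaining[hi] > 0:
                assigned[vi] = hi
                remaining[hi] -= 1
                break
    labels = np.zeros(tumor.shape, dtype=np.int16)
    labels[tuple(coords.T)] = assigned + 1
    return labels
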