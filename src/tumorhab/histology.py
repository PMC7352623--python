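"""Histology processing: stain segmentation, registration, density maps,
and histological habitat discovery.

From stained-section images (or stain-positive masks) the pipeline builds
co-registered stain-density maps — connected-component counts (nuclei,
Ki-67+ nuclei, microvessels) or percent-positive area (necrosis) within the
150 um x 150 um neighbourhood ("unit") around each pixel — downsamples
them, pools pixels across tumors, and reuses the habitat-discovery
machinery to find histological habitats.  Cluster means label habitats:
high-vascularity when mean vessels/unit > 3, high-cellularity when mean
nuclei/unit > 100 (strict; boundary falls low).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters as skfilters
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation
from sklearn.cluster import KMeans

from . import defaults
from .habitats import HabitatClusterer, HabitatModel
from .synth.histology import (COLOR_BACKGROUND, COLOR_EOSIN, COLOR_NECROSIS,
                              COLOR_NUCLEUS)

__all__ = [
    "StainDensityStack",
    "segment_hne",
    "segment_dab",
    "tissue_mask",
    "rigid_register",
    "RigidTransform",
    "density_map",
    "density_at",
    "downsample_density",
    "label_habitats_histology",
    "discover_histology_habitats",
]

log = logging.getLogger(__name__)

STAIN_ORDER = ("nuclei", "necrosis", "ki67", "vessels")


@dataclass
class StainDensityStack:
    """Co-registered stain-density maps sharing a pixel grid.

    Keys: 'nuclei', 'ki67', 'vessels' in counts/unit; 'necrosis' in percent
    area/unit; a unit is the 150 um x 150 um neighbourhood around a pixel.
    """

    maps: dict[str, np.ndarray]
    tissue: np.ndarray
    pixel_size_um: float
    window_um: float = defaults.DENSITY_WINDOW_UM

    def __post_init__(self):
        shapes = {m.shape for m in self.maps.values()} | {self.tissue.shape}
        if len(shapes) != 1:
            raise ValueError("all maps must share a shape")
        for key, m in self.maps.items():
            if np.any(m < 0):
                raise ValueError(f"{key} density must be non-negative")
        if "necrosis" in self.maps and np.any(self.maps["necrosis"] > 100):
            raise ValueError("necrosis percent-area must be <= 100")


def segment_hne(rgb_image: np.ndarray, n_clusters: int = 4,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """K-means segmentation of an H&E section into nuclei and necrosis masks.

    Pixels are clustered in RGB space (k = 4: nuclei, viable eosin tissue,
    pale necrosis, background) and each cluster is assigned to the class
    whose reference stain colour its centroid is nearest.  Deterministic
    for a fixed seed; a blank (near-constant) image returns empty masks.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an RGB image")
    flat = rgb.reshape(-1, 3)
    if flat.std(axis=0).max() < 1.5:  # blank slide
        empty = np.zeros(rgb.shape[:2], dtype=bool)
        return empty, empty
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed).fit(flat)
    refs = np.stack([COLOR_NUCLEUS, COLOR_EOSIN, COLOR_NECROSIS, COLOR_BACKGROUND])
    ref_class = np.array(["nuclei", "eosin", "necrosis", "background"])
    d = np.linalg.norm(km.cluster_centers_[:, None, :] - refs[None, :, :], axis=2)
    assign = ref_class[np.argmin(d, axis=1)]
    labels = km.labels_.reshape(rgb.shape[:2])
    nuclei = np.isin(labels, np.flatnonzero(assign == "nuclei"))
    necrosis = np.isin(labels, np.flatnonzero(assign == "necrosis"))
    return nuclei, necrosis


def segment_dab(image: np.ndarray) -> np.ndarray:
    """Otsu threshold of a single-channel stain image; positives are bright.

    The threshold maximizes between-class variance over a 256-bin histogram.
    A constant image yields an empty mask with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if np.ptp(img) == 0:
        warnings.warn("constant image: no Otsu threshold exists, returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    thr = skfilters.threshold_otsu(img, nbins=256)
    return img > thr


def tissue_mask(rgb_image: np.ndarray, roi: np.ndarray | None = None,
                saturation_threshold: float = 0.08,
                min_object_px: int = 64) -> np.ndarray:
    """Whole-tissue mask: remove gray/white (low-saturation) background.

    Saturation is (max-min)/max over RGB.  Small specks are removed and
    holes filled; an optional ROI mask is intersected.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx == 0, 1, mx), 0.0)
    mask = sat > saturation_threshold
    if mask.any():
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)))
        mask = ndimage.binary_fill_holes(mask)
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            mask = np.isin(lab, np.flatnonzero(sizes >= min_object_px))
    if roi is not None:
        mask = mask & np.asarray(roi, bool)
    return mask


@dataclass
class RigidTransform:
    angle_deg: float
    shift: tuple[float, float]     # (row, col) translation after rotation
    overlap: float                 # Dice overlap after alignment
    warning: bool = False

    def apply(self, mask: np.ndarray) -> np.ndarray:
        rot = sktransform.rotate(np.asarray(mask, float), self.angle_deg,
                                 order=0, preserve_range=True) > 0.5
        return ndimage.shift(rot.astype(float), self.shift, order=0) > 0.5


def _dice(a, b):
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 0.0


def rigid_register(moving_mask: np.ndarray, fixed_mask: np.ndarray,
                   angle_range_deg: float = 20.0,
                   coarse_step_deg: float = 1.0) -> RigidTransform:
    """Rotation + translation aligning ``moving_mask`` onto ``fixed_mask``.

    Searches rotations on a 1 degree grid (refined to 0.1 degree) with the
    translation at each angle from FFT cross-correlation, maximizing Dice
    overlap.  A final overlap below 0.5 sets the warning flag.
    """
    moving = np.asarray(moving_mask, bool)
    fixed = np.asarray(fixed_mask, bool)
    if not moving.any() or not fixed.any():
        raise ValueError("both masks must be non-empty")

    def score(angle):
        rot = sktransform.rotate(moving.astype(float), angle, order=0,
                                 preserve_range=True) > 0.5
        shift, _, _ = phase_cross_correlation(
            fixed.astype(float), rot.astype(float), upsample_factor=4,
            normalization=None)
        moved = ndimage.shift(rot.astype(float), shift, order=0) > 0.5
        return _dice(moved, fixed), tuple(float(s) for s in shift)

    best = (-1.0, 0.0, (0.0, 0.0))
    for ang in np.arange(-angle_range_deg, angle_range_deg + 1e-9, coarse_step_deg):
        d, sh = score(ang)
        if d > best[0]:
            best = (d, float(ang), sh)
    for ang in np.arange(best[1] - 0.9, best[1] + 0.95, 0.1):
        d, sh = score(ang)
        if d > best[0]:
            best = (d, float(ang), sh)
    overlap, angle, shift = best
    return RigidTransform(angle_deg=angle, shift=shift, overlap=overlap,
                          warning=overlap < 0.5)


def _box_sum(arr: np.ndarray, half: int) -> np.ndarray:
    """Sum of ``arr`` over the (2*half+1)^2 window around each pixel,
    truncated at the borders (integral-image, exact)."""
    pad = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=pad[1:, 1:])
    n0, n1 = arr.shape
    i0 = np.clip(np.arange(n0) - half, 0, n0)
    i1 = np.clip(np.arange(n0) + half + 1, 0, n0)
    j0 = np.clip(np.arange(n1) - half, 0, n1)
    j1 = np.clip(np.arange(n1) + half + 1, 0, n1)
    return (pad[np.ix_(i1, j1)] - pad[np.ix_(i0, j1)]
            - pad[np.ix_(i1, j0)] + pad[np.ix_(i0, j0)])


def _window_half(window_um: float, pixel_size_um: float) -> int:
    w = int(round(window_um / pixel_size_um))
    if w < 3:
        raise ValueError("window smaller than 3 pixels")
    return w // 2


def density_map(mask: np.ndarray, mode: str = "count",
                window_um: float = defaults.DENSITY_WINDOW_UM,
                pixel_size_um: float = defaults.HISTOLOGY_PIXEL_UM) -> np.ndarray:
    """Neighbourhood stain density around every pixel.

    count mode: the number of 8-connected components of ``mask`` that
    intersect the window centered on the pixel (components touching the
    window count; windows are truncated at the image border).
    percent_area mode: percent of positive pixels within the (truncated,
    area-renormalized) window.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    mask = np.asarray(mask, bool)
    half = _window_half(window_um, pixel_size_um)
    if mode == "percent_area":
        pos = _box_sum(mask.astype(float), half)
        area = _box_sum(np.ones(mask.shape), half)
        return 100.0 * pos / area
    if mode != "count":
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros(mask.shape, dtype=float)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return out
    objects = ndimage.find_objects(lab)
    for comp, sl in enumerate(objects, start=1):
        # Window centers whose window touches the component: the component
        # dilated by the window box (separable maximum filter on its bbox).
        r0 = max(sl[0].start - half, 0)
        r1 = min(sl[0].stop + half, mask.shape[0])
        c0 = max(sl[1].start - half, 0)
        c1 = min(sl[1].stop + half, mask.shape[1])
        local = (lab[r0:r1, c0:c1] == comp).astype(np.uint8)
        hit = ndimage.maximum_filter(local, size=2 * half + 1, mode="constant")
        out[r0:r1, c0:c1] += hit
    return out


def density_at(mask: np.ndarray, centers: np.ndarray, mode: str = "count",
               window_um: float = defaults.DENSITY_WINDOW_UM,
               pixel_size_um: float = defaults.HISTOLOGY_PIXEL_UM) -> np.ndarray:
    """Density values at selected pixel centers only.

    Exactly equals ``density_map(...)[centers]`` (the nearest-neighbour
    downsampling path evaluates the dense map at sampled pixels, so sparse
    evaluation is equivalent and much cheaper on large sections).
    """
    mask = np.asarray(mask, bool)
    centers = np.asarray(centers, dtype=int)
    half = _window_half(window_um, pixel_size_um)
    out = np.empty(centers.shape[0], dtype=float)
    if mode == "count":
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        for i, (r, c) in enumerate(centers):
            win = lab[max(r - half, 0): r + half + 1,
                      max(c - half, 0): c + half + 1]
            vals = np.unique(win)
            out[i] = vals.size - (1 if vals.size and vals[0] == 0 else 0)
    elif mode == "percent_area":
        for i, (r, c) in enumerate(centers):
            win = mask[max(r - half, 0): r + half + 1,
                       max(c - half, 0): c + half + 1]
            out[i] = 100.0 * win.mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def _nn_indices(n: int, factor: float) -> np.ndarray:
    out_n = max(int(np.floor(n * factor)), 1)
    return np.minimum(((np.arange(out_n) + 0.5) / factor).astype(int), n - 1)


def downsample_density(stack_or_map, axis_factor: float = 0.01):
    """Nearest-neighbour downsampling by a per-axis scale factor.

    Accepts a 2-D array or a StainDensityStack; sampled values are original
    pixel values (no interpolation).  Rejects outputs smaller than 4 x 4.
    """
    if not (0.0 < axis_factor < 1.0):
        raise ValueError("factor must lie in (0, 1)")

    def one(arr):
        ii = _nn_indices(arr.shape[0], axis_factor)
        jj = _nn_indices(arr.shape[1], axis_factor)
        if ii.size < 4 or jj.size < 4:
            raise ValueError("downsampled output smaller than 4 x 4")
        return arr[np.ix_(ii, jj)]

    if isinstance(stack_or_map, StainDensityStack):
        return StainDensityStack(
            maps={k: one(v) for k, v in stack_or_map.maps.items()},
            tissue=one(stack_or_map.tissue),
            pixel_size_um=stack_or_map.pixel_size_um / axis_factor,
            window_um=stack_or_map.window_um,
        )
    return one(np.asarray(stack_or_map))


def stack_from_masks(
    masks: dict[str, np.ndarray],
    tissue: np.ndarray,
    pixel_size_um: float,
    downsample_factor: float = 0.01,
    window_um: float = defaults.DENSITY_WINDOW_UM,
) -> StainDensityStack:
    """Downsampled density stack computed directly at the sampled pixels.

    Nearest-neighbour downsampling of a dense density map just evaluates the
    map at sampled pixel centers, so computing densities only there is exact
    and far cheaper on large sections.  Returns a stack whose grid is the
    downsampled grid (pass ``downsample_factor=None`` downstream).
    """
    tissue = np.asarray(tissue, bool)
    ii = _nn_indices(tissue.shape[0], downsample_factor)
    jj = _nn_indices(tissue.shape[1], downsample_factor)
    if ii.size < 4 or jj.size < 4:
        raise ValueError("downsampled output smaller than 4 x 4")
    centers = np.array([(r, c) for r in ii for c in jj])
    out_shape = (ii.size, jj.size)
    maps = {}
    for stain in STAIN_ORDER:
        mode = "percent_area" if stain == "necrosis" else "count"
        vals = density_at(masks[stain], centers, mode=mode,
                          window_um=window_um, pixel_size_um=pixel_size_um)
        maps[stain] = vals.reshape(out_shape)
    return StainDensityStack(maps=maps, tissue=tissue[np.ix_(ii, jj)],
                             pixel_size_um=pixel_size_um / downsample_factor,
                             window_um=window_um)


def label_habitats_histology(
    means,
    vessel_threshold: float = defaults.HV_VESSEL_THRESHOLD,
    nuclei_threshold: float = defaults.HC_NUCLEI_THRESHOLD,
) -> list[str] | str:
    """HV/LV x HC/LC labels from cluster mean vessel and nuclei densities.

    Accepts a single {'vessels':..., 'nuclei':...} mapping or a sequence of
    them.  Strict inequalities; boundary values label low.
    """
    single = isinstance(means, dict)
    items = [means] if single else list(means)
    labels = []
    for m in items:
        hv = m["vessels"] > vessel_threshold
        hc = m["nuclei"] > nuclei_threshold
        labels.append(f"{'HV' if hv else 'LV'}-{'HC' if hc else 'LC'}")
    return labels[0] if single else labels


def discover_histology_habitats(
    stacks: dict,
    downsample_factor: float | None = 0.01,
    k: int | None = None,
    k_range=defaults.K_RANGE,
    n_refs: int = defaults.GAP_N_REFS,
    selection: str = "1se",
    random_state: int | None = None,
    max_pooled_pixels: int | None = None,
) -> tuple[HabitatModel, dict, pd.DataFrame]:
    """Pooled clustering of stain-density pixels into histological habitats.

    ``stacks`` maps tumor id -> StainDensityStack (already downsampled when
    ``downsample_factor`` is None).  Tumors missing any of the four density
    maps are excluded with a log entry.  Returns the fitted model, per-tumor
    habitat label maps (0 = non-tissue), and a percent-tumor-area table.
    """
    usable = {}
    for tumor, stack in stacks.items():
        missing = [s for s in STAIN_ORDER if s not in stack.maps]
        if missing:
            log.warning("tumor %s excluded: missing stain map(s) %s", tumor, missing)
            continue
        usable[tumor] = (downsample_density(stack, downsample_factor)
                         if downsample_factor is not None else stack)
    if not usable:
        raise ValueError("no tumor has all four stain-density maps")

    feats, prov = [], []
    for tumor, stack in usable.items():
        sel = stack.tissue
        X = np.column_stack([stack.maps[s][sel] for s in STAIN_ORDER])
        feats.append(X)
        prov.extend((tumor, i) for i in np.flatnonzero(sel.ravel()))
    X = np.vstack(feats)
    rng = np.random.default_rng(random_state)
    keep = np.arange(X.shape[0])
    if max_pooled_pixels is not None and X.shape[0] > max_pooled_pixels:
        keep = np.sort(rng.choice(X.shape[0], size=max_pooled_pixels, replace=False))
    means = X[keep].mean(axis=0)
    sds = X[keep].std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise ValueError("constant stain-density feature: scaling undefined")
    Z = (X - means) / sds

    clusterer = HabitatClusterer(k=k, k_range=k_range, n_refs=n_refs,
                                 selection=selection,
                                 random_state=int(rng.integers(2**31 - 1)))
    clusterer.fit(Z[keep])
    labels = np.empty(X.shape[0], dtype=int)
    labels[keep] = clusterer.labels_
    rest = np.setdiff1d(np.arange(X.shape[0]), keep, assume_unique=True)
    if rest.size:
        labels[rest] = clusterer.predict(Z[rest])

    centroids = clusterer.centroids_ * sds + means
    names = label_habitats_histology(
        [dict(zip(STAIN_ORDER, row)) for row in centroids])
    model = HabitatModel(
        k=clusterer.k_, centroids_z=clusterer.centroids_, centroids=centroids,
        feature_names=STAIN_ORDER, scaling_means=means, scaling_sds=sds,
        habitat_labels=tuple(names), linkage=clusterer.linkage_,
        gap=clusterer.gap_)

    maps_out, comp_rows = {}, []
    offset = 0
    for tumor, stack in usable.items():
        n = int(stack.tissue.sum())
        lab_img = np.zeros(stack.tissue.shape, dtype=np.int16)
        lab_img[stack.tissue] = labels[offset: offset + n] + 1
        offset += n
        maps_out[tumor] = lab_img
        pct = percent_area(lab_img)
        for cluster, p in pct.items():
            comp_rows.append({"tumor": tumor, "cluster": cluster,
                              "habitat": names[cluster - 1], "percent": p})
    return model, maps_out, pd.DataFrame(comp_rows)


def percent_area(label_image: np.ndarray) -> dict[int, float]:
    """Percent tumor area per cluster id (>0) of a label image."""
    from .composition import percent_tumor_volume

    return percent_tumor_volume(label_image)
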