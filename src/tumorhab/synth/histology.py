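"""Synthetic stained-section generator coupled to a habitat geometry slice.

Stain-positive objects (nuclei, microvessels, Ki-67+ nuclei) are placed by
per-habitat hard-core point processes whose *retained* intensity matches the
target counts per 150 um x 150 um unit: a Matern-II thinning of a Poisson
proposal, with the proposal intensity solved from the thinning identity

    lambda_retained = (1 - exp(-lambda_prop * pi * d^2)) / (pi * d^2).

The hard core keeps objects disjoint under 8-connected component counting,
so brute-force window counts reproduce the table densities; at realistic
nuclear density a plain Poisson process would merge components and
undercount.  Objects are compact seeds (nuclei/Ki-67 radius 1.5 um, vessels
4 um) rather than full-size nuclei for the same reason.  Necrosis is a
smooth random field thresholded per habitat at the quantile giving the
target percent area.  Each section also gets brightfield-style renderings
(H&E RGB; bright-positive single-channel CD31/Ki-67 images) for exercising
the segmentation ops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .. import defaults
from .tables import HabitatParameterTable, STAIN_PARAMS

__all__ = ["SyntheticSection", "simulate_histology", "sample_density_features"]

UNIT_AREA_UM2 = defaults.DENSITY_WINDOW_UM ** 2  # 150 um x 150 um

OBJECT_RADIUS_UM = {"nuclei": 1.5, "ki67": 1.5, "vessels": 4.0}
HARD_CORE_UM = {"nuclei": 4.0, "ki67": 4.0}

# Reference rendering palette (RGB, uint8).
COLOR_BACKGROUND = np.array([245, 245, 245], dtype=float)
COLOR_EOSIN = np.array([228, 130, 155], dtype=float)
COLOR_NECROSIS = np.array([242, 190, 200], dtype=float)
COLOR_NUCLEUS = np.array([62, 48, 136], dtype=float)


@dataclass
class SyntheticSection:
    """Stain-positive masks, habitat truth, and renderings for one section."""

    masks: dict[str, np.ndarray]           # bool, keys = STAIN_PARAMS
    habitat_labels: np.ndarray             # int, 0 = background
    pixel_size_um: float
    hne_rgb: np.ndarray | None = None      # uint8 HxWx3
    cd31_channel: np.ndarray | None = None  # uint8, bright = positive
    ki67_channel: np.ndarray | None = None

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.habitat_labels > 0


def _hardcore_points(region_mask, intensity_per_um2, min_dist_um, pixel_size_um, rng):
    """Matern-II hard-core point sample over a pixel mask.

    Returns float pixel coordinates (n, 2).  The Poisson proposal intensity
    is compensated so the retained intensity equals ``intensity_per_um2``.
    """
    if intensity_per_um2 <= 0:
        return np.empty((0, 2))
    area_um2 = float(region_mask.sum()) * pixel_size_um ** 2
    if area_um2 == 0:
        return np.empty((0, 2))
    disc = np.pi * min_dist_um ** 2
    x = intensity_per_um2 * disc
    if x >= 0.999:
        raise ValueError("target density infeasible for the hard-core distance")
    lam_prop = -np.log(1.0 - x) / disc
    n = rng.poisson(lam_prop * area_um2)
    if n == 0:
        return np.empty((0, 2))
    pix = np.argwhere(region_mask)
    idx = rng.integers(0, pix.shape[0], size=n)
    pts = pix[idx] + rng.random((n, 2))
    marks = rng.random(n)
    tree = cKDTree(pts * pixel_size_um)
    pairs = tree.query_pairs(min_dist_um, output_type="ndarray")
    keep = np.ones(n, dtype=bool)
    if pairs.size:
        # Matern II: a point dies if any *proposal* point with a smaller mark
        # lies within d (whether or not that point is itself retained).
        older = marks[pairs[:, 0]] < marks[pairs[:, 1]]
        keep[np.where(older, pairs[:, 1], pairs[:, 0])] = False
    return pts[keep]


def _grid_points(region_mask, intensity_per_um2, pixel_size_um, rng,
                 jitter: float = 0.35):
    """Jittered-grid point sample: quasi-regular spacing at the target density.

    Microvessels are laid out on a square grid of spacing 1/sqrt(intensity)
    with uniform jitter (+-``jitter`` cell widths), emulating the
    Krogh-cylinder regularity of capillary spacing set by oxygen diffusion
    distance; window counts are then strongly under-dispersed relative to
    Poisson, as for real vascular beds.
    """
    if intensity_per_um2 <= 0 or not region_mask.any():
        return np.empty((0, 2))
    spacing_px = 1.0 / (np.sqrt(intensity_per_um2) * pixel_size_um)
    h, w = region_mask.shape
    off = rng.random(2) * spacing_px
    gi = np.arange(off[0], h, spacing_px)
    gj = np.arange(off[1], w, spacing_px)
    pts = np.stack(np.meshgrid(gi, gj, indexing="ij"), axis=-1).reshape(-1, 2)
    pts = pts + rng.uniform(-jitter, jitter, pts.shape) * spacing_px
    ii = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    jj = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    inside = region_mask[ii, jj] & (pts[:, 0] >= 0) & (pts[:, 0] < h) \
        & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    return pts[inside]


def _stamp_discs(shape, points_px, radius_px):
    mask = np.zeros(shape, dtype=bool)
    if points_px.shape[0] == 0:
        return mask
    r = max(int(np.floor(radius_px)), 0)
    ii = np.round(points_px[:, 0]).astype(int)
    jj = np.round(points_px[:, 1]).astype(int)
    inside = (ii >= 0) & (ii < shape[0]) & (jj >= 0) & (jj < shape[1])
    ii, jj = ii[inside], jj[inside]
    if r == 0:
        mask[ii, jj] = True
        return mask
    di, dj = np.mgrid[-r: r + 1, -r: r + 1]
    disc = (di ** 2 + dj ** 2) <= radius_px ** 2
    oi, oj = di[disc], dj[disc]
    pi = (ii[:, None] + oi[None, :]).clip(0, shape[0] - 1)
    pj = (jj[:, None] + oj[None, :]).clip(0, shape[1] - 1)
    mask[pi.ravel(), pj.ravel()] = True
    return mask


def _necrosis_field(habitat_labels, targets_pct, pixel_size_um, rng):
    """Smooth blobs whose per-habitat area fraction hits the target percent."""
    shape = habitat_labels.shape
    noise = rng.standard_normal(shape)
    # Fine (~8 um) eosinophilic speckle: necrotic habitats are a textured
    # mix of debris and ghost cells at cellular scale, so a 150 um window
    # averages many patches and its percent-area tracks the habitat mean.
    sigma = max(8.0 / pixel_size_um, 1.0)
    noise = ndimage.gaussian_filter(noise, sigma=sigma)
    mask = np.zeros(shape, dtype=bool)
    for h, pct in targets_pct.items():
        sel = habitat_labels == h
        if not sel.any() or pct <= 0:
            continue
        frac = min(pct / 100.0, 1.0)
        thr = np.quantile(noise[sel], 1.0 - frac)
        mask[sel] = noise[sel] >= thr
    return mask


def _upsample_labels(geometry_slice, voxel_size_mm, pixel_size_um):
    """Nearest-neighbour habitat labels on the histology pixel grid."""
    vox_um = (voxel_size_mm[0] * 1000.0, voxel_size_mm[1] * 1000.0)
    out_shape = (
        max(int(round(geometry_slice.shape[0] * vox_um[0] / pixel_size_um)), 1),
        max(int(round(geometry_slice.shape[1] * vox_um[1] / pixel_size_um)), 1),
    )
    ii = np.minimum((np.arange(out_shape[0]) + 0.5) * pixel_size_um / vox_um[0],
                    geometry_slice.shape[0] - 1).astype(int)
    jj = np.minimum((np.arange(out_shape[1]) + 0.5) * pixel_size_um / vox_um[1],
                    geometry_slice.shape[1] - 1).astype(int)
    return geometry_slice[np.ix_(ii, jj)]


def simulate_histology(
    geometry_slice: np.ndarray,
    table: HabitatParameterTable,
    pixel_size_um: float = defaults.HISTOLOGY_PIXEL_UM,
    seed: int | None = None,
    voxel_size_mm=defaults.VOXEL_SIZE_MM,
    render: bool = True,
) -> SyntheticSection:
    """Simulate stain-positive masks (and renderings) for one tumor section.

    ``geometry_slice`` is a 2-D integer habitat label image on the MRI voxel
    grid; it is resampled to the histology pixel grid.  Densities come from
    ``table.histology`` (counts or percent-area per 150 um x 150 um unit).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    geometry_slice = np.asarray(geometry_slice)
    ids = sorted(set(np.unique(geometry_slice)) - {0})
    for h in ids:
        if h not in table.histology:
            raise ValueError(f"histology table missing habitat {h}")
        for key in STAIN_PARAMS:
            if key not in table.histology[h]:
                raise ValueError(f"histology table missing stain {key!r}")
    rng = np.random.default_rng(seed)
    labels = _upsample_labels(geometry_slice, voxel_size_mm, pixel_size_um)
    shape = labels.shape

    masks = {}
    for stain in ("nuclei", "ki67", "vessels"):
        pts_all = []
        for h in ids:
            lam = table.histology[h][stain] / UNIT_AREA_UM2
            if stain == "vessels":
                pts = _grid_points(labels == h, lam, pixel_size_um, rng)
            else:
                pts = _hardcore_points(labels == h, lam, HARD_CORE_UM[stain],
                                       pixel_size_um, rng)
            pts_all.append(pts)
        pts_all = np.vstack(pts_all) if pts_all else np.empty((0, 2))
        radius_px = OBJECT_RADIUS_UM[stain] / pixel_size_um
        masks[stain] = _stamp_discs(shape, pts_all, radius_px)
    masks["necrosis"] = _necrosis_field(
        labels, {h: table.histology[h]["necrosis"] for h in ids},
        pixel_size_um, rng)

    section = SyntheticSection(masks=masks, habitat_labels=labels,
                               pixel_size_um=pixel_size_um)
    if render:
        tissue = labels > 0
        rgb = np.broadcast_to(COLOR_BACKGROUND, shape + (3,)).copy()
        rgb[tissue] = COLOR_EOSIN
        rgb[masks["necrosis"] & tissue] = COLOR_NECROSIS
        rgb[masks["nuclei"]] = COLOR_NUCLEUS
        rgb += rng.normal(0, 3.0, rgb.shape)
        section.hne_rgb = np.clip(rgb, 0, 255).astype(np.uint8)
        for stain, attr in (("vessels", "cd31_channel"), ("ki67", "ki67_channel")):
            chan = np.full(shape, 25.0)
            chan[tissue] = 60.0
            chan[masks[stain]] = 210.0
            chan += rng.normal(0, 4.0, shape)
            setattr(section, attr, np.clip(chan, 0, 255).astype(np.uint8))
    return section


def sample_density_features(
    geometry_slice: np.ndarray,
    table: HabitatParameterTable,
    n_pixels: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw stain-density feature vectors at random tissue pixels of a slice.

    Reduced-scale counterpart of running ``simulate_histology`` followed by
    the density-map pipeline: window counts are Poisson draws around the
    habitat's table density and necrosis percent-area is a clipped normal.
    Shares the habitat geometry with the MRI side, which is what couples the
    two modalities.  Returns (features[n, 4] in STAIN_PARAMS order,
    habitat_ids[n]).
    """
    rng = np.random.default_rng(seed)
    tissue = np.argwhere(geometry_slice > 0)
    if tissue.shape[0] == 0:
        raise ValueError("geometry slice contains no tumor pixels")
    idx = rng.integers(0, tissue.shape[0], size=n_pixels)
    habs = geometry_slice[tuple(tissue[idx].T)]
    feats = np.zeros((n_pixels, len(STAIN_PARAMS)))
    for h in np.unique(habs):
        sel = habs == h
        dens = table.histology[int(h)]
        for j, stain in enumerate(STAIN_PARAMS):
            if stain == "necrosis":
                vals = rng.normal(dens[stain], 0.25 * dens[stain] + 1.0, sel.sum())
                feats[sel, j] = np.clip(vals, 0.0, 100.0)
            else:
                feats[sel, j] = rng.poisson(dens[stain], sel.sum())
    return feats, habs.astype(int)
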