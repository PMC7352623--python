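"""Habitat discovery: pooled feature scaling, Ward clustering, gap-statistic
cluster-number selection, and physiological labelling.

Voxel feature vectors (Ktrans, ve, kep, ADC) are pooled across tumors and
timepoints, z-scored per feature over the pooled cohort, and clustered with
agglomerative Ward linkage under Euclidean distance.  The number of
clusters is chosen with the Tibshirani gap statistic against uniform
references drawn over the per-feature bounding box.  Cluster centroids,
mapped back to original units, are labelled high/low vascularity (Ktrans,
kep) and cellularity (ADC, ve) by fixed thresholds.

`HabitatClusterer` is a scikit-learn estimator (fit / fit_predict /
predict) so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from . import defaults
from .qmri.maps import PARAM_NAMES, ParameterMapSet

__all__ = [
    "FeatureTable",
    "GapResult",
    "HabitatClusterer",
    "HabitatModel",
    "pool_and_scale",
    "agglomerative_cluster",
    "gap_statistic",
    "label_habitats_mri",
    "map_labels_to_volumes",
    "discover_mri_habitats",
]

PROVENANCE_COLS = ("tumor", "timepoint", "voxel_index")


@dataclass
class FeatureTable:
    """Pooled voxel features with provenance and per-column scaling."""

    frame: pd.DataFrame                 # provenance + raw feature columns
    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    shapes: dict = field(default_factory=dict)  # (tumor, timepoint) -> volume shape

    @property
    def X(self) -> np.ndarray:
        """Z-scored feature matrix (n_voxels, n_features)."""
        raw = self.frame[list(self.feature_names)].to_numpy(dtype=float)
        return (raw - self.means) / self.sds

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def unscale(self, centroids_z: np.ndarray) -> np.ndarray:
        return centroids_z * self.sds + self.means


def pool_and_scale(parameter_sets: list[ParameterMapSet],
                   feature_names=PARAM_NAMES) -> FeatureTable:
    """Pool valid voxels of all scans into one z-scored feature table.

    Only voxels valid in all four parameters contribute.  Raises when fewer
    than two voxels remain or a feature has zero pooled variance.
    """
    rows = []
    shapes = {}
    for ps in parameter_sets:
        valid = ps.valid_all
        idx = np.flatnonzero(valid.ravel())
        if idx.size == 0:
            continue
        tumor = ps.provenance.get("tumor", "?")
        tp = ps.provenance.get("timepoint", 0)
        shapes[(tumor, tp)] = ps.shape
        rec = {
            "tumor": np.full(idx.size, tumor, dtype=object),
            "timepoint": np.full(idx.size, tp),
            "voxel_index": idx,
        }
        for p in feature_names:
            rec[p] = ps.maps[p].ravel()[idx]
        rows.append(pd.DataFrame(rec))
    if not rows:
        raise ValueError("no valid voxels to pool")
    frame = pd.concat(rows, ignore_index=True)
    if len(frame) < 2:
        raise ValueError("pooled table needs at least two voxels for scaling")
    raw = frame[list(feature_names)].to_numpy(dtype=float)
    if np.any(~np.isfinite(raw)):
        raise ValueError("pooled features contain non-finite values")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = [feature_names[i] for i in bad]
        raise ValueError(f"constant feature column(s) {names}: scaling undefined")
    return FeatureTable(frame=frame, feature_names=tuple(feature_names),
                        means=means, sds=sds, shapes=shapes)


def agglomerative_cluster(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward/Euclidean agglomerative clustering cut at ``k`` clusters.

    Returns ``(labels in 1..k, linkage matrix)``; deterministic given input
    order.
    """
    X = np.asarray(X, dtype=float)
    if k < 1 or k > X.shape[0]:
        raise ValueError("k must satisfy 1 <= k <= n_rows")
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust"), Z


def _within_dispersion(X, labels):
    """Pooled within-cluster sum of squared distances to centroids."""
    w = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


@dataclass
class GapResult:
    ks: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    log_w: np.ndarray
    k_one_se: int
    k_argmax: int

    def selected(self, rule: str = "1se") -> int:
        return self.k_one_se if rule == "1se" else self.k_argmax


def gap_statistic(
    X: np.ndarray,
    k_range=defaults.K_RANGE,
    n_refs: int = defaults.GAP_N_REFS,
    seed: int | None = None,
    linkage_matrix: np.ndarray | None = None,
) -> GapResult:
    """Tibshirani gap statistic over Ward clusterings.

    Gap(k) = E*[log W_k] - log W_k against ``n_refs`` uniform references
    drawn over the per-feature bounding box of ``X``.  The one-standard-
    error selection is the smallest k with Gap(k) >= Gap(k+1) - s(k+1)
    (falling back to the argmax when the rule never fires); the plain
    argmax is also reported.
    """
    X = np.asarray(X, dtype=float)
    ks = np.arange(k_range[0], k_range[1] + 1)
    if X.shape[0] < ks.max():
        raise ValueError("need at least max(k_range) rows")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all rows identical")
    rng = np.random.default_rng(seed)

    def log_w_curve(data, Z=None):
        if Z is None:
            Z = linkage(data, method="ward")
        out = np.empty(ks.shape[0])
        for i, k in enumerate(ks):
            lab = fcluster(Z, t=int(k), criterion="maxclust")
            out[i] = np.log(max(_within_dispersion(data, lab), 1e-300))
        return out

    log_w = log_w_curve(X, linkage_matrix)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_log_w = np.empty((n_refs, ks.shape[0]))
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_log_w[b] = log_w_curve(ref)
    gap = ref_log_w.mean(axis=0) - log_w
    sd = ref_log_w.std(axis=0, ddof=0)
    s_k = sd * np.sqrt(1.0 + 1.0 / n_refs)

    k_argmax = int(ks[np.argmax(gap)])
    k_one_se = k_argmax
    for i in range(ks.shape[0] - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            k_one_se = int(ks[i])
            break
    return GapResult(ks=ks, gap=gap, s_k=s_k, log_w=log_w,
                     k_one_se=k_one_se, k_argmax=k_argmax)


def label_habitats_mri(
    centroids: np.ndarray,
    feature_names=PARAM_NAMES,
    ktrans_threshold: float = defaults.HV_KTRANS_THRESHOLD,
    kep_threshold: float = defaults.HV_KEP_THRESHOLD,
    adc_threshold: float = defaults.HC_ADC_THRESHOLD,
    ve_threshold: float = defaults.HC_VE_THRESHOLD,
) -> list[str]:
    """Physiological labels for cluster centroids in original units.

    Vascularity: HV iff mean Ktrans > 0.1 /min OR mean kep > 0.5 /min
    (strict).  Cellularity: HC iff mean ADC < 1e-3 mm^2/s OR mean ve < 0.3;
    when the two cellularity indicators disagree, ve decides (low-ADC cores
    with near-unity ve are necrotic, not cell-dense).  Boundary equality
    falls on the low side.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    cols = {name: i for i, name in enumerate(feature_names)}
    labels = []
    for row in centroids:
        hv = row[cols["ktrans"]] > ktrans_threshold or row[cols["kep"]] > kep_threshold
        adc_hc = row[cols["adc"]] < adc_threshold
        ve_hc = row[cols["ve"]] < ve_threshold
        hc = ve_hc if adc_hc != ve_hc else adc_hc
        labels.append(f"{'HV' if hv else 'LV'}-{'HC' if hc else 'LC'}")
    return labels


class HabitatClusterer(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering with gap-statistic model selection.

    Parameters
    ----------
    k : int or None
        Number of clusters; when None it is selected by the gap statistic
        over ``k_range``.
    k_range : (int, int)
        Inclusive search range for the gap statistic.
    n_refs : int
        Uniform reference draws for the gap statistic.
    selection : {"1se", "argmax"}
        Gap selection rule.
    subsample_cap : int
        Above this row count a seeded subsample is clustered and remaining
        rows are assigned to the nearest centroid.
    random_state : int or None

    Attributes
    ----------
    k_ : selected number of clusters
    labels_ : cluster labels (0..k-1) of the training rows
    centroids_ : cluster centroids in feature space (z-space when the input
        was z-scored)
    linkage_ : scipy linkage matrix of the (sub)sampled rows
    gap_ : GapResult or None
    """

    def __init__(self, k=None, k_range=defaults.K_RANGE,
                 n_refs=defaults.GAP_N_REFS, selection="1se",
                 subsample_cap=50_000, gap_subsample=None, random_state=None):
        self.k = k
        self.k_range = k_range
        self.n_refs = n_refs
        self.selection = selection
        self.subsample_cap = subsample_cap
        self.gap_subsample = gap_subsample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least two rows")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        if n > self.subsample_cap:
            core_idx = rng.choice(n, size=self.subsample_cap, replace=False)
            core_idx.sort()
        else:
            core_idx = np.arange(n)
        core = X[core_idx]

        Z = linkage(core, method="ward")
        self.linkage_ = Z
        if self.k is None:
            if self.gap_subsample is not None and core.shape[0] > self.gap_subsample:
                sel_idx = rng.choice(core.shape[0], size=self.gap_subsample,
                                     replace=False)
                gap = gap_statistic(core[sel_idx], self.k_range, self.n_refs,
                                    seed=rng.integers(2**31 - 1))
            else:
                gap = gap_statistic(core, self.k_range, self.n_refs,
                                    seed=rng.integers(2**31 - 1), linkage_matrix=Z)
            self.gap_ = gap
            self.k_ = gap.selected(self.selection)
        else:
            if self.k > core.shape[0]:
                raise ValueError("k exceeds number of rows")
            self.gap_ = None
            self.k_ = int(self.k)
        core_labels = fcluster(Z, t=self.k_, criterion="maxclust") - 1
        self.centroids_ = np.vstack(
            [core[core_labels == c].mean(axis=0) for c in range(self.k_)])
        labels = np.empty(n, dtype=int)
        labels[core_idx] = core_labels
        rest = np.setdiff1d(np.arange(n), core_idx, assume_unique=True)
        if rest.size:
            labels[rest] = self._nearest(X[rest])
        self.labels_ = labels
        self.n_features_in_ = X.shape[1]
        return self

    def _nearest(self, X):
        d = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        X = np.asarray(X, dtype=float)
        return self._nearest(X)


@dataclass
class HabitatModel:
    """Fitted habitat model: centroids, scaling, dendrogram, labels."""

    k: int
    centroids_z: np.ndarray
    centroids: np.ndarray           # original units
    feature_names: tuple[str, ...]
    scaling_means: np.ndarray
    scaling_sds: np.ndarray
    habitat_labels: tuple[str, ...]  # per-cluster physiological label
    linkage: np.ndarray | None = None
    gap: GapResult | None = None

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "feature_names": list(self.feature_names),
            "centroids_z": self.centroids_z.tolist(),
            "centroids": self.centroids.tolist(),
            "scaling_means": self.scaling_means.tolist(),
            "scaling_sds": self.scaling_sds.tolist(),
            "habitat_labels": list(self.habitat_labels),
        }


def map_labels_to_volumes(table: FeatureTable, labels: np.ndarray) -> dict:
    """Scatter pooled cluster labels back to per-scan voxel volumes.

    Returns {(tumor, timepoint): int volume} with cluster c stored as c+1
    and 0 marking background/unassigned (removed) voxels.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_rows:
        raise ValueError("labels do not match the feature table")
    out = {}
    frame = table.frame
    for (tumor, tp), shape in table.shapes.items():
        sel = (frame["tumor"] == tumor) & (frame["timepoint"] == tp)
        vol = np.zeros(int(np.prod(shape)), dtype=np.int16)
        vol[frame.loc[sel, "voxel_index"].to_numpy()] = labels[sel.to_numpy()] + 1
        out[(tumor, tp)] = vol.reshape(shape)
    return out


def discover_mri_habitats(
    parameter_sets: list[ParameterMapSet],
    k: int | None = None,
    k_range=defaults.K_RANGE,
    n_refs: int = defaults.GAP_N_REFS,
    selection: str = "1se",
    random_state: int | None = None,
) -> tuple[HabitatModel, dict]:
    """End-to-end discovery: pool -> scale -> cluster -> label -> map back."""
    table = pool_and_scale(parameter_sets)
    clusterer = HabitatClusterer(k=k, k_range=k_range, n_refs=n_refs,
                                 selection=selection, random_state=random_state)
    clusterer.fit(table.X)
    centroids = table.unscale(clusterer.centroids_)
    names = label_habitats_mri(centroids, table.feature_names)
    model = HabitatModel(
        k=clusterer.k_,
        centroids_z=clusterer.centroids_,
        centroids=centroids,
        feature_names=table.feature_names,
        scaling_means=table.means,
        scaling_sds=table.sds,
        habitat_labels=tuple(names),
        linkage=clusterer.linkage_,
        gap=clusterer.gap_,
    )
    volumes = map_labels_to_volumes(table, clusterer.labels_)
    return model, volumes
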