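"""PCA projection and hierarchical spike classification.

Waveforms are projected onto the first two principal components and
clustered agglomeratively (centroid linkage, Euclidean distance).  The
partition is chosen by a dispersion-vs-separation criterion: scanning cut
levels from the maximum cluster count downward, the first partition whose
clusters are pairwise separated — the dispersions of two clusters summed
stay below the distance between their centroids, i.e. their bounding
spheres are disjoint — is returned.  Small clusters (including
singletons, which take part in clustering but are excluded only at the
end) are then rejected, and clusters whose mean waveform is below a
peak-to-peak floor are flagged as collections of false-positive noise
detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .detect import SpikeEvent, WaveformMatrix
from .recording import Recording


@dataclass
class SortingConfig:
    n_components: int = 2
    max_clusters: int = 7
    min_cluster_size: int = 10
    noise_pp_uv: float = 30.0
    dispersion: str = "radius"  # "radius" (max member distance) or "rms"
    separation: str = "spheres"  # "spheres": D_i + D_j < |Cm_i - Cm_j|; "one_sided": D_i < |Cm_i - Cm_j|

    def __post_init__(self) -> None:
        if min(self.n_components, self.max_clusters, self.min_cluster_size) < 1:
            raise ValueError("n_components, max_clusters, min_cluster_size must be >= 1")
        if self.noise_pp_uv <= 0:
            raise ValueError("noise_pp_uv must be positive")
        if self.dispersion not in ("radius", "rms"):
            raise ValueError("dispersion must be 'radius' or 'rms'")
        if self.separation not in ("spheres", "one_sided"):
            raise ValueError("separation must be 'spheres' or 'one_sided'")


@dataclass
class PCAModel:
    """Principal components of the waveform matrix and the 2-D scores."""

    components: np.ndarray  # (n_components, c), orthonormal rows
    mean_waveform: np.ndarray  # (c,)
    scores: np.ndarray  # (N, n_components)
    explained_variance: np.ndarray  # (n_components,)


def fit_pca(waveforms: WaveformMatrix | np.ndarray, n_components: int = 2) -> PCAModel:
    """Mean-centered PCA of the aligned waveforms.

    Components are ordered by explained variance; each component's
    largest-|loading| element is made positive so signs are reproducible.
    """
    X = waveforms.waveforms if isinstance(waveforms, WaveformMatrix) else np.asarray(waveforms, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 waveforms")
    n_components = min(n_components, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    return PCAModel(
        components=comps,
        mean_waveform=pca.mean_,
        scores=scores,
        explained_variance=pca.explained_variance_,
    )


def build_tree(scores: np.ndarray) -> np.ndarray:
    """Agglomerative merge tree over the PC scores.

    Centroid linkage with Euclidean distance: at each step the two clusters
    with the nearest centroids are merged, from N singletons up to one
    cluster.  Returns the (N-1, 4) linkage matrix; a single observation
    yields an empty tree.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 2:
        return np.empty((0, 4))
    return hierarchy.linkage(scores, method="centroid", metric="euclidean")


def _cluster_stats(
    scores: np.ndarray, labels: np.ndarray, dispersion: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster (ids, sizes, centroids, dispersions) in PC space."""
    ids = np.unique(labels)
    centroids = np.array([scores[labels == i].mean(axis=0) for i in ids])
    sizes = np.array([(labels == i).sum() for i in ids])
    disp = []
    for i, cm in zip(ids, centroids):
        d = np.linalg.norm(scores[labels == i] - cm, axis=1)
        disp.append(d.max() if dispersion == "radius" else np.sqrt(np.mean(d**2)))
    return ids, sizes, centroids, np.array(disp)


def separation_holds(
    centroids: np.ndarray, dispersions: np.ndarray, mode: str = "spheres"
) -> bool:
    """Dispersion-vs-centroid-distance criterion for a partition.

    ``"spheres"`` (default): for every cluster pair the summed dispersions
    are strictly smaller than the centroid distance, i.e. the clusters'
    bounding spheres are disjoint.  ``"one_sided"``: each cluster's own
    dispersion alone must stay below its distance to every other centroid.
    Vacuously true for a single cluster; a singleton has dispersion 0.
    """
    m = centroids.shape[0]
    for i in range(m):
        for j in range(i + 1, m):
            dist = np.linalg.norm(centroids[i] - centroids[j])
            if mode == "spheres":
                if not (dispersions[i] + dispersions[j] < dist):
                    return False
            else:
                if not (dispersions[i] < dist and dispersions[j] < dist):
                    return False
    return True


@dataclass
class ClusterModel:
    """A chosen partition of the waveforms with per-cluster statistics."""

    tree: np.ndarray  # linkage matrix
    labels: np.ndarray  # (N,) cluster label per waveform, 1-based
    cluster_ids: np.ndarray
    sizes: np.ndarray
    centroids: np.ndarray  # PC-space centers of mass
    dispersions: np.ndarray
    accepted: np.ndarray  # per-cluster flag (set by prune_clusters)
    is_noise: np.ndarray  # per-cluster flag (set by flag_noise_clusters)
    mean_waveforms: np.ndarray | None = None  # (M, c), set when flagged

    @property
    def n_clusters(self) -> int:
        return self.cluster_ids.size

    @property
    def n_singletons(self) -> int:
        return int(np.sum(self.sizes == 1))

    def cluster_of(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)

    def summary(self) -> dict:
        cent = self.centroids
        pair = {
            f"{int(a)}-{int(b)}": float(np.linalg.norm(cent[i] - cent[j]))
            for i, a in enumerate(self.cluster_ids)
            for j, b in enumerate(self.cluster_ids)
            if i < j
        }
        return {
            "n_clusters": int(self.n_clusters),
            "n_singletons": int(self.n_singletons),
            "sizes": {int(c): int(s) for c, s in zip(self.cluster_ids, self.sizes)},
            "dispersions": {
                int(c): float(d) for c, d in zip(self.cluster_ids, self.dispersions)
            },
            "centroid_distances": pair,
            "accepted": {int(c): bool(a) for c, a in zip(self.cluster_ids, self.accepted)},
            "is_noise": {int(c): bool(z) for c, z in zip(self.cluster_ids, self.is_noise)},
        }


def select_partition(
    tree: np.ndarray, scores: np.ndarray, config: SortingConfig | None = None
) -> ClusterModel:
    """Cut the tree at the largest admissible cluster count.

    Cut levels M = min(max_clusters, N) down to 2 are examined; the first
    partition whose clusters all satisfy :func:`separation_holds` is
    returned (favoring resolution).  If none qualifies, everything is one
    cluster.  Singletons are legitimate clusters here; they are only
    rejected later by :func:`prune_clusters`.
    """
    config = config or SortingConfig()
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    chosen = np.ones(n, dtype=int)
    if n > 1:
        for m in range(min(config.max_clusters, n), 1, -1):
            labels = hierarchy.fcluster(tree, t=m, criterion="maxclust")
            if np.unique(labels).size != m:
                continue
            _, _, cent, disp = _cluster_stats(scores, labels, config.dispersion)
            if separation_holds(cent, disp, config.separation):
                chosen = labels
                break
    ids, sizes, cent, disp = _cluster_stats(scores, chosen, config.dispersion)
    return ClusterModel(
        tree=tree,
        labels=chosen,
        cluster_ids=ids,
        sizes=sizes,
        centroids=cent,
        dispersions=disp,
        accepted=np.ones(ids.size, dtype=bool),
        is_noise=np.zeros(ids.size, dtype=bool),
    )


def prune_clusters(model: ClusterModel, config: SortingConfig | None = None) -> ClusterModel:
    """Reject clusters below the minimum size (singletons included).

    Rejected clusters keep their statistics but are marked not accepted;
    their waveforms count as unassigned.  No re-merging is attempted.
    """
    config = config or SortingConfig()
    model.accepted = model.sizes >= config.min_cluster_size
    return model


def flag_noise_clusters(
    model: ClusterModel,
    waveforms: WaveformMatrix | np.ndarray,
    config: SortingConfig | None = None,
) -> ClusterModel:
    """Flag accepted clusters whose mean waveform is a noise-level blip.

    A cluster with mean-waveform peak-to-peak amplitude strictly below
    ``noise_pp_uv`` gathers false-positive detections; it is kept but
    reported separately.
    """
    config = config or SortingConfig()
    X = waveforms.waveforms if isinstance(waveforms, WaveformMatrix) else np.asarray(waveforms, dtype=float)
    means = np.array([X[model.labels == cid].mean(axis=0) for cid in model.cluster_ids])
    pp = means.max(axis=1) - means.min(axis=1)
    model.mean_waveforms = means
    model.is_noise = model.accepted & (pp < config.noise_pp_uv)
    return model


def sort_waveforms(
    waveforms: WaveformMatrix, config: SortingConfig | None = None
) -> tuple[PCAModel, ClusterModel]:
    """Full classification: PCA, tree, cut selection, pruning, noise flags."""
    config = config or SortingConfig()
    pca = fit_pca(waveforms, config.n_components)
    tree = build_tree(pca.scores)
    model = select_partition(tree, pca.scores, config)
    model = prune_clusters(model, config)
    model = flag_noise_clusters(model, waveforms, config)
    return pca, model


def reconstruct_signal(
    model: ClusterModel,
    waveforms: WaveformMatrix,
    trace_len: int,
    include_noise_clusters: bool = False,
) -> Recording:
    """Rebuild the trace from classified spikes.

    Each event of an accepted (optionally non-noise) cluster contributes
    its cluster's mean waveform at the event's aligned position; the rest
    of the trace is zero.
    """
    if model.mean_waveforms is None:
        raise ValueError("run flag_noise_clusters first (cluster means missing)")
    out = np.zeros(trace_len)
    offset = waveforms.alignment_offset
    keep = {
        int(cid)
        for cid, acc, noi in zip(model.cluster_ids, model.accepted, model.is_noise)
        if acc and (include_noise_clusters or not noi)
    }
    mean_of = {
        int(cid): model.mean_waveforms[i] for i, cid in enumerate(model.cluster_ids)
    }
    for ev, lab in zip(waveforms.events, model.labels):
        if int(lab) not in keep:
            continue
        start = ev.peak_index - offset
        stop = start + waveforms.n_samples
        if start < 0 or stop > trace_len:
            continue
        out[start:stop] += mean_of[int(lab)]
    return Recording(out, waveforms.fs_hz, channel_id="reconstruction")


def labels_to_frame(model: ClusterModel, waveforms: WaveformMatrix) -> pd.DataFrame:
    acc = {int(c): bool(a) for c, a in zip(model.cluster_ids, model.accepted)}
    noi = {int(c): bool(z) for c, z in zip(model.cluster_ids, model.is_noise)}
    return pd.DataFrame(
        {
            "event_index": [e.peak_index for e in waveforms.events],
            "cluster_id": model.labels.astype(int),
            "accepted": [acc[int(l)] for l in model.labels],
            "is_noise": [noi[int(l)] for l in model.labels],
        }
    )
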