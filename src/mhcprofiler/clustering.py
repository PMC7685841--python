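"""Consensus clustering of the subtype x MHC-gene probability matrix.

Three algorithms (Ward hierarchical, k-means, PAM) are run over a range of
cluster counts; a battery of 12 validity indices with fixed orientations is
rank-aggregated to choose the optimal K; the three assignments at that K are
aligned by Hungarian matching and combined by majority vote; the resulting
clusters are ordered by mean MHC probability and labeled
MHC-low / MHC-intermediate / MHC-high.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("hierarchical", "kmeans", "pam")

#: index name -> True if higher is better
INDEX_ORIENTATION = {
    "silhouette": True,
    "calinski_harabasz": True,
    "davies_bouldin": False,
    "dunn": True,
    "connectivity": False,
    "c_index": False,
    "wss": False,
    "bss_wss": True,
    "gap": True,
    "pbm": True,
    "xie_beni": False,
    "separation_gap": True,
}

MHC_CLASS_NAMES = ("MHC-low", "MHC-intermediate", "MHC-high")


@dataclass
class ClusteringResult:
    selected_k: int
    assignments: dict[tuple[str, int], np.ndarray]   # (algorithm, K) -> labels
    validity: pd.DataFrame                           # algorithm, K, index, score, rank
    consensus: pd.Series                             # row id -> cluster (0..K-1)
    cluster_labels: dict[int, str]                   # cluster -> MHC class name
    cluster_means: pd.Series                         # cluster -> mean MHC probability

    @property
    def classes(self) -> pd.Series:
        """MHC class per row."""
        return self.consensus.map(self.cluster_labels).rename("mhc_class")


# ---------------------------------------------------------------------------
# algorithms
# ---------------------------------------------------------------------------

def _pam(x: np.ndarray, k: int, seed: int, max_swap: int = 200) -> np.ndarray:
    """Partitioning around medoids: greedy BUILD then SWAP on Euclidean distance."""
    d = cdist(x, x)
    n = x.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - d[:, c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best = cost(medoids)
    for _ in range(max_swap):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                c = cost(cand)
                if c < best - 1e-12:
                    medoids, best, improved = cand, c, True
        if not improved:
            break
    return np.argmin(d[:, medoids], axis=1)


def run_algorithms(
    matrix: pd.DataFrame,
    k_range: range = range(2, 6),
    seed: int = 0,
) -> tuple[dict[tuple[str, int], np.ndarray], pd.DataFrame]:
    """Cluster the rows of ``matrix`` with every algorithm at every K.

    Rows with missing values are dropped with a warning. Returns the
    assignment map and the (possibly reduced) matrix actually clustered.
    """
    complete = matrix.dropna(axis=0)
    if len(complete) < len(matrix):
        warnings.warn(f"{len(matrix) - len(complete)} rows with missing values dropped "
                      "before clustering")
    n = len(complete)
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"K range {ks} outside 2..{n - 1}")
    x = complete.to_numpy(dtype=float)
    z = linkage(x, method="ward")
    out: dict[tuple[str, int], np.ndarray] = {}
    for k in ks:
        out[("hierarchical", k)] = fcluster(z, t=k, criterion="maxclust") - 1
        km = KMeans(n_clusters=k, n_init=25, random_state=seed % (2**31))
        out[("kmeans", k)] = km.fit_predict(x)
        out[("pam", k)] = _pam(x, k, seed)
    return out, complete


# ---------------------------------------------------------------------------
# validity indices
# ---------------------------------------------------------------------------

def _wss(x: np.ndarray, labels: np.ndarray) -> float:
    return float(sum(
        ((x[labels == c] - x[labels == c].mean(axis=0)) ** 2).sum()
        for c in np.unique(labels)
    ))


def validity_indices(
    matrix: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_gap_refs: int = 20,
    n_neighbors: int = 10,
) -> dict[str, float]:
    """The fixed 12-index validity battery (orientations in INDEX_ORIENTATION).

    Indices undefined for a partition (e.g. singleton clusters) are returned
    as NaN and treated as worst-rank during aggregation.
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n = x.shape[0]
    clusters = np.unique(labels)
    k = clusters.size
    if k < 2:
        raise ValueError("need at least 2 non-empty clusters")
    dmat = squareform(pdist(x))
    if dmat.max() == 0:
        raise ValueError("all points identical; validity indices undefined")
    sizes = np.array([(labels == c).sum() for c in clusters])
    scores: dict[str, float] = {name: np.nan for name in INDEX_ORIENTATION}

    singleton = (sizes < 2).any()
    try:
        scores["silhouette"] = float(silhouette_score(x, labels))
        scores["calinski_harabasz"] = float(calinski_harabasz_score(x, labels))
        scores["davies_bouldin"] = float(davies_bouldin_score(x, labels))
    except ValueError:
        pass

    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    within_d = dmat[same & off]
    between_d = dmat[~same]
    if between_d.size and within_d.size:
        diam = max(
            dmat[np.ix_(labels == c, labels == c)].max() for c in clusters
        )
        if diam > 0:
            scores["dunn"] = float(between_d.min() / diam)
        # C-index over within-cluster pairs
        npairs = within_d.size // 2
        dsorted = np.sort(dmat[off & (np.arange(n)[:, None] < np.arange(n)[None, :])])
        s = within_d.sum() / 2
        smin = dsorted[:npairs].sum()
        smax = dsorted[-npairs:].sum()
        if smax > smin:
            scores["c_index"] = float((s - smin) / (smax - smin))
        scores["separation_gap"] = float(between_d.mean() - within_d.mean())
    elif between_d.size:
        scores["separation_gap"] = float(between_d.mean())

    # connectivity with n_neighbors nearest neighbours
    nn = np.argsort(dmat + np.eye(n) * (dmat.max() + 1), axis=1)[:, :min(n_neighbors, n - 1)]
    penalty = 1.0 / (np.arange(nn.shape[1]) + 1)
    scores["connectivity"] = float(
        sum(penalty[j] for i in range(n) for j in range(nn.shape[1])
            if labels[nn[i, j]] != labels[i])
    )

    wss = _wss(x, labels)
    scores["wss"] = wss
    centroid = x.mean(axis=0)
    tss = float(((x - centroid) ** 2).sum())
    bss = tss - wss
    if wss > 0:
        scores["bss_wss"] = bss / wss

    # gap statistic: reference draws uniform in the bounding box, partitioned
    # by k-means at the same K
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    if wss > 0:
        ref_logw = []
        for _ in range(n_gap_refs):
            xr = rng.uniform(lo, hi, size=x.shape)
            km = KMeans(n_clusters=k, n_init=4,
                        random_state=int(rng.integers(2**31)))
            ref_logw.append(np.log(max(_wss(xr, km.fit_predict(xr)), 1e-12)))
        scores["gap"] = float(np.mean(ref_logw) - np.log(wss))

    centroids = np.stack([x[labels == c].mean(axis=0) for c in clusters])
    inter = pdist(centroids)
    if inter.size and inter.min() > 0:
        e1 = np.linalg.norm(x - centroid, axis=1).sum()
        ek = sum(
            np.linalg.norm(x[labels == c] - centroids[i], axis=1).sum()
            for i, c in enumerate(clusters)
        )
        if ek > 0:
            scores["pbm"] = float(((e1 / ek) * inter.max() / k) ** 2)
        scores["xie_beni"] = float(
            sum(((x[labels == c] - centroids[i]) ** 2).sum()
                for i, c in enumerate(clusters)) / (n * inter.min() ** 2)
        )
    if singleton:
        logger.info("partition contains singleton clusters; some indices undefined")
    return scores


def aggregate_optimal_k(validity: pd.DataFrame) -> int:
    """Mean-rank aggregation over (algorithm, index) pairs; ties toward smaller K.

    ``validity`` must have columns algorithm, K, index, score. Within each
    (algorithm, index) series the K candidates are ranked best-to-worst
    respecting the index orientation; NaN scores get the worst rank.
    """
    ks = sorted(validity["K"].unique())
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate K")
    mean_ranks = pd.Series(0.0, index=ks)
    n_series = 0
    for (_, index), sub in validity.groupby(["algorithm", "index"]):
        scores = sub.set_index("K")["score"].reindex(ks)
        oriented = -scores if INDEX_ORIENTATION[index] else scores
        filled = oriented.fillna(np.inf)   # undefined -> worst
        if np.isinf(filled).all():
            continue
        r = pd.Series(rankdata(filled.to_numpy()), index=ks)
        mean_ranks += r
        n_series += 1
    if n_series == 0:
        return ks[0]
    mean_ranks /= n_series
    best = mean_ranks.min()
    return int(min(k for k in ks if mean_ranks[k] <= best + 1e-12))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _align(reference: np.ndarray, other: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``other`` to maximize agreement with ``reference`` (Hungarian)."""
    agreement = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            agreement[a, b] = np.sum((reference == a) & (other == b))
    rows, cols = linear_sum_assignment(-agreement)
    mapping = {int(b): int(a) for a, b in zip(rows, cols)}
    return np.array([mapping.get(int(b), int(b)) for b in other])


def consensus_assignments(
    assignments: dict[str, np.ndarray],
    matrix: pd.DataFrame | np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority-vote consensus after Hungarian label alignment to k-means.

    Rows with three-way disagreement are assigned to the cluster whose
    centroid (mean over unanimously assigned members) is nearest. Algorithms
    that produced fewer than ``k`` non-empty clusters are excluded from the
    vote with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    usable = {}
    for name, lab in assignments.items():
        if np.unique(lab).size < k:
            warnings.warn(f"algorithm {name!r} produced fewer than {k} clusters; "
                          "excluded from the consensus vote")
            continue
        usable[name] = np.asarray(lab)
    if not usable:
        raise ValueError("no usable algorithm assignments for consensus")
    ref_name = "kmeans" if "kmeans" in usable else sorted(usable)[0]
    ref = usable[ref_name]
    aligned = {ref_name: ref}
    for name, lab in usable.items():
        if name != ref_name:
            aligned[name] = _align(ref, lab, k)
    votes = np.stack(list(aligned.values()))       # algorithms x rows
    n = votes.shape[1]
    consensus = np.full(n, -1)
    for i in range(n):
        vals, counts = np.unique(votes[:, i], return_counts=True)
        if counts.max() > votes.shape[0] // 2:
            consensus[i] = vals[np.argmax(counts)]
    unresolved = consensus == -1
    if unresolved.any():
        unanimous = (votes == votes[0]).all(axis=0)
        centroids = []
        for c in range(k):
            members = unanimous & (votes[0] == c)
            if not members.any():
                members = ~unresolved & (consensus == c)
            centroids.append(
                x[members].mean(axis=0) if members.any() else np.full(x.shape[1], np.inf)
            )
        centroids = np.stack(centroids)
        for i in np.flatnonzero(unresolved):
            consensus[i] = int(np.argmin(np.linalg.norm(centroids - x[i], axis=1)))
    return consensus


def label_mhc_clusters(
    consensus: np.ndarray,
    matrix: pd.DataFrame,
) -> tuple[dict[int, str], pd.Series]:
    """Order clusters by mean MHC probability; name them when K = 3.

    Lowest mean -> MHC-low, middle -> MHC-intermediate, highest -> MHC-high;
    for other K the clusters are named cluster_1..cluster_K by ascending
    mean. Ties in the mean are broken by cluster size (larger = lower).
    """
    clusters = np.unique(consensus)
    k = clusters.size
    if k < 2:
        raise ValueError("labeling requires at least 2 clusters")
    x = matrix.to_numpy(dtype=float)
    means = {int(c): float(np.nanmean(x[consensus == c])) for c in clusters}
    sizes = {int(c): int((consensus == c).sum()) for c in clusters}
    order = sorted(means, key=lambda c: (means[c], -sizes[c]))
    if k == 3:
        names = dict(zip(order, MHC_CLASS_NAMES))
    else:
        names = {c: f"cluster_{i + 1}" for i, c in enumerate(order)}
    return names, pd.Series(means).rename("mean_mhc_probability")


def cluster_mhc(
    matrix: pd.DataFrame,
    k_range: range = range(2, 6),
    seed: int = 0,
) -> ClusteringResult:
    """Full clustering stage: algorithms, validity, K selection, consensus,
    MHC class labeling. ``matrix`` is subtypes x MHC-gene probabilities."""
    assignments, complete = run_algorithms(matrix, k_range, seed)
    records = []
    for (algo, k), labels in assignments.items():
        scores = validity_indices(complete, labels, seed=seed + k)
        for index, score in scores.items():
            records.append({"algorithm": algo, "K": k, "index": index, "score": score})
    validity = pd.DataFrame(records)
    ranks = []
    for (_, _), sub in validity.groupby(["algorithm", "index"]):
        oriented = np.where(
            [INDEX_ORIENTATION[i] for i in sub["index"]], -sub["score"], sub["score"]
        )
        ranks.append(pd.Series(
            rankdata(np.where(np.isfinite(oriented), oriented, np.inf)), index=sub.index
        ))
    validity["rank"] = pd.concat(ranks).sort_index()
    selected_k = aggregate_optimal_k(validity)
    at_k = {algo: assignments[(algo, selected_k)] for algo in ALGORITHMS}
    consensus = consensus_assignments(at_k, complete, selected_k)
    names, means = label_mhc_clusters(consensus, complete)
    return ClusteringResult(
        selected_k=selected_k,
        assignments=assignments,
        validity=validity,
        consensus=pd.Series(consensus, index=complete.index, name="cluster"),
        cluster_labels=names,
        cluster_means=means,
    )
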