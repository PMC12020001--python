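"""Unsupervised phase-diagram engine.

A phase diagram is built in two moves: project each (T*, p*) phase
point's descriptor to 3 dimensions with a manifold-learning method
(metric MDS, Isomap, spectral embedding or t-SNE), then group the
embedded points with a clustering algorithm (k-means, Ward
hierarchical on standardized coordinates, or DBSCAN).  Default
hyperparameters are the production settings: Isomap with 100
neighbors; t-SNE with perplexity 20, early exaggeration 12, learning
rate 100 and 3000 iterations; DBSCAN min_samples 80 in embedded space
and 60 for the diffusion peeling.

The "intelligent" pipeline first separates states of matter by
sequential DBSCAN peeling of the (normalized) diffusion coefficient -
each of three rounds marks the sparse/outlier points as the current
most-mobile group and keeps the dense remainder, yielding gas, two
liquid parts and a solid group - then sub-clusters the solid points on
the remaining 14 standardized properties.

Agreement between two label grids is the fraction of phase points
whose labels match after (a) user-supplied phase merges and (b) an
optimal one-to-one Hungarian assignment of predicted to reference
labels; unassigned (noise) points always count as disagreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.manifold import MDS, TSNE, Isomap, SpectralEmbedding

from .descriptors import FeatureTable, drop_feature, standardize

__all__ = [
    "Embedding", "PhaseLabelGrid", "MergeMap", "NOISE", "reduce",
    "cluster", "eps_from_kdistance", "eps_scan",
    "sequential_diffusion_dbscan",
    "fraction_of_agreement", "adf_phase_pipeline",
    "intelligent_phase_pipeline",
]

NOISE = -1

REDUCER_DEFAULTS = {
    "mds": {},
    "isomap": {"n_neighbors": 100},
    "spectral": {},
    "tsne": {"perplexity": 20.0, "early_exaggeration": 12.0,
             "learning_rate": 100.0, "max_iter": 3000},
}


@dataclass
class Embedding:
    coords: np.ndarray           # (points, 3)
    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("embedding must have exactly 3 components")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class PhaseLabelGrid:
    """Integer phase label per (T*, p*) point; NOISE marks unassigned."""

    phase_points: list
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if len(self.labels) != len(self.phase_points):
            raise ValueError("one label per phase point required")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != NOISE]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "T": [t for t, _ in self.phase_points],
            "p": [p for _, p in self.phase_points],
            "label": self.labels,
        }).to_csv(path, index=False)
        Path(str(path) + ".json").write_text(
            json.dumps(self.provenance, indent=1, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhaseLabelGrid":
        df = pd.read_csv(path)
        prov = {}
        side = Path(str(path) + ".json")
        if side.exists():
            prov = json.loads(side.read_text())
        return cls(list(zip(df["T"], df["p"])), df["label"].to_numpy(), prov)


@dataclass
class MergeMap:
    """Disjoint label groups treated as single phases during scoring."""

    groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for g in self.groups:
            g = set(g)
            if g & seen:
                raise ValueError("merge groups must be disjoint")
            seen |= g

    def apply(self, labels: np.ndarray) -> np.ndarray:
        out = labels.copy()
        for g in self.groups:
            g = sorted(g)
            rep = g[0]
            for lab in g[1:]:
                out[labels == lab] = rep
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "MergeMap":
        return cls(json.loads(Path(path).read_text())["groups"])


# -- dimensionality reduction ----------------------------------------

def reduce(table: FeatureTable, method: str, hyperparams: dict | None = None,
           seed: int = 0) -> Embedding:
    """3-component embedding of a feature table; deterministic per seed."""
    if table.n_points < 4:
        raise ValueError("need at least 4 phase points")
    hp = dict(REDUCER_DEFAULTS.get(method, {}))
    hp.update(hyperparams or {})
    x = table.features
    try:
        if method == "mds":
            model = MDS(n_components=3, random_state=seed,
                        normalized_stress=False, n_init=4, **hp)
        elif method == "isomap":
            hp["n_neighbors"] = min(hp.get("n_neighbors", 100),
                                    table.n_points - 1)
            model = Isomap(n_components=3, **hp)
        elif method == "spectral":
            model = SpectralEmbedding(n_components=3, random_state=seed,
                                      **hp)
        elif method == "tsne":
            hp["perplexity"] = min(hp.get("perplexity", 20.0),
                                   (table.n_points - 1) / 3.0)
            model = TSNE(n_components=3, random_state=seed, init="pca",
                         method="exact", **hp)
        else:
            raise ValueError(f"unknown reduction method {method!r}")
        coords = model.fit_transform(x)
    except ValueError:
        raise
    except Exception as exc:  # e.g. disconnected neighbor graphs
        raise RuntimeError(f"{method} embedding failed: {exc}") from exc
    return Embedding(coords, method, hp, seed)


# -- clustering -------------------------------------------------------

def cluster(embedding: Embedding, algo: str, n_clusters: int | None = None,
            eps: float | None = None, min_samples: int = 80,
            seed: int = 0, phase_points=None) -> PhaseLabelGrid:
    """Cluster an embedding into a phase-label grid."""
    x = embedding.coords
    if algo in ("kmeans", "ward"):
        if n_clusters is None:
            raise ValueError(f"{algo} requires n_clusters")
        if n_clusters > len(x):
            raise ValueError("more clusters than points")
    if algo == "kmeans":
        labels = KMeans(n_clusters=n_clusters, random_state=seed,
                        n_init=10).fit_predict(x)
    elif algo == "ward":
        # "normalized Euclidean": standardize coordinates before Ward
        labels = AgglomerativeClustering(
            n_clusters=n_clusters, linkage="ward").fit_predict(standardize(x))
    elif algo == "dbscan":
        if eps is None:
            eps = eps_scan(x, min_samples)
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(x)
    else:
        raise ValueError(f"unknown clustering algorithm {algo!r}")
    labels = _relabel_contiguous(labels)
    prov = {"algo": algo, "n_clusters": n_clusters, "eps": eps,
            "min_samples": min_samples, "seed": seed,
            "reduce_method": embedding.method,
            "reduce_hyperparams": embedding.hyperparams,
            "reduce_seed": embedding.seed}
    pts = phase_points if phase_points is not None \
        else [(float(i), 0.0) for i in range(len(x))]
    return PhaseLabelGrid(list(pts), labels, prov)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, int)
    out = np.full(len(labels), NOISE)
    next_id = 0
    for lab in sorted(set(labels[labels != NOISE])):
        out[labels == lab] = next_id
        next_id += 1
    return out


def eps_from_kdistance(data: np.ndarray, k: int,
                       smooth: int = 5) -> float:
    """DBSCAN eps from the elbow of the sorted k-distance curve.

    The distances to the k-th nearest neighbor are sorted in
    descending order; the elbow - where the curve "falls almost to
    zero and becomes flat" - is located at the maximum second
    difference after a moving-average smoothing.  Deterministic.
    """
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[0] == 1 and data.shape[1] > 1 and data.ndim == 2 \
            and data.shape[0] < data.shape[1]:
        data = data.T
    n = len(data)
    if n <= k:
        raise ValueError("need more points than k")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(data)
    dist, _ = nn.kneighbors(data)
    kdist = np.sort(dist[:, k])[::-1]
    if kdist[0] == kdist[-1]:
        return float(max(kdist[0], 1e-12))
    w = min(smooth, max(1, n // 10))
    kernel = np.ones(w) / w
    sm = np.convolve(kdist, kernel, mode="valid")
    if len(sm) < 3:
        return float(np.median(kdist))
    d2 = np.diff(sm, 2)
    # the extreme head/tail of the sorted curve produce spurious
    # curvature; keep the elbow search in the interior
    trim = max(1, len(d2) // 50)
    lo, hi = trim, max(trim + 1, len(d2) - trim)
    elbow = lo + int(np.argmax(d2[lo:hi])) + 1
    return float(max(sm[elbow], 1e-12))


def eps_scan(data: np.ndarray, min_samples: int,
             n_candidates: int = 24) -> float:
    """Automated DBSCAN eps choice for embedded-space clustering.

    DBSCAN in an embedded space is sensitive to eps, and no single
    elbow rule is reliable on t-SNE-style island geometries, so the
    neighbor count is fixed and the distance is scanned, keeping the
    choice where clustering is most successful - the largest number of
    clusters, and among ties the fewest unassigned points (largest eps
    breaks remaining ties).  Candidates span the observed k-distance
    range.  Deterministic.
    """
    data = np.asarray(data, float)
    k = min(min_samples, len(data) - 1)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(data)
    dist, _ = nn.kneighbors(data)
    kd = dist[:, k]
    lo = max(kd.min() * 0.5, 1e-12)
    hi = max(kd.max() * 1.2, lo * 1.01)
    best = None
    for eps in np.geomspace(lo, hi, n_candidates):
        labels = DBSCAN(eps=float(eps), min_samples=min_samples
                        ).fit_predict(data)
        n_cl = len(set(labels[labels != NOISE]))
        n_noise = int(np.sum(labels == NOISE))
        score = (n_cl, -n_noise, eps)
        if n_cl > 0 and (best is None or score > best[0]):
            best = (score, float(eps))
    if best is None:
        return float(np.median(kd))
    return best[1]


# -- sequential diffusion peeling -------------------------------------

def sequential_diffusion_dbscan(diffusion, phase_points=None,
                                min_pts: int = 60, n_rounds: int = 3,
                                ) -> PhaseLabelGrid:
    """Separate states of matter by peeling the diffusion distribution.

    Each round runs DBSCAN on the z-normalized remaining diffusion
    values (eps from the k-distance elbow); the points left outside
    any cluster form the current group - the most mobile, most
    scattered state - and are removed.  After ``n_rounds`` successful
    rounds four groups exist, ordered by descending mean diffusion:
    0 = gas, 1 = liquid-a, 2 = liquid-b, 3 = solid.  Rounds that peel
    nothing end the process early (fewer groups, warning flag).
    """
    d = np.asarray(diffusion, float).ravel()
    n = len(d)
    if phase_points is None:
        phase_points = [(float(i), 0.0) for i in range(n)]
    remaining = np.arange(n)
    groups: list[np.ndarray] = []
    warning = None
    for _ in range(n_rounds):
        if len(remaining) <= min_pts:
            warning = "too few points left to continue peeling"
            break
        x = d[remaining].reshape(-1, 1)
        sd = x.std()
        xn = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        try:
            eps = eps_from_kdistance(xn, k=min(min_pts, len(xn) - 1))
        except ValueError:
            warning = "k-distance undefined"
            break
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xn)
        peeled = remaining[labels == NOISE]
        if len(peeled) == 0 or len(peeled) == len(remaining):
            warning = "a peeling round found no outliers"
            break
        groups.append(peeled)
        remaining = remaining[labels != NOISE]
    groups.append(remaining)

    labels = np.empty(n, dtype=int)
    for gi, idx in enumerate(groups):
        labels[idx] = gi
    # enforce descending-diffusion ordering of the group ids
    order = np.argsort([-d[idx].mean() for idx in groups])
    remap = {int(old): rank for rank, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    prov = {"algo": "sequential_diffusion_dbscan", "min_pts": min_pts,
            "n_rounds": n_rounds, "n_groups": len(groups)}
    if warning:
        prov["warning"] = warning
    return PhaseLabelGrid(list(phase_points), labels, prov)


# -- agreement scoring ------------------------------------------------

def fraction_of_agreement(predicted: PhaseLabelGrid,
                          reference: PhaseLabelGrid,
                          merge: MergeMap | None = None,
                          merge_reference: MergeMap | None = None,
                          count_noise: bool = True) -> float:
    """Fraction of phase points with the correctly predicted phase.

    Cluster ids carry no meaning, so predicted labels are matched
    one-to-one to reference labels by the Hungarian assignment
    maximizing total agreement on the merged label sets.  Noise points
    never match; with ``count_noise=False`` they are dropped from the
    denominator as well.
    """
    if len(predicted.labels) != len(reference.labels) or any(
            tuple(np.round(a, 9)) != tuple(np.round(b, 9))
            for a, b in zip(np.asarray(predicted.phase_points, float),
                            np.asarray(reference.phase_points, float))):
        raise ValueError("phase-point grids differ")
    pred = (merge or MergeMap()).apply(predicted.labels)
    ref = (merge_reference if merge_reference is not None
           else (merge or MergeMap())).apply(reference.labels)

    ok = (pred != NOISE) & (ref != NOISE)
    total = len(pred) if count_noise else int(np.sum(ok))
    if total == 0:
        return 0.0
    p_ids = sorted(set(pred[ok]))
    r_ids = sorted(set(ref[ok]))
    cont = np.zeros((len(p_ids), len(r_ids)))
    for a, pa in enumerate(p_ids):
        for b, rb in enumerate(r_ids):
            cont[a, b] = np.sum((pred == pa) & (ref == rb))
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / total)


# -- pipelines --------------------------------------------------------

def adf_phase_pipeline(table: FeatureTable, reduce_method: str,
                       cluster_algo: str, n_clusters: int | None = None,
                       seed: int = 0, eps: float | None = None,
                       min_samples: int = 80) -> PhaseLabelGrid:
    """reduce -> cluster composition with full provenance."""
    emb = reduce(table, reduce_method, seed=seed)
    grid = cluster(emb, cluster_algo, n_clusters=n_clusters, eps=eps,
                   min_samples=min_samples, seed=seed,
                   phase_points=table.phase_points)
    grid.provenance["pipeline"] = "adf"
    grid.provenance["seed"] = seed
    return grid


def intelligent_phase_pipeline(table: FeatureTable, reduce_method: str,
                               cluster_algo: str,
                               n_clusters: int | None = None,
                               seed: int = 0, min_pts: int = 60,
                               min_samples: int = 80,
                               eps: float | None = None,
                               min_solid: int = 8) -> PhaseLabelGrid:
    """Two-stage phase diagram from the 15-quantity property table.

    Stage 1 peels gas/liquid-a/liquid-b/solid off the diffusion
    coefficient; stage 2 re-standardizes the solid subset on the other
    14 features, embeds it in 3D and clusters it into solid sub-phases.
    Labels 0..2 are the stage-1 fluid groups; solid sub-phases continue
    from 3.  Returns solids unsplit (with a warning) when the solid
    subset is smaller than ``min_solid``.
    """
    if "diffusion" not in table.feature_names:
        raise ValueError("property table must contain 'diffusion'")
    dif = table.raw[:, table.feature_names.index("diffusion")]
    stage1 = sequential_diffusion_dbscan(dif, table.phase_points,
                                         min_pts=min_pts)
    labels = stage1.labels.copy()
    solid_id = labels.max()
    solid_idx = np.where(labels == solid_id)[0]
    prov = {"pipeline": "intelligent", "stage1": stage1.provenance,
            "seed": seed}
    if len(solid_idx) < max(min_solid, 4):
        prov["warning"] = "solid subset too small to sub-cluster"
        return PhaseLabelGrid(list(table.phase_points), labels, prov)

    sub_raw = table.raw[solid_idx]
    sub = FeatureTable([table.phase_points[i] for i in solid_idx],
                       standardize(sub_raw), list(table.feature_names),
                       standardized=True, raw=sub_raw)
    sub = drop_feature(sub, "diffusion")
    emb = reduce(sub, reduce_method, seed=seed)
    sub_ms = min(min_samples, max(2, len(solid_idx) // 4))
    sub_grid = cluster(emb, cluster_algo, n_clusters=n_clusters, eps=eps,
                       min_samples=sub_ms, seed=seed,
                       phase_points=sub.phase_points)
    out = labels.copy()
    for local, gi in enumerate(solid_idx):
        lab = sub_grid.labels[local]
        out[gi] = NOISE if lab == NOISE else solid_id + lab
    prov["stage2"] = sub_grid.provenance
    return PhaseLabelGrid(list(table.phase_points), out, prov)
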