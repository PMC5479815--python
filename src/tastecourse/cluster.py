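"""Temporal archetype clustering and stage dendrograms.

K-means uses Lloyd's algorithm with uniform-random point initialization,
restarted ``n_starts`` times from a single seeded RNG stream; the restart
with the smallest within-cluster sum of squares wins.  Empty clusters are
re-seeded with the point currently farthest from its assigned center, so the
model always keeps exactly k clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .containers import StageMatrix, stage_day
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """K-means result over gene profiles.

    Cluster indices are 1-based (1..k).  ``archetype_labels`` maps the
    cluster index to an archetype name once :func:`label_archetypes` has run.
    """

    k: int
    assignments: pd.Series  # gene id -> cluster in 1..k
    centers: np.ndarray  # k x n_stages
    within_ss: float
    stages: list[str]
    seed: int
    n_starts: int
    max_iter: int
    archetype_labels: dict[int, str] = field(default_factory=dict)

    def genes_in(self, cluster: int) -> set:
        return set(self.assignments.index[self.assignments == cluster])

    def cluster_of_archetype(self, name: str) -> int:
        for c, lab in self.archetype_labels.items():
            if lab == name:
                return c
        raise InputError(f"no cluster labelled {name!r}")

    def sizes(self) -> dict[int, int]:
        return {c: int((self.assignments == c).sum()) for c in range(1, self.k + 1)}

    def to_tsv(self, path) -> None:
        df = self.assignments.rename("cluster").to_frame()
        if self.archetype_labels:
            df["archetype"] = [self.archetype_labels[c] for c in self.assignments]
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "within_ss": self.within_ss,
                    "centers": self.centers.tolist(),
                    "stages": self.stages,
                    "seed": self.seed,
                    "n_starts": self.n_starts,
                    "max_iter": self.max_iter,
                    "archetype_labels": {str(c): v for c, v in
                                         sorted(self.archetype_labels.items())},
                    "sizes": {str(c): v for c, v in self.sizes().items()},
                },
                fh, indent=2, sort_keys=True,
            )


def _assign(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return np.argmin(cdist(data, centers), axis=1)


def lloyd(data: np.ndarray, init_centers: np.ndarray,
          max_iter: int = 30000) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations from explicit initial centers.

    Returns (assignments 0-based, centers, within-cluster SS).  Deterministic
    given the inputs; empty clusters are re-seeded from the farthest point.
    """
    centers = init_centers.copy()
    k = centers.shape[0]
    assign = None
    for _ in range(max_iter):
        new_assign = _assign(data, centers)
        # re-seed empty clusters with the point farthest from its center
        for c in range(k):
            if not (new_assign == c).any():
                dists = np.linalg.norm(data - centers[new_assign], axis=1)
                far = int(np.argmax(dists))
                centers[c] = data[far]
                new_assign = _assign(data, centers)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            centers[c] = data[assign == c].mean(axis=0)
    wss = float(((data - centers[assign]) ** 2).sum())
    return assign, centers, wss


def kmeans_cluster(
    X: StageMatrix,
    k: int = 4,
    n_starts: int = 30,
    max_iter: int = 30000,
    seed: int = 0,
) -> ClusterModel:
    """Restarted K-means over normalized gene profiles.

    The best (lowest within-SS) of ``n_starts`` Lloyd runs is returned, so
    the result can only improve as ``n_starts`` grows for a fixed seed.
    """
    data = X.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise InputError("non-finite values in clustering input")
    n = data.shape[0]
    if k > n:
        raise InputError(f"k={k} exceeds number of genes ({n})")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_starts):
        init = data[rng.choice(n, size=k, replace=False)]
        assign, centers, wss = lloyd(data, init, max_iter=max_iter)
        if best is None or wss < best[0] - 1e-12:
            best = (wss, assign, centers)
    wss, assign, centers = best
    return ClusterModel(
        k=k,
        assignments=pd.Series(assign + 1, index=X.gene_ids, name="cluster"),
        centers=centers,
        within_ss=wss,
        stages=X.stages,
        seed=seed,
        n_starts=n_starts,
        max_iter=max_iter,
    )


def _shape_similarity(center: np.ndarray, template: np.ndarray) -> float:
    """Pearson correlation, with a distance fallback for flat profiles."""
    sc, st = center.std(), template.std()
    if sc > 1e-12 and st > 1e-12:
        return float(np.corrcoef(center, template)[0, 1])
    dist = float(np.linalg.norm(center - template))
    return 1.0 / (1.0 + dist)


def label_archetypes(model: ClusterModel, templates) -> ClusterModel:
    """Attach archetype names to clusters by maximum-similarity matching.

    ``templates`` is a sequence of :class:`~tastecourse.simulate.ArchetypeSpec`
    (one per cluster); each name is used exactly once (optimal bipartite
    assignment on shape similarity).
    """
    templates = list(templates)
    if len(templates) != model.k:
        raise InputError(f"need exactly {model.k} templates, got {len(templates)}")
    tmats = np.stack([t.template_array - t.template_array.mean() for t in templates])
    sim = np.empty((model.k, model.k))
    for i in range(model.k):
        for j in range(model.k):
            sim[i, j] = _shape_similarity(model.centers[i], tmats[j])
    rows, cols = linear_sum_assignment(-sim)
    model.archetype_labels = {int(r) + 1: templates[c].name
                              for r, c in zip(rows, cols)}
    return model


@dataclass
class StageDendrogram:
    """Agglomerative clustering of stage columns."""

    linkage: np.ndarray  # scipy linkage matrix over stages
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> list[set]:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return [
            {lab for lab, g in zip(self.labels, flat) if g == grp}
            for grp in sorted(set(flat))
        ]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
            dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def cluster_stages(
    X: StageMatrix,
    metric: str = "euclidean",
    method: str = "complete",
) -> StageDendrogram:
    """Hierarchically cluster stage columns of a log2(RPKM+1) matrix."""
    if X.values.shape[1] < 2:
        raise InputError("need at least 2 stage columns")
    cols = X.values.to_numpy(dtype=float).T
    Z = hierarchy.linkage(cols, method=method, metric=metric)
    return StageDendrogram(linkage=Z, labels=X.stages)


def two_branch_split(dend: StageDendrogram) -> tuple[set, set]:
    """The two root branches (2-cut), early branch first (by min day)."""
    groups = dend.cut(2)
    groups.sort(key=lambda g: min(stage_day(s) for s in g))
    return groups[0], groups[1]
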