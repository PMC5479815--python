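"""Cross-replicate cluster matching and consensus gene sets.

K-means cluster indices are arbitrary, so clusters of the two replicate
models are aligned before intersecting: by identical archetype label when
both models are labelled, otherwise by the minimum-total-distance bijection
between centroid sets (optimal assignment).  The "combined up" set is the
analogue of pooling the two rising clusters in both replicates: genes in
(late_rise u early_rise) of A that are also in the matched clusters of B.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .cluster import ClusterModel
from .errors import InputError

logger = logging.getLogger(__name__)

UP_ARCHETYPES = ("late_rise", "early_rise")


def _distance_mapping(model_a: ClusterModel, model_b: ClusterModel) -> dict[int, int]:
    D = cdist(model_a.centers, model_b.centers)
    rows, cols = linear_sum_assignment(D)
    return {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


def match_clusters(model_a: ClusterModel, model_b: ClusterModel) -> dict[int, int]:
    """Bijection cluster-of-A -> cluster-of-B.

    When both models carry archetype labels the label identity defines the
    mapping and any disagreement with the distance-optimal assignment is
    logged; otherwise the assignment-problem solution on centroid distances
    is used directly.
    """
    if model_a.k != model_b.k:
        raise InputError(f"models have different k ({model_a.k} vs {model_b.k})")
    dist_map = _distance_mapping(model_a, model_b)
    if model_a.archetype_labels and model_b.archetype_labels:
        by_label = {
            ca: model_b.cluster_of_archetype(lab)
            for ca, lab in model_a.archetype_labels.items()
        }
        if by_label != dist_map:
            logger.warning(
                "label-identity mapping %s disagrees with distance-optimal %s",
                by_label, dist_map,
            )
        return by_label
    return dist_map


@dataclass
class ConsensusResult:
    """Per-matched-cluster intersections and the combined rising set."""

    mapping: dict[int, int]
    shared_sets: dict[int, set]
    combined_up_set: set
    sizes: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mapping": {str(a): b for a, b in sorted(self.mapping.items())},
                    "sizes": self.sizes,
                },
                fh, indent=2, sort_keys=True,
            )

    def write_gene_lists(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for c, genes in self.shared_sets.items():
            with open(outdir / f"consensus_cluster_{c}.txt", "w") as fh:
                fh.write("\n".join(sorted(genes)) + "\n")
        with open(outdir / "consensus_combined_up.txt", "w") as fh:
            fh.write("\n".join(sorted(self.combined_up_set)) + "\n")


def _up_clusters(model: ClusterModel) -> list[int]:
    if model.archetype_labels:
        return [c for c, lab in model.archetype_labels.items()
                if lab in UP_ARCHETYPES]
    return [c for c in (1, 2) if c <= model.k]


def intersect_clusters(
    model_a: ClusterModel,
    model_b: ClusterModel,
    mapping: dict[int, int] | None = None,
) -> ConsensusResult:
    """Intersect corresponding clusters of the two replicate models."""
    if set(model_a.assignments.index) != set(model_b.assignments.index):
        raise InputError("models cover different gene universes")
    if mapping is None:
        mapping = match_clusters(model_a, model_b)
    if sorted(mapping) != list(range(1, model_a.k + 1)) or sorted(
            mapping.values()) != list(range(1, model_b.k + 1)):
        raise InputError("mapping is not a bijection over 1..k")

    shared = {
        c: model_a.genes_in(c) & model_b.genes_in(mapping[c])
        for c in range(1, model_a.k + 1)
    }
    up_a = set().union(*(model_a.genes_in(c) for c in _up_clusters(model_a)))
    up_b = set().union(*(model_b.genes_in(c) for c in _up_clusters(model_b)))
    combined = up_a & up_b

    sizes = {
        "per_cluster_A": {str(c): len(model_a.genes_in(c))
                          for c in range(1, model_a.k + 1)},
        "per_cluster_B": {str(c): len(model_b.genes_in(c))
                          for c in range(1, model_b.k + 1)},
        "shared": {str(c): len(g) for c, g in shared.items()},
        "combined_up": len(combined),
    }
    return ConsensusResult(mapping=dict(mapping), shared_sets=shared,
                           combined_up_set=combined, sizes=sizes)
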