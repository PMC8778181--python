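"""Behavioral-state induction: k-means over face trees under the lattice distance.

The nine behavioral states 0..8 are the nine head poses, obtained by
clustering the complete-frame trivial trees with k-means using the lattice
tree distance in the assignment step.  Clustering runs with 11 centroids —
one per head-pose sub-class, initialized at the midpoint trees of the 11
interval prototypes — and the three Front sub-class clusters are merged
into state 0 for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, StateError
from .face_tree import TrivialTree
from .lattice_metric import (
    MetricParams,
    TreeBank,
    pairwise_distance,
    tree_centroid,
)
from .pose_prototypes import SUBCLASS_LABELS, PrototypeSet, merged_pose

#: cluster index (canonical sub-class order) -> reported state 0..8
DEFAULT_MERGE = tuple(merged_pose(lab) for lab in SUBCLASS_LABELS)


@dataclass
class KMeansResult:
    """Raw clustering output before any state merging."""

    centroids: list[TrivialTree]
    assignments: np.ndarray
    objective_history: list[float]
    n_iter: int
    converged: bool


def kmeans_lattice(
    trees,
    init_centroids,
    params: MetricParams | None = None,
    max_iter: int = 300,
) -> KMeansResult:
    """k-means with lattice-distance assignment and mean-tree updates.

    Assignment ties break to the lowest cluster index; a cluster left empty
    keeps its previous centroid; iteration stops when assignments repeat.
    The centroid update is the per-coordinate arithmetic mean (classical
    k-means); a coordinate-median update would be the exact minimizer of
    the weighted-L1 objective but the mean is kept as the canonical choice
    (see docs/methods.md).
    """
    trees = list(trees)
    if not trees:
        raise InputError("cannot cluster an empty tree list")
    centroids = [TrivialTree(r=c.r.copy(), phi=c.phi.copy(), provenance=c.provenance)
                 for c in init_centroids]
    params = params or MetricParams.default()
    bank = TreeBank.from_trees(trees)
    prev = None
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dmat = pairwise_distance(bank, TreeBank.from_trees(centroids), params)
        assign = np.argmin(dmat, axis=1)  # first minimum: lowest index
        history.append(float(dmat[np.arange(len(trees)), assign].sum()))
        if prev is not None and np.array_equal(assign, prev):
            converged = True
            break
        prev = assign
        for j in range(len(centroids)):
            members = [trees[i] for i in np.nonzero(assign == j)[0]]
            if members:  # empty cluster keeps its previous centroid
                c = tree_centroid(members)
                c.provenance = centroids[j].provenance
                centroids[j] = c
    return KMeansResult(
        centroids=centroids,
        assignments=prev,
        objective_history=history,
        n_iter=it,
        converged=converged,
    )


@dataclass
class StateModel:
    """Fitted behavioral-state model: 11 labeled centroids, the merge map
    onto the 9 reported states, and the metric parameters used."""

    centroids: list[TrivialTree]
    merged_states: tuple[int, ...] = DEFAULT_MERGE
    params: MetricParams = field(default_factory=MetricParams.default)

    def __post_init__(self):
        if len(self.centroids) != len(self.merged_states):
            raise InputError("one merge entry is required per centroid")
        if set(self.merged_states) != set(range(9)):
            raise InputError("merge map must cover states 0..8")

    def cluster_counts_to_state_counts(self, cluster_counts) -> np.ndarray:
        """Aggregate per-cluster frame counts into the 9 reported states."""
        cluster_counts = np.asarray(cluster_counts)
        if cluster_counts.shape != (len(self.centroids),):
            raise InputError("one count per cluster is required")
        out = np.zeros(9, dtype=cluster_counts.dtype)
        for j, s in enumerate(self.merged_states):
            out[s] += cluster_counts[j]
        return out


def induce_states(
    trees,
    prototypes: PrototypeSet,
    params: MetricParams | None = None,
    max_iter: int = 300,
) -> tuple[StateModel, np.ndarray]:
    """Cluster complete-frame trees into the 9 states.

    Initializes the 11 centroids at the midpoint trees of the interval
    prototypes, runs :func:`kmeans_lattice`, and returns the fitted model
    together with the merged per-tree state labels.
    """
    params = params or MetricParams.default()
    init = [p.midpoint_tree() for p in prototypes.prototypes]
    res = kmeans_lattice(trees, init, params, max_iter=max_iter)
    model = StateModel(centroids=res.centroids, params=params)
    states = np.asarray(model.merged_states)[res.assignments]
    return model, states


def assign_states(trees, model: StateModel) -> np.ndarray:
    """Nearest-centroid cluster per tree, merged to reported states 0..8."""
    if model is None or not model.centroids:
        raise StateError("state model is not fitted")
    trees = list(trees)
    if not trees:
        return np.zeros(0, dtype=int)
    dmat = pairwise_distance(
        TreeBank.from_trees(trees), TreeBank.from_trees(model.centroids), model.params
    )
    clusters = np.argmin(dmat, axis=1)
    return np.asarray(model.merged_states)[clusters]
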