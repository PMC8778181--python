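"""Interval-tree head-pose prototypes and nearest-prototype classification.

Nine head poses are modeled — Front(0), UpperLeft(1), Up(2), UpperRight(3),
Right(4), LowerRight(5), Down(6), LowerLeft(7), Left(8) — with Front split
into three sub-classes (FrontLeft, FrontProper, FrontRight), giving 11
prototypes in all.  A prototype is the per-node min/max envelope of the
labeled training trees of its sub-class; a face is classified to the
prototype minimizing the lattice tree distance, and the three Front
sub-classes collapse to Front at reporting level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, InputError, LabelError
from .face_tree import TrivialTree
from .lattice_metric import (
    IntervalTree,
    MetricParams,
    TreeBank,
    pairwise_distance,
)

POSE_NAMES = (
    "Front",
    "UpperLeft",
    "Up",
    "UpperRight",
    "Right",
    "LowerRight",
    "Down",
    "LowerLeft",
    "Left",
)

#: the 11 sub-class labels in canonical prototype order
SUBCLASS_LABELS = (
    "FrontLeft",
    "FrontProper",
    "FrontRight",
    "UpperLeft",
    "Up",
    "UpperRight",
    "Right",
    "LowerRight",
    "Down",
    "LowerLeft",
    "Left",
)

FRONT_SUBCLASSES = SUBCLASS_LABELS[:3]


def merged_pose(subclass_label: str) -> int:
    """Map a sub-class label to its reported pose numeral 0..8."""
    if subclass_label in FRONT_SUBCLASSES:
        return 0
    try:
        return POSE_NAMES.index(subclass_label)
    except ValueError:
        raise LabelError(f"unknown pose label: {subclass_label!r}") from None


@dataclass(frozen=True)
class PoseLabel:
    """A reported pose numeral plus, for Front, the deciding sub-class."""

    value: int
    subclass: str | None = None

    @property
    def name(self) -> str:
        return POSE_NAMES[self.value]


@dataclass
class PrototypeSet:
    """The 11 labeled interval-tree prototypes, in canonical order."""

    prototypes: list[IntervalTree]

    def __post_init__(self):
        labels = [p.label for p in self.prototypes]
        if len(labels) != len(set(labels)):
            raise LabelError("prototype labels must be unique")
        order = {lab: i for i, lab in enumerate(SUBCLASS_LABELS)}
        unknown = [lab for lab in labels if lab not in order]
        if unknown:
            raise LabelError(f"unknown pose labels: {unknown}")
        self.prototypes = sorted(self.prototypes, key=lambda p: order[p.label])

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.prototypes]

    def to_list(self) -> list[dict]:
        return [p.to_dict() for p in self.prototypes]

    @classmethod
    def from_list(cls, items: list[dict]) -> "PrototypeSet":
        return cls([IntervalTree.from_dict(d) for d in items])


def induce_prototype(trees, label: str | None = None) -> IntervalTree:
    """Min/max envelope over trivial trees: per node, [min r, max r] and
    [min phi, max phi]."""
    trees = list(trees)
    if not trees:
        raise InputError("cannot induce a prototype from zero trees")
    provs = {t.provenance for t in trees if t.provenance is not None}
    if label is None:
        if len(provs) > 1:
            raise LabelError(f"mixed labels in prototype induction: {sorted(provs)}")
        label = provs.pop() if provs else None
    elif provs and provs != {label}:
        raise LabelError(f"trees labeled {sorted(provs)} do not match {label!r}")
    r = np.stack([t.r for t in trees])
    phi = np.stack([t.phi for t in trees])
    return IntervalTree(
        r_lo=r.min(axis=0),
        r_hi=r.max(axis=0),
        phi_lo=phi.min(axis=0),
        phi_hi=phi.max(axis=0),
        label=label,
    )


def build_prototype_set(trees, labels) -> PrototypeSet:
    """Induce one envelope prototype per sub-class label."""
    labels = list(labels)
    trees = list(trees)
    if len(trees) != len(labels):
        raise InputError("trees and labels differ in length")
    protos = []
    for lab in sorted(set(labels), key=SUBCLASS_LABELS.index):
        members = [t for t, l in zip(trees, labels) if l == lab]
        protos.append(induce_prototype(members, label=lab))
    return PrototypeSet(protos)


def classify(
    tree: TrivialTree, protos: PrototypeSet, params: MetricParams | None = None
) -> PoseLabel:
    """Nearest-prototype pose; ties break to the lowest prototype index."""
    return classify_batch([tree], protos, params)[0]


def classify_batch(trees, protos: PrototypeSet, params: MetricParams | None = None):
    """Classify many trees at once; returns a list of :class:`PoseLabel`."""
    if not protos.prototypes:
        raise InputError("empty prototype set")
    params = params or MetricParams.default()
    dmat = pairwise_distance(TreeBank.from_trees(trees), TreeBank.from_trees(protos.prototypes), params)
    idx = np.argmin(dmat, axis=1)  # argmin takes the first minimum: lowest index wins
    labels = protos.labels
    return [PoseLabel(value=merged_pose(labels[i]), subclass=labels[i]) for i in idx]


def cross_validate(
    trees,
    labels,
    params: MetricParams | None = None,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold accuracy of nearest-prototype classification.

    Prototypes are induced on each fold's training split only; accuracy is
    scored on the merged 9-pose labels.
    """
    trees = list(trees)
    labels = list(labels)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if len(set(labels)) < 2:
        raise ConfigurationError("cross-validation needs at least two classes")
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if folds > min(counts.values()):
        raise ConfigurationError(
            f"folds={folds} exceeds the smallest class size {min(counts.values())}"
        )
    params = params or MetricParams.default()
    y = np.asarray(labels)
    merged = np.array([merged_pose(l) for l in labels])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        protos = build_prototype_set([trees[i] for i in train_idx], y[train_idx])
        pred = classify_batch([trees[i] for i in test_idx], protos, params)
        accs.append(float(np.mean([p.value for p in pred] == merged[test_idx])))
    return float(np.mean(accs))


def confusion_matrix(trees, labels, protos: PrototypeSet, params=None) -> np.ndarray:
    """9x9 confusion over reported poses (Front sub-classes merged)."""
    pred = classify_batch(trees, protos, params)
    cm = np.zeros((9, 9), dtype=int)
    for lab, p in zip(labels, pred):
        cm[merged_pose(lab), p.value] += 1
    return cm
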