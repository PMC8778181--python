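"""Hierarchical polar-feature tree built from 68 facial landmarks.

A face is represented as a three-level tree anchored at the nose.  The root
is the nose axis (bridge-top to tip).  Eight *primary* nodes hang off the
root: the two eye centers (centroids of the eye contours, measured from the
nose top), the mouth center (centroid of the outer mouth contour, measured
from the nose tip) and the five lower-nose (nostril-line) points (from the
nose tip).  Fifty-one *secondary* nodes hang off the first three primaries:
the eye and brow contour points under each eye center, and the outer-mouth
and jaw contour points under the mouth center.

Every node stores the polar coordinates (r, phi) of the vector connecting
its parent's endpoint to its own point.  Lengths are divided by the nose
length and orientations are measured relative to the nose axis and wrapped
into [-pi, pi], which makes the representation invariant to uniform
scaling, rotation and translation of the input landmarks — and anonymous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InputError

N_LANDMARKS = 68
N_NODES = 59  # non-root feature nodes

# 68-point convention index spans
JAW = list(range(0, 17))
LEFT_BROW = list(range(17, 22))
RIGHT_BROW = list(range(22, 27))
NOSE_TOP = 27
NOSE_TIP = 30
NOSTRILS = list(range(31, 36))
LEFT_EYE = list(range(36, 42))
RIGHT_EYE = list(range(42, 48))
OUTER_MOUTH = list(range(48, 60))
INNER_MOUTH = list(range(60, 68))  # not part of the tree

PRIMARY_IDS = tuple(range(1, 9))
# children spans (inclusive) of the three non-leaf primaries
CHILD_SPANS = {1: (9, 19), 2: (20, 30), 3: (31, 59)}

#: parent node id for each node id 1..59
PARENT_ID = np.zeros(N_NODES + 1, dtype=int)
for _p, (_lo, _hi) in CHILD_SPANS.items():
    PARENT_ID[_lo : _hi + 1] = _p

#: raw landmark index feeding each secondary node id, in tree-id order
SECONDARY_LANDMARKS = LEFT_EYE + LEFT_BROW + RIGHT_EYE + RIGHT_BROW + OUTER_MOUTH + JAW
assert len(SECONDARY_LANDMARKS) == 51


def _wrap_angle(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [-pi, pi]."""
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class LandmarkSet:
    """An ordered set of 68 planar landmark coordinates, in pixels."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise InputError(f"expected {N_LANDMARKS} (x, y) points, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InputError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)


@dataclass
class TrivialTree:
    """A single face: 59 nodes with degenerate (point) polar coordinates.

    ``r[i]`` and ``phi[i]`` hold node id ``i + 1``; the root (node 0, the
    nose) carries no coordinates by convention.
    """

    r: np.ndarray
    phi: np.ndarray
    provenance: str | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.r.shape != (N_NODES,) or self.phi.shape != (N_NODES,):
            raise InputError("a face tree carries exactly 59 (r, phi) node pairs")

    def to_dict(self) -> dict:
        """JSON-ready mapping node_id -> {r, phi, parent}."""
        return {
            str(i + 1): {
                "r": float(self.r[i]),
                "phi": float(self.phi[i]),
                "parent": int(PARENT_ID[i + 1]),
            }
            for i in range(N_NODES)
        }

    @classmethod
    def from_dict(cls, d: dict, provenance: str | None = None) -> "TrivialTree":
        r = np.empty(N_NODES)
        phi = np.empty(N_NODES)
        for i in range(N_NODES):
            node = d[str(i + 1)]
            r[i] = node["r"]
            phi[i] = node["phi"]
        return cls(r=r, phi=phi, provenance=provenance)


@dataclass(frozen=True)
class PolarNode:
    """One tree node as an (id, r, phi, parent, level) record."""

    node_id: int
    r: float
    phi: float
    parent_id: int
    level: str


def nodes_of(tree: TrivialTree) -> list[PolarNode]:
    """Explode a tree into per-node records (root excluded)."""
    out = []
    for i in range(N_NODES):
        nid = i + 1
        level = "primary" if nid in PRIMARY_IDS else "secondary"
        out.append(PolarNode(nid, float(tree.r[i]), float(tree.phi[i]), int(PARENT_ID[nid]), level))
    return out


def centroid_point(points) -> np.ndarray:
    """Arithmetic mean (center of mass) of a nonempty list of planar points."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise InputError("centroid of an empty point list is undefined")
    return pts.reshape(-1, 2).mean(axis=0)


def build_face_tree(landmarks, provenance: str | None = None) -> TrivialTree:
    """Build the normalized 59-node polar-feature tree from 68 landmarks.

    Parameters
    ----------
    landmarks
        A :class:`LandmarkSet` or any (68, 2) array of (x, y) pixels.

    Returns
    -------
    TrivialTree
        Nose-normalized tree; all r are nondimensional (nose length = 1)
        and all phi are relative to the nose axis, in [-pi, pi].
    """
    if not isinstance(landmarks, LandmarkSet):
        landmarks = LandmarkSet(np.asarray(landmarks))
    pts = landmarks.points

    top = pts[NOSE_TOP]
    tip = pts[NOSE_TIP]
    nose = tip - top
    nose_len = float(np.hypot(*nose))
    if nose_len <= 0.0:
        raise DegenerateGeometryError("nose top and tip coincide; cannot normalize")
    nose_angle = float(np.arctan2(nose[1], nose[0]))

    left_eye_c = centroid_point(pts[LEFT_EYE])
    right_eye_c = centroid_point(pts[RIGHT_EYE])
    mouth_c = centroid_point(pts[OUTER_MOUTH])

    # primary vectors: eye centers from the nose top, mouth center and the
    # five nostril-line points from the nose tip
    primary_origin = np.array([top, top, tip, tip, tip, tip, tip, tip])
    primary_end = np.vstack([left_eye_c, right_eye_c, mouth_c, pts[NOSTRILS]])

    # secondary vectors originate at their primary parent's endpoint
    sec_origin = np.vstack(
        [
            np.tile(left_eye_c, (11, 1)),
            np.tile(right_eye_c, (11, 1)),
            np.tile(mouth_c, (29, 1)),
        ]
    )
    sec_end = pts[SECONDARY_LANDMARKS]

    vec = np.vstack([primary_end - primary_origin, sec_end - sec_origin])
    r = np.hypot(vec[:, 0], vec[:, 1]) / nose_len
    phi = _wrap_angle(np.arctan2(vec[:, 1], vec[:, 0]) - nose_angle)
    return TrivialTree(r=r, phi=phi, provenance=provenance)
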