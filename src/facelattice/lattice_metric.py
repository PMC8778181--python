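"""Parametric lattice distance between (trivial or interval) face trees.

Each tree node carries an interval per polar coordinate; a single face is a
*trivial* tree (all intervals degenerate) and a face granule — e.g. a
head-pose prototype — is an *interval* tree.  The distance between two
corresponding node intervals [a, b] and [c, e] is computed from a positive
valuation function v(x) = lambda * x and the dual-order map theta(x) = 1 - x:

    d([a,b], [c,e]) = [v(theta(a ^ c)) - v(theta(a v c))] + [v(b v e) - v(b ^ e)]

which for this choice of v and theta equals lambda * (|a - c| + |b - e|).
Branch distances combine a parent node's term with a weighted sum of its
children's terms, evaluated from the leaves up; the whole-tree distance sums
the eight primary branches separately for r and phi and combines the two
with the weights k_r and k_phi.  The root (nose) contributes zero because
both trees are nose-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError, StructuralError
from .face_tree import CHILD_SPANS, N_NODES, PRIMARY_IDS, TrivialTree, _wrap_angle

N_GENES = 126  # 59 + 59 node weights, 3 + 3 hierarchy weights, k_r, k_phi


@dataclass
class IntervalNode:
    """One interval-valued tree node: [a, b] for r and [c, d] for phi."""

    node_id: int
    r_interval: tuple[float, float]
    phi_interval: tuple[float, float]


@dataclass
class IntervalTree:
    """A face granule: 59 nodes with an interval per polar coordinate."""

    r_lo: np.ndarray
    r_hi: np.ndarray
    phi_lo: np.ndarray
    phi_hi: np.ndarray
    label: str | None = None

    def __post_init__(self):
        arrs = []
        for name in ("r_lo", "r_hi", "phi_lo", "phi_hi"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (N_NODES,):
                raise InputError(f"{name} must have shape ({N_NODES},)")
            setattr(self, name, a)
            arrs.append(a)
        if np.any(self.r_lo > self.r_hi) or np.any(self.phi_lo > self.phi_hi):
            raise InputError("interval lower bounds must not exceed upper bounds")

    @property
    def is_trivial(self) -> bool:
        return bool(np.all(self.r_lo == self.r_hi) and np.all(self.phi_lo == self.phi_hi))

    def midpoint_tree(self) -> TrivialTree:
        """The trivial tree at the per-node interval midpoints."""
        return TrivialTree(
            r=0.5 * (self.r_lo + self.r_hi),
            phi=0.5 * (self.phi_lo + self.phi_hi),
            provenance=self.label,
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "r_lo": self.r_lo.tolist(),
            "r_hi": self.r_hi.tolist(),
            "phi_lo": self.phi_lo.tolist(),
            "phi_hi": self.phi_hi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalTree":
        return cls(
            r_lo=np.asarray(d["r_lo"]),
            r_hi=np.asarray(d["r_hi"]),
            phi_lo=np.asarray(d["phi_lo"]),
            phi_hi=np.asarray(d["phi_hi"]),
            label=d.get("label"),
        )


def as_interval(tree: TrivialTree | IntervalTree) -> IntervalTree:
    """Promote a trivial tree to a degenerate interval tree (no copy needed)."""
    if isinstance(tree, IntervalTree):
        return tree
    if isinstance(tree, TrivialTree):
        return IntervalTree(
            r_lo=tree.r, r_hi=tree.r, phi_lo=tree.phi, phi_hi=tree.phi, label=tree.provenance
        )
    raise StructuralError(f"not a face tree: {type(tree).__name__}")


@dataclass
class MetricParams:
    """The 126 tunable weights of the tree distance.

    lambda_r / lambda_phi : per-node weights, one per node id 1..59.
    k_r123 / k_phi123     : hierarchy weights applied to the children of the
                            three non-leaf primaries (eye, eye, mouth).
    k_r / k_phi           : combiner weights for the two coordinate sums.
    The root combiner k_c is fixed to 1.
    """

    lambda_r: np.ndarray = field(default_factory=lambda: np.ones(N_NODES))
    lambda_phi: np.ndarray = field(default_factory=lambda: np.ones(N_NODES))
    k_r123: np.ndarray = field(default_factory=lambda: np.ones(3))
    k_phi123: np.ndarray = field(default_factory=lambda: np.ones(3))
    k_r: float = 1.0
    k_phi: float = 1.0

    def __post_init__(self):
        self.lambda_r = np.asarray(self.lambda_r, dtype=float)
        self.lambda_phi = np.asarray(self.lambda_phi, dtype=float)
        self.k_r123 = np.asarray(self.k_r123, dtype=float)
        self.k_phi123 = np.asarray(self.k_phi123, dtype=float)
        if self.lambda_r.shape != (N_NODES,) or self.lambda_phi.shape != (N_NODES,):
            raise ParameterError("lambda_r and lambda_phi must each carry 59 weights")
        if self.k_r123.shape != (3,) or self.k_phi123.shape != (3,):
            raise ParameterError("k_r123 and k_phi123 must each carry 3 weights")
        allw = np.concatenate(
            [self.lambda_r, self.lambda_phi, self.k_r123, self.k_phi123, [self.k_r, self.k_phi]]
        )
        if not np.all(np.isfinite(allw)) or np.any(allw < 0):
            raise ParameterError("all metric weights must be finite and nonnegative")

    @classmethod
    def default(cls) -> "MetricParams":
        """All weights 1: the plain (linear) lattice distance."""
        return cls()

    def node_weights(self, coord: str) -> np.ndarray:
        """Effective flat weight per node: 1 for primaries, k_j for the
        secondaries under primary j, times the per-node lambda."""
        lam = self.lambda_r if coord == "r" else self.lambda_phi
        k = self.k_r123 if coord == "r" else self.k_phi123
        w = np.ones(N_NODES)
        for j, pid in enumerate(sorted(CHILD_SPANS)):
            lo, hi = CHILD_SPANS[pid]
            w[lo - 1 : hi] = k[j]
        return w * lam


def interval_distance(x, y, lam: float = 1.0) -> float:
    """Lattice distance between two intervals under v(t) = lam*t, theta(t) = 1-t.

    Evaluates the valuation form term by term; algebraically equal to
    ``lam * (|a - c| + |b - e|)`` for x = [a, b], y = [c, e].
    """
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    a, b = float(x[0]), float(x[1])
    c, e = float(y[0]), float(y[1])
    if a > b or c > e:
        raise InputError("interval lower bounds must not exceed upper bounds")

    def v(t):
        return lam * t

    def theta(t):
        return 1.0 - t

    return (v(theta(min(a, c))) - v(theta(max(a, c)))) + (v(max(b, e)) - v(min(b, e)))


def _node_terms(ta: IntervalTree, tb: IntervalTree, lam: np.ndarray, coord: str) -> np.ndarray:
    """Vectorized per-node valuation-form distance for one coordinate."""
    if coord == "r":
        a, b, c, e = ta.r_lo, ta.r_hi, tb.r_lo, tb.r_hi
    else:
        a, b, c, e = ta.phi_lo, ta.phi_hi, tb.phi_lo, tb.phi_hi
    lower = (1.0 - np.minimum(a, c)) - (1.0 - np.maximum(a, c))
    upper = np.maximum(b, e) - np.minimum(b, e)
    return lam * (lower + upper)


def branch_distance(
    ta: TrivialTree | IntervalTree,
    tb: TrivialTree | IntervalTree,
    primary_id: int,
    params: MetricParams,
    coord: str,
) -> float:
    """Distance between the branches rooted at one primary node.

    The parent node's own interval distance plus k_child times the sum of
    its children's interval distances; leaf primaries (the five nostril
    points) contribute only their own term.
    """
    if primary_id not in PRIMARY_IDS:
        raise StructuralError(f"primary node ids are 1..8, got {primary_id}")
    if coord not in ("r", "phi"):
        raise InputError("coord must be 'r' or 'phi'")
    ta, tb = as_interval(ta), as_interval(tb)
    lam = params.lambda_r if coord == "r" else params.lambda_phi
    k = params.k_r123 if coord == "r" else params.k_phi123
    terms = _node_terms(ta, tb, lam, coord)
    d = float(terms[primary_id - 1])
    if primary_id in CHILD_SPANS:
        lo, hi = CHILD_SPANS[primary_id]
        d += float(k[primary_id - 1]) * float(terms[lo - 1 : hi].sum())
    return d


def tree_distance(
    ta: TrivialTree | IntervalTree,
    tb: TrivialTree | IntervalTree,
    params: MetricParams | None = None,
) -> float:
    """Whole-tree lattice distance: k_r * D_r + k_phi * D_phi.

    Each coordinate distance sums the eight primary-branch distances; the
    root contributes zero because both trees are nose-normalized.
    """
    params = params or MetricParams.default()
    total = 0.0
    for coord, kc in (("r", params.k_r), ("phi", params.k_phi)):
        d_coord = sum(branch_distance(ta, tb, pid, params, coord) for pid in PRIMARY_IDS)
        total += kc * d_coord
    return total


def tree_centroid(trees) -> TrivialTree:
    """Coordinate-wise mean of trivial trees; phi re-wrapped to [-pi, pi]."""
    trees = list(trees)
    if not trees:
        raise InputError("centroid of an empty tree list is undefined")
    r = np.mean([t.r for t in trees], axis=0)
    phi = _wrap_angle(np.mean([t.phi for t in trees], axis=0))
    return TrivialTree(r=r, phi=phi)


# ---------------------------------------------------------------------------
# batch evaluation used by classification, cross-validation and clustering
# ---------------------------------------------------------------------------


@dataclass
class TreeBank:
    """Stacked endpoint arrays for n trees, for vectorized distances."""

    r_lo: np.ndarray  # (n, 59)
    r_hi: np.ndarray
    phi_lo: np.ndarray
    phi_hi: np.ndarray

    def __len__(self) -> int:
        return self.r_lo.shape[0]

    @classmethod
    def from_trees(cls, trees) -> "TreeBank":
        ivs = [as_interval(t) for t in trees]
        if not ivs:
            raise InputError("empty tree collection")
        return cls(
            r_lo=np.stack([t.r_lo for t in ivs]),
            r_hi=np.stack([t.r_hi for t in ivs]),
            phi_lo=np.stack([t.phi_lo for t in ivs]),
            phi_hi=np.stack([t.phi_hi for t in ivs]),
        )


def pairwise_distance(a: TreeBank, b: TreeBank, params: MetricParams | None = None) -> np.ndarray:
    """(len(a), len(b)) matrix of tree distances.

    Uses the closed form lam * (|a - c| + |b - e|) per node with the flat
    hierarchy weights; identical to :func:`tree_distance` applied pairwise.
    """
    params = params or MetricParams.default()
    out = np.zeros((len(a), len(b)))
    for coord, kc in (("r", params.k_r), ("phi", params.k_phi)):
        w = params.node_weights(coord)
        if coord == "r":
            lo_a, hi_a, lo_b, hi_b = a.r_lo, a.r_hi, b.r_lo, b.r_hi
        else:
            lo_a, hi_a, lo_b, hi_b = a.phi_lo, a.phi_hi, b.phi_lo, b.phi_hi
        d = np.abs(lo_a[:, None, :] - lo_b[None, :, :]) + np.abs(
            hi_a[:, None, :] - hi_b[None, :, :]
        )
        out += kc * (d * w).sum(axis=2)
    return out
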