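"""K-means, BIRCH and affinity propagation with a uniform fit/assign contract.

All three algorithms operate on per-user feature vectors and expose the
internal state the rest of the pipeline (and its tests) reason about:

* K-means keeps its centroids and the sum of squared errors
  SSE = sum_i sum_{x in C_i} ||x - m_i||^2,
  minimised by alternating nearest-centroid assignment with centroid means.
* BIRCH summarises subclusters as cluster-feature (CF) triples
  (count, linear sum, squared sum); CFs are additive, leaves obey a radius
  threshold, and a global agglomerative pass merges leaf centroids.
* Affinity propagation exchanges damped responsibility/availability
  messages over a similarity matrix s(i,k) = -||x_i - x_k||^2 and elects
  exemplars from the criterion matrix C = R + A.

``assign_cluster`` maps a new feature vector to a cluster id for any of the
three fitted models (nearest centroid / nearest leaf's global label /
nearest exemplar's cluster; ties broken by lowest index).  An unconverged
affinity-propagation fit labels everything -1, and assignment then returns
the -1 sentinel as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

__all__ = [
    "CentroidModel",
    "CFTriple",
    "CFTreeModel",
    "APState",
    "kmeans_fit",
    "sse_curve",
    "birch_fit",
    "ap_fit",
    "assign_cluster",
    "responsibility_update",
    "availability_update",
]


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------

@dataclass
class CentroidModel:
    """Fitted K-means state: centroids, labels, SSE and iteration count."""

    centroids: np.ndarray  # (k, d)
    labels: np.ndarray  # (n,)
    sse: float
    n_iter: int
    sse_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centroids)


def _sse(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: subsequent centroids drawn with probability
    proportional to squared distance from the nearest chosen centroid."""
    n = len(X)
    centroids = np.empty((k, X.shape[1]), dtype=float)
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            centroids[j] = X[rng.integers(n)]
            continue
        centroids[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int):
    labels = np.full(len(X), -1, dtype=int)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        # empty cluster: re-seed its centroid at the point farthest from
        # its assigned centroid, then re-assign
        for j in range(len(centroids)):
            if not np.any(new_labels == j):
                far = d2[np.arange(len(X)), new_labels].argmax()
                centroids[j] = X[far]
                d2 = cdist(X, centroids, "sqeuclidean")
                new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(len(centroids)):
            mask = labels == j
            if mask.any():  # a cluster can stay empty when all points coincide
                centroids[j] = X[mask].mean(axis=0)
        history.append(_sse(X, centroids, labels))
    return centroids, labels, history, n_iter


def kmeans_fit(
    X: np.ndarray,
    k: int,
    max_iter: int = 300,
    n_restarts: int = 10,
    seed: int | None = 0,
) -> CentroidModel:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by SSE."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n={n}, got {k}")
    rng = np.random.default_rng(seed)
    best: CentroidModel | None = None
    for _ in range(max(1, n_restarts)):
        centroids = _kmeanspp_init(X, k, rng)
        centroids, labels, history, n_iter = _lloyd(X, centroids.copy(), max_iter)
        sse = _sse(X, centroids, labels)
        if best is None or sse < best.sse:
            best = CentroidModel(
                centroids=centroids, labels=labels, sse=sse,
                n_iter=n_iter, sse_history=history,
            )
    return best


def sse_curve(
    X: np.ndarray,
    k_range,
    max_iter: int = 300,
    n_restarts: int = 10,
    seed: int | None = 0,
) -> list[tuple[int, float]]:
    """Best-of-restarts SSE per k, for elbow inspection."""
    return [
        (k, kmeans_fit(X, k, max_iter=max_iter, n_restarts=n_restarts, seed=seed).sse)
        for k in k_range
    ]


# ---------------------------------------------------------------------------
# BIRCH
# ---------------------------------------------------------------------------

@dataclass
class CFTriple:
    """Cluster feature: point count, linear sum and sum of squared coordinates.

    CFs are additive: merging two subclusters sums all three fields.
    """

    count: int
    linear_sum: np.ndarray
    squared_sum: float

    @classmethod
    def from_point(cls, x: np.ndarray) -> "CFTriple":
        x = np.asarray(x, dtype=float)
        return cls(count=1, linear_sum=x.copy(), squared_sum=float((x ** 2).sum()))

    def merged(self, other: "CFTriple") -> "CFTriple":
        return CFTriple(
            count=self.count + other.count,
            linear_sum=self.linear_sum + other.linear_sum,
            squared_sum=self.squared_sum + other.squared_sum,
        )

    @property
    def centroid(self) -> np.ndarray:
        return self.linear_sum / self.count

    @property
    def radius(self) -> float:
        """RMS distance of member points from the subcluster centroid."""
        var = self.squared_sum / self.count - float((self.centroid ** 2).sum())
        return float(np.sqrt(max(var, 0.0)))


class _CFNode:
    """CF-tree node; leaves hold subcluster CFs, interior nodes hold children."""

    def __init__(self, is_leaf: bool):
        self.is_leaf = is_leaf
        self.entries: list[CFTriple] = []  # leaf subclusters
        self.children: list[_CFNode] = []  # interior children
        self.child_cfs: list[CFTriple] = []  # summary CF per child

    def summary(self) -> CFTriple:
        cfs = self.entries if self.is_leaf else self.child_cfs
        total = cfs[0]
        for cf in cfs[1:]:
            total = total.merged(cf)
        return total


def _nearest(cfs: list[CFTriple], x: np.ndarray) -> int:
    d2 = [float(((cf.centroid - x) ** 2).sum()) for cf in cfs]
    return int(np.argmin(d2))


def _split(cfs: list[CFTriple]) -> tuple[list[int], list[int]]:
    """Split a CF list around its two farthest-apart centroids."""
    cents = np.array([cf.centroid for cf in cfs])
    d2 = cdist(cents, cents, "sqeuclidean")
    a, b = np.unravel_index(d2.argmax(), d2.shape)
    left, right = [], []
    for i in range(len(cfs)):
        (left if d2[i, a] <= d2[i, b] else right).append(i)
    if not left:
        left.append(right.pop(0))
    if not right:
        right.append(left.pop())
    return left, right


@dataclass
class CFTreeModel:
    """Fitted BIRCH model: leaf CFs plus a global cluster label per leaf."""

    threshold: float
    branching: int
    leaf_cfs: list[CFTriple]
    leaf_labels: np.ndarray  # global label per leaf CF
    labels: np.ndarray  # training-point labels
    root_cf: CFTriple

    @property
    def n_clusters(self) -> int:
        return len(set(self.leaf_labels.tolist()))

    @property
    def leaf_centroids(self) -> np.ndarray:
        return np.array([cf.centroid for cf in self.leaf_cfs])


class _CFTree:
    def __init__(self, threshold: float, branching: int):
        self.threshold = threshold
        self.branching = branching
        self.root = _CFNode(is_leaf=True)

    def insert(self, x: np.ndarray) -> None:
        split = self._insert(self.root, x)
        if split is not None:
            new_root = _CFNode(is_leaf=False)
            for node in split:
                new_root.children.append(node)
                new_root.child_cfs.append(node.summary())
            self.root = new_root

    def _insert(self, node: _CFNode, x: np.ndarray):
        """Insert a point; return a (left, right) node pair if ``node`` split."""
        if node.is_leaf:
            if node.entries:
                i = _nearest(node.entries, x)
                merged = node.entries[i].merged(CFTriple.from_point(x))
                if merged.radius <= self.threshold:
                    node.entries[i] = merged
                    return None
            node.entries.append(CFTriple.from_point(x))
            if len(node.entries) <= self.branching:
                return None
            left_i, right_i = _split(node.entries)
            left, right = _CFNode(True), _CFNode(True)
            left.entries = [node.entries[i] for i in left_i]
            right.entries = [node.entries[i] for i in right_i]
            return left, right
        i = _nearest(node.child_cfs, x)
        split = self._insert(node.children[i], x)
        if split is None:
            node.child_cfs[i] = node.child_cfs[i].merged(CFTriple.from_point(x))
            return None
        node.children[i : i + 1] = list(split)
        node.child_cfs[i : i + 1] = [c.summary() for c in split]
        if len(node.children) <= self.branching:
            return None
        left_i, right_i = _split(node.child_cfs)
        left, right = _CFNode(False), _CFNode(False)
        for idx in left_i:
            left.children.append(node.children[idx])
            left.child_cfs.append(node.child_cfs[idx])
        for idx in right_i:
            right.children.append(node.children[idx])
            right.child_cfs.append(node.child_cfs[idx])
        return left, right

    def leaves(self) -> list[CFTriple]:
        out: list[CFTriple] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.extend(node.entries)
            else:
                stack.extend(node.children)
        return out


def birch_fit(
    X: np.ndarray,
    threshold: float = 0.5,
    branching: int = 50,
    n_global_clusters: int = 4,
) -> CFTreeModel:
    """Two-phase BIRCH: build the CF tree, then agglomerate leaf centroids.

    Phase 1 inserts each point into its nearest leaf subcluster provided the
    merged radius stays within ``threshold``, otherwise opens a new
    subcluster (splitting nodes that exceed the branching factor).  Phase 2
    merges the leaf centroids into ``n_global_clusters`` labels by
    average-linkage agglomeration.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if branching < 2:
        raise ValueError("branching factor must be at least 2")
    tree = _CFTree(threshold, branching)
    for x in X:
        tree.insert(x)
    leaf_cfs = tree.leaves()
    centroids = np.array([cf.centroid for cf in leaf_cfs])
    n_leaves = len(leaf_cfs)
    n_global = min(n_global_clusters, n_leaves)
    if n_leaves == 1 or n_global == 1:
        leaf_labels = np.zeros(n_leaves, dtype=int)
    else:
        Z = linkage(centroids, method="average")
        raw = fcluster(Z, t=n_global, criterion="maxclust")
        # relabel in order of first appearance for determinism
        remap: dict[int, int] = {}
        leaf_labels = np.array([remap.setdefault(r, len(remap)) for r in raw])
    root_cf = leaf_cfs[0]
    for cf in leaf_cfs[1:]:
        root_cf = root_cf.merged(cf)
    point_labels = leaf_labels[cdist(X, centroids, "sqeuclidean").argmin(axis=1)]
    return CFTreeModel(
        threshold=threshold,
        branching=branching,
        leaf_cfs=leaf_cfs,
        leaf_labels=leaf_labels,
        labels=point_labels,
        root_cf=root_cf,
    )


# ---------------------------------------------------------------------------
# Affinity propagation
# ---------------------------------------------------------------------------

def responsibility_update(S: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Undamped responsibility sweep:
    r(i,k) = s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]."""
    AS = A + S
    n = len(S)
    idx = np.arange(n)
    first = AS.argmax(axis=1)
    first_val = AS[idx, first]
    AS2 = AS.copy()
    AS2[idx, first] = -np.inf
    second_val = AS2.max(axis=1)
    max_excl = np.where(np.arange(n)[None, :] == first[:, None],
                        second_val[:, None], first_val[:, None])
    return S - max_excl


def availability_update(R: np.ndarray) -> np.ndarray:
    """Undamped availability sweep:
    a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k))),
    a(k,k) = sum_{i' != k} max(0, r(i',k))."""
    n = len(R)
    Rp = np.maximum(R, 0.0)
    np.fill_diagonal(Rp, 0.0)  # exclude i' = k from all sums
    col = Rp.sum(axis=0)
    A = np.minimum(0.0, R.diagonal()[None, :] + col[None, :] - Rp)
    np.fill_diagonal(A, col)
    return A


@dataclass
class APState:
    """Fitted affinity-propagation state (similarity, message and criterion
    matrices, exemplars and training labels)."""

    S: np.ndarray
    R: np.ndarray
    A: np.ndarray
    damping: float
    preference: float
    exemplars: np.ndarray  # indices into the training set
    exemplar_points: np.ndarray  # (m, d)
    labels: np.ndarray  # -1 everywhere when unconverged
    converged: bool
    n_iter: int

    @property
    def C(self) -> np.ndarray:
        return self.R + self.A

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def similarity_matrix(X: np.ndarray, preference: float | str = "median") -> np.ndarray:
    """Negative squared Euclidean similarities with the preference on the
    diagonal; preference="median" uses the median off-diagonal similarity."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = -cdist(X, X, "sqeuclidean")
    n = len(X)
    if preference == "median":
        if n > 1:
            off = S[~np.eye(n, dtype=bool)]
            pref = float(np.median(off))
        else:
            pref = 0.0
    else:
        pref = float(preference)
    np.fill_diagonal(S, pref)
    return S


def ap_fit(
    X: np.ndarray,
    damping: float = 0.7,
    preference: float | str = "median",
    max_iter: int = 200,
    convergence_iter: int = 15,
) -> APState:
    """Affinity propagation by damped responsibility/availability passing.

    Each sweep mixes the freshly computed messages into the old ones with
    weight (1 - damping).  The fit converges when the exemplar set — the
    points whose criterion diagonal is positive — is stable for
    ``convergence_iter`` consecutive sweeps.  On non-convergence within
    ``max_iter`` sweeps every training label is the sentinel -1.
    """
    if not 0.5 <= damping < 1.0:
        raise ValueError(f"damping must be in [0.5, 1), got {damping}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    S = similarity_matrix(X, preference)
    pref = float(S[0, 0]) if n else 0.0
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    if n == 1:
        return APState(S=S, R=R, A=A, damping=damping, preference=pref,
                       exemplars=np.array([0]), exemplar_points=X.copy(),
                       labels=np.array([0]), converged=True, n_iter=0)
    off = S[~np.eye(n, dtype=bool)]
    if np.allclose(off, off[0], rtol=1e-10, atol=0):
        # fully symmetric input: message passing can never break the tie, so
        # resolve by the preference directly — below the shared similarity
        # one cluster (exemplar 0), at or above it every point is its own
        if pref < off[0]:
            return APState(S=S, R=R, A=A, damping=damping, preference=pref,
                           exemplars=np.array([0]), exemplar_points=X[:1].copy(),
                           labels=np.zeros(n, dtype=int), converged=True, n_iter=0)
        return APState(S=S, R=R, A=A, damping=damping, preference=pref,
                       exemplars=np.arange(n), exemplar_points=X.copy(),
                       labels=np.arange(n), converged=True, n_iter=0)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        R = damping * R + (1 - damping) * responsibility_update(S, A)
        A = damping * A + (1 - damping) * availability_update(R)
        exemplars = np.flatnonzero((R + A).diagonal() > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= convergence_iter and len(exemplars) > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars
    if not converged:
        return APState(S=S, R=R, A=A, damping=damping, preference=pref,
                       exemplars=np.array([], dtype=int),
                       exemplar_points=np.empty((0, X.shape[1])),
                       labels=np.full(n, -1), converged=False, n_iter=it)
    exemplars = np.flatnonzero((R + A).diagonal() > 0)
    d2 = cdist(X, X[exemplars], "sqeuclidean")
    labels = d2.argmin(axis=1)
    labels[exemplars] = np.arange(len(exemplars))  # exemplars label themselves
    return APState(S=S, R=R, A=A, damping=damping, preference=pref,
                   exemplars=exemplars, exemplar_points=X[exemplars].copy(),
                   labels=labels, converged=True, n_iter=it)


# ---------------------------------------------------------------------------
# Uniform assignment
# ---------------------------------------------------------------------------

def _check_dim(model_dim: int, fv: np.ndarray) -> np.ndarray:
    fv = np.asarray(fv, dtype=float).ravel()
    if len(fv) != model_dim:
        raise ValueError(f"feature vector has dimension {len(fv)}, model expects {model_dim}")
    return fv


def assign_cluster(model, fv: np.ndarray) -> int:
    """Assign a new feature vector to a cluster under any fitted model.

    K-means: nearest centroid.  BIRCH: global label of the nearest leaf
    centroid.  AP: cluster of the nearest exemplar, or -1 if the fit never
    converged.  Nearest-by-squared-distance, lowest index on ties.
    """
    if isinstance(model, CentroidModel):
        fv = _check_dim(model.centroids.shape[1], fv)
        return int(((model.centroids - fv) ** 2).sum(axis=1).argmin())
    if isinstance(model, CFTreeModel):
        cents = model.leaf_centroids
        fv = _check_dim(cents.shape[1], fv)
        return int(model.leaf_labels[((cents - fv) ** 2).sum(axis=1).argmin()])
    if isinstance(model, APState):
        if not model.converged or len(model.exemplars) == 0:
            return -1
        fv = _check_dim(model.exemplar_points.shape[1], fv)
        return int(((model.exemplar_points - fv) ** 2).sum(axis=1).argmin())
    raise TypeError(f"unsupported model type {type(model).__name__}")
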