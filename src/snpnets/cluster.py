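"""Single- and multigraph min-max graph-cut clustering of SNP networks.

The min-max cut partitions a similarity graph by minimizing, over cluster
indicators q_k, the sum of ratios (q_k' D q_k) / (q_k' A q_k) where A is the
similarity (adjacency) matrix and D its degree matrix.  Because
q' D q = within-cluster weight + cut weight, each ratio is
1 + cut/within: the objective jointly minimizes between-cluster similarity
and maximizes within-cluster similarity, and is bounded below by K (with
equality iff the cut is empty).  The multigraph variant sums the objective
over m similarity views that share the node set, so a single partition is
scored against all views at once::

    min_{Q' Q = I}  sum_v sum_k (q_k' D_v q_k) / (q_k' A_v q_k)

``MultigraphMinMaxCut`` is the model object; ``fit`` relaxes Q to a
nonnegative matrix with orthonormal columns, minimizes the objective by
projected gradient descent with a backtracking (non-increasing) line
search from a spectral + k-means start, discretizes by row-argmax, and
repairs empty clusters by greedy minimal-damage transfers.  The result
object carries the assignment, the relaxed-objective trace, and the hard
objective of the final partition.

``solve_exhaustive`` enumerates all partitions of small instances and serves
as an independent correctness oracle for the descent solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .networks import SimilarityNetwork

__all__ = [
    "MultigraphMinMaxCut",
    "MinMaxCutResults",
    "degree_matrix",
    "hard_objective",
    "solve_multigraph",
    "solve_singlegraph",
    "solve_exhaustive",
]

#: Denominator guard for relaxed indicator columns with near-zero support.
EPS = 1e-12


def degree_matrix(network: SimilarityNetwork) -> np.ndarray:
    """Degree matrix D = diag(row sums of the weight matrix)."""
    return np.diag(network.weights.sum(axis=1))


def _as_label_array(assignment, snp_ids: list[str]) -> np.ndarray:
    if isinstance(assignment, dict):
        return np.array([assignment[s] for s in snp_ids], dtype=int)
    return np.asarray(assignment, dtype=int)


def hard_objective(views: list[SimilarityNetwork], assignment, K: int) -> float:
    """Multigraph min-max cut objective of a hard partition.

    The ratio (q_k' D q_k)/(q_k' A q_k) is scale-invariant in q_k, so the
    unnormalized 0/1 indicators are used directly.  Every cluster
    0..K-1 must be nonempty.
    """
    labels = _as_label_array(assignment, views[0].snp_ids)
    counts = np.bincount(labels, minlength=K)
    if (counts[:K] == 0).any() or labels.max() >= K or labels.min() < 0:
        raise ValueError("assignment must use every cluster label 0..K-1")
    total = 0.0
    for net in views:
        A = net.weights
        deg = A.sum(axis=1)
        for k in range(K):
            mask = labels == k
            within = A[np.ix_(mask, mask)].sum()
            total += deg[mask].sum() / within
    return float(total)


def _objective_nonempty(views: list[SimilarityNetwork], labels: np.ndarray) -> float:
    """Objective summed over the nonempty clusters only (used during repair)."""
    total = 0.0
    for net in views:
        A = net.weights
        deg = A.sum(axis=1)
        for k in np.unique(labels):
            mask = labels == k
            total += deg[mask].sum() / A[np.ix_(mask, mask)].sum()
    return float(total)


def _relaxed_objective(Q: np.ndarray, mats: list[tuple[np.ndarray, np.ndarray]]) -> float:
    total = 0.0
    for A, D in mats:
        AQ = A @ Q
        dq = D[:, np.newaxis] * Q
        num = np.einsum("ik,ik->k", Q, dq)
        den = np.einsum("ik,ik->k", Q, AQ) + EPS
        total += float((num / den).sum())
    return total


def _relaxed_gradient(Q: np.ndarray, mats: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    grad = np.zeros_like(Q)
    for A, D in mats:
        AQ = A @ Q
        DQ = D[:, np.newaxis] * Q
        num = np.einsum("ik,ik->k", Q, DQ)
        den = np.einsum("ik,ik->k", Q, AQ) + EPS
        grad += 2.0 * DQ / den - 2.0 * AQ * (num / den**2)
    return grad


def _project(Q: np.ndarray) -> np.ndarray:
    """Project onto nonnegative matrices with (approximately) orthonormal columns."""
    Q = np.maximum(Q, 0.0)
    for _ in range(2):
        M = Q.T @ Q
        vals, vecs = np.linalg.eigh(M)
        vals = np.maximum(vals, EPS)
        Q = Q @ (vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T)
        Q = np.maximum(Q, 0.0)
    norms = np.linalg.norm(Q, axis=0)
    # A column that lost all support is revived uniformly.
    dead = norms < np.sqrt(EPS)
    if dead.any():
        Q[:, dead] = 1.0
        norms = np.linalg.norm(Q, axis=0)
    return Q / norms


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first occurrence (0, 1, ...)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class MinMaxCutResults:
    """Fitted min-max cut partition and diagnostics.

    Attributes
    ----------
    labels_ : per-node cluster indices in canonical (first-occurrence) order
    assignment : snp_id -> cluster index
    Q : final nonnegative relaxed indicator with exactly orthonormal columns
    hard_objective_ : multigraph objective of the hard partition (>= m*K)
    objective_trace : relaxed objective after each accepted descent step
        (non-increasing by construction)
    """

    model: "MultigraphMinMaxCut"
    labels_: np.ndarray
    Q: np.ndarray
    hard_objective_: float
    objective_trace: list[float]
    n_iterations: int
    converged: bool
    seed: int

    @property
    def assignment(self) -> dict[str, int]:
        return {s: int(l) for s, l in zip(self.model.snp_ids, self.labels_)}

    @property
    def cluster_sizes(self) -> list[int]:
        return np.bincount(self.labels_, minlength=self.model.n_clusters).tolist()

    def summary(self) -> str:
        m = self.model
        lines = [
            "Min-max graph cut results",
            "=" * 40,
            f"nodes:            {len(m.snp_ids)}",
            f"views:            {len(m.views)} ({', '.join(v.measure or '?' for v in m.views)})",
            f"clusters (K):     {m.n_clusters}",
            f"cluster sizes:    {self.cluster_sizes}",
            f"hard objective:   {self.hard_objective_:.6f}  (lower bound {len(m.views) * m.n_clusters})",
            f"iterations:       {self.n_iterations} ({'converged' if self.converged else 'max_iter reached'})",
            f"seed:             {self.seed}",
        ]
        return "\n".join(lines)


class MultigraphMinMaxCut:
    """Min-max graph-cut model over one or more similarity views.

    Parameters
    ----------
    views : similarity networks sharing an identical node (SNP) ordering
    n_clusters : number of clusters K, 2 <= K <= n_nodes - 1
    """

    def __init__(self, views: list[SimilarityNetwork] | SimilarityNetwork, n_clusters: int):
        if isinstance(views, SimilarityNetwork):
            views = [views]
        if not views:
            raise ValueError("at least one similarity view is required")
        ids = views[0].snp_ids
        for v in views[1:]:
            if v.snp_ids != ids:
                raise ValueError("all views must share the same snp_ids ordering")
        S = len(ids)
        if not (2 <= n_clusters <= S - 1):
            raise ValueError(f"n_clusters must be in [2, {S - 1}], got {n_clusters}")
        self.views = list(views)
        self.snp_ids = list(ids)
        self.n_clusters = int(n_clusters)

    def _initial_q(self, seed: int) -> np.ndarray:
        """Spectral embedding of the view-averaged normalized adjacency + k-means."""
        S, K = len(self.snp_ids), self.n_clusters
        avg = np.zeros((S, S))
        for v in self.views:
            deg = v.weights.sum(axis=1)
            dinv = 1.0 / np.sqrt(np.maximum(deg, EPS))
            avg += dinv[:, np.newaxis] * v.weights * dinv[np.newaxis, :]
        avg /= len(self.views)
        avg = (avg + avg.T) / 2.0
        _, vecs = eigh(avg, subset_by_index=[S - K, S - 1])
        rows = np.linalg.norm(vecs, axis=1, keepdims=True)
        embedding = vecs / np.maximum(rows, EPS)
        km = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31))
        labels = km.fit_predict(embedding)
        H = np.zeros((S, K))
        H[np.arange(S), labels] = 1.0
        return _project(H + 0.2)  # smoothed nonnegative indicator

    def fit(self, seed: int = 0, max_iter: int = 1000, tol: float = 1e-6) -> MinMaxCutResults:
        """Minimize the relaxed objective and return the hard partition.

        Deterministic for a fixed seed.  Projected gradient descent with a
        backtracking line search that only accepts non-increasing steps;
        stops when the relative objective change drops below ``tol``.
        """
        mats = [(v.weights, v.weights.sum(axis=1)) for v in self.views]
        Q = self._initial_q(seed)
        obj = _relaxed_objective(Q, mats)
        trace = [obj]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            grad = _relaxed_gradient(Q, mats)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0:
                converged = True
                break
            step = np.linalg.norm(Q) / gnorm
            accepted = False
            for _ in range(40):
                cand = _project(Q - step * grad)
                cand_obj = _relaxed_objective(cand, mats)
                if cand_obj <= obj:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                converged = True
                break
            rel_change = (obj - cand_obj) / max(abs(obj), EPS)
            Q, obj = cand, cand_obj
            trace.append(obj)
            if rel_change < tol:
                converged = True
                break

        labels = self._discretize(Q)
        labels = self._repair_empty(labels)
        labels = self._local_refine(labels)
        labels = _canonical_labels(labels)
        K = self.n_clusters
        hard = hard_objective(self.views, labels, K)
        # Exact final projection: the hard indicator with unit columns is the
        # nearest nonnegative matrix with exactly orthonormal columns.
        Qh = np.zeros((len(labels), K))
        Qh[np.arange(len(labels)), labels] = 1.0
        Qh /= np.linalg.norm(Qh, axis=0)
        return MinMaxCutResults(
            model=self,
            labels_=labels,
            Q=Qh,
            hard_objective_=hard,
            objective_trace=trace,
            n_iterations=it,
            converged=converged,
            seed=seed,
        )

    def _discretize(self, Q: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lowest cluster index.
        return np.argmax(Q, axis=1)

    def _local_refine(self, labels: np.ndarray, max_passes: int = 100) -> np.ndarray:
        """Polish the discretized partition: greedily apply the single-node
        move that most decreases the hard objective until none improves.

        Move deltas are computed incrementally from per-cluster degree and
        within-weight totals, so a full pass costs O(m * S^2) rather than
        O(m * S^3)."""
        K = self.n_clusters
        labels = labels.copy()
        A_list = [v.weights for v in self.views]
        deg_list = [A.sum(axis=1) for A in A_list]
        for _ in range(max_passes):
            H = np.zeros((len(labels), K))
            H[np.arange(len(labels)), labels] = 1.0
            counts = H.sum(axis=0)
            best_delta, best_move = -1e-10, None
            # per view: row-to-cluster weight sums, cluster degree/within totals
            view_R = [A @ H for A in A_list]
            view_degsum = [deg @ H for deg in deg_list]
            view_within = [np.einsum("ik,ik->k", H, R) for R in view_R]
            for i in range(len(labels)):
                a = labels[i]
                if counts[a] < 2:
                    continue
                for b in range(K):
                    if b == a:
                        continue
                    delta = 0.0
                    for A, deg, R, degsum, within in zip(
                        A_list, deg_list, view_R, view_degsum, view_within
                    ):
                        wa = within[a] - 2 * R[i, a] + A[i, i]
                        wb = within[b] + 2 * R[i, b] + A[i, i]
                        da = degsum[a] - deg[i]
                        db = degsum[b] + deg[i]
                        delta += (
                            da / wa + db / wb - degsum[a] / within[a] - degsum[b] / within[b]
                        )
                    if delta < best_delta:
                        best_delta, best_move = delta, (i, b)
            if best_move is None:
                break
            labels[best_move[0]] = best_move[1]
        return labels

    def _repair_empty(self, labels: np.ndarray) -> np.ndarray:
        """Fill empty clusters by moving, one at a time, the node whose
        transfer least increases the objective over nonempty clusters."""
        K = self.n_clusters
        labels = labels.copy()
        while True:
            counts = np.bincount(labels, minlength=K)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                return labels
            target = int(empty[0])
            best, best_node = None, None
            for node in range(len(labels)):
                if counts[labels[node]] < 2:
                    continue  # never empty a source cluster
                trial = labels.copy()
                trial[node] = target
                val = _objective_nonempty(self.views, trial)
                if best is None or val < best:
                    best, best_node = val, node
            if best_node is None:
                raise RuntimeError("cannot repair empty clusters: no movable node")
            counts[labels[best_node]] -= 1
            labels[best_node] = target
            counts[target] += 1


def solve_multigraph(
    views: list[SimilarityNetwork],
    K: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MinMaxCutResults:
    """Convenience wrapper: fit a multigraph min-max cut model."""
    return MultigraphMinMaxCut(views, K).fit(seed=seed, max_iter=max_iter, tol=tol)


def solve_singlegraph(
    view: SimilarityNetwork,
    K: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MinMaxCutResults:
    """Single-graph min-max cut: the multigraph model with one view."""
    return MultigraphMinMaxCut([view], K).fit(seed=seed, max_iter=max_iter, tol=tol)


def _partitions_into_k(n: int, K: int):
    """Yield restricted-growth label arrays using exactly K labels."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, used: int):
        if i == n:
            if used == K:
                yield labels.copy()
            return
        # pruning: remaining positions must be able to introduce missing labels
        if used + (n - i) < K:
            return
        for lab in range(min(used + 1, K)):
            labels[i] = lab
            yield from rec(i + 1, used + (1 if lab == used else 0))

    yield from rec(1, 1)  # node 0 fixed to label 0 (canonical order)


@dataclass
class ExhaustiveResult:
    labels: np.ndarray
    objective: float
    n_evaluated: int

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self._snp_ids, (int(l) for l in self.labels)))

    _snp_ids: list[str] = field(default_factory=list)


def solve_exhaustive(views: list[SimilarityNetwork] | SimilarityNetwork, K: int) -> ExhaustiveResult:
    """Global minimum of the hard objective by Stirling-number enumeration.

    Refuses instances beyond S = 15 nodes or K = 3 clusters; intended as a
    correctness oracle for the descent solver on small instances.
    """
    if isinstance(views, SimilarityNetwork):
        views = [views]
    S = len(views[0].snp_ids)
    if S > 15 or K > 3:
        raise ValueError(
            f"exhaustive enumeration limited to S <= 15 nodes and K <= 3 "
            f"clusters (got S={S}, K={K})"
        )
    best_labels, best_obj, count = None, np.inf, 0
    for labels in _partitions_into_k(S, K):
        count += 1
        obj = hard_objective(views, labels, K)
        if obj < best_obj:
            best_obj, best_labels = obj, labels
    result = ExhaustiveResult(labels=best_labels, objective=float(best_obj), n_evaluated=count)
    result._snp_ids = list(views[0].snp_ids)
    return result
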