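"""Clustering of RSN overlap profiles, and its graph-based validation.

Two independent routes classify the rows of an overlap matrix:

* a diagonal-covariance Bayesian Gaussian mixture fitted by variational EM
  with a Dirichlet-process weight prior, so that superfluous components are
  emptied automatically and the model order is determined by the data
  ("automatic determination of the number of components");
* weighted Newman-Girvan community detection on a cosine-similarity graph
  over the same rows, where the network itself fixes the number and size of
  the groups.

Agreement between the two partitions is summarized by a confusion matrix
after optimal one-to-one label matching, and by the resulting accuracy
(correct predictions / total predictions).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import BayesianGaussianMixture

from .errors import ValidationError
from .overlap_matrices import OverlapMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "CommunityPartition",
    "ConcordanceSummary",
    "em_mixture_cluster",
    "profile_graph",
    "modularity",
    "detect_communities",
    "concordance_accuracy",
]


@dataclass
class ClusteringResult:
    """Mixture-model partition of overlap-matrix rows."""

    assignment: dict[str, int]
    n_clusters: int
    responsibilities: np.ndarray
    log_evidence: float  # variational lower bound of the selected model
    row_labels: list[str]

    def members(self, cluster_id: int) -> list[str]:
        return [r for r, c in self.assignment.items() if c == cluster_id]


@dataclass
class CommunityPartition:
    """Partition of graph nodes with its modularity score."""

    assignment: dict[str, int]
    modularity_q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class ConcordanceSummary:
    """Confusion matrix (after optimal matching) and accuracy of agreement."""

    confusion: np.ndarray
    accuracy: float


def em_mixture_cluster(
    matrix: OverlapMatrix,
    max_components: int = 12,
    restarts: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """Variational Bayesian Gaussian mixture over row profiles.

    Rows (overlap profiles) are standardized per column and fitted with a
    diagonal-covariance mixture of up to ``max_components`` Gaussians under
    a Dirichlet-process weight prior: variational EM drives the weights of
    unsupported components to zero, so the number of occupied components is
    determined automatically by the data.  ``restarts`` seeded
    initializations are run and the best lower bound kept; empty components
    are pruned from the reported cluster count.  Deterministic given
    ``seed``.
    """
    X = matrix.counts.astype(float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("overlap matrix contains non-finite entries")
    n_rows = X.shape[0]
    if n_rows < 2:
        raise ValidationError("need at least 2 rows to cluster")
    if not 1 <= max_components <= n_rows:
        raise ValidationError("max_components must be in [1, n_rows]")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence warnings tolerated
        gmm = BayesianGaussianMixture(
            n_components=max_components,
            covariance_type="diag",
            weight_concentration_prior_type="dirichlet_process",
            reg_covar=1e-6,
            tol=1e-8,
            max_iter=2000,
            n_init=restarts,
            random_state=int(seed),
        ).fit(Xs)

    resp = gmm.predict_proba(Xs)
    hard = resp.argmax(axis=1)
    used = sorted(set(hard))
    relabel = {old: new + 1 for new, old in enumerate(used)}
    labels = [str(r) for r in matrix.row_labels]
    assignment = {lbl: relabel[h] for lbl, h in zip(labels, hard)}
    return ClusteringResult(
        assignment=assignment,
        n_clusters=len(used),
        responsibilities=resp,
        log_evidence=float(gmm.lower_bound_),
        row_labels=labels,
    )


def profile_graph(matrix: OverlapMatrix) -> nx.Graph:
    """Weighted graph over rows: cosine similarity, mean-weight sparsified.

    Edge weight is the cosine similarity of two row profiles (negatives
    clipped to zero); edges strictly below the mean positive weight are
    removed.  All-zero rows become isolated nodes (logged).
    """
    X = matrix.counts.astype(float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows")
    labels = [str(r) for r in matrix.row_labels]
    norms = np.linalg.norm(X, axis=1)
    zero_rows = [lbl for lbl, nrm in zip(labels, norms) if nrm == 0]
    if zero_rows:
        logger.warning("all-zero profiles left isolated: %s", zero_rows)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    cos = (X @ X.T) / np.outer(safe, safe)
    cos = np.clip(cos, 0.0, None)
    np.fill_diagonal(cos, 0.0)

    iu = np.triu_indices_from(cos, k=1)
    weights = cos[iu]
    positive = weights[weights > 0]
    cutoff = positive.mean() if positive.size else 0.0

    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, j, w in zip(iu[0], iu[1], weights):
        if w > 0 and w >= cutoff:
            g.add_edge(labels[i], labels[j], weight=float(w))
    return g


def modularity(graph: nx.Graph, partition: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity Q of a node partition.

    Q = sum over communities c of ( w_in(c)/W - (s(c)/2W)^2 ), with W the
    total edge weight, w_in(c) the weight of edges inside c, and s(c) the
    total strength of c's nodes.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    missing = set(graph.nodes) - set(partition)
    if missing:
        raise ValidationError(f"partition does not cover nodes {sorted(missing)}")
    W = graph.size(weight="weight")
    if W == 0:
        return 0.0
    q = 0.0
    for com in set(partition.values()):
        nodes = {n for n in graph.nodes if partition[n] == com}
        w_in = sum(
            d.get("weight", 1.0)
            for u, v, d in graph.edges(nodes, data=True)
            if u in nodes and v in nodes
        )
        strength = sum(dict(graph.degree(nodes, weight="weight")).values())
        q += w_in / W - (strength / (2 * W)) ** 2
    return float(q)


def detect_communities(graph: nx.Graph) -> CommunityPartition:
    """Greedy agglomerative modularity maximization.

    Starting from singleton communities, repeatedly merge the pair of
    communities giving the largest positive change in Q; stop when no merge
    increases Q.  On small graphs this matches exhaustive search over all
    partitions (checked in the test battery).
    """
    if graph.number_of_nodes() < 1:
        raise ValidationError("empty graph")
    partition = {n: i for i, n in enumerate(graph.nodes)}
    q = modularity(graph, partition) if graph.number_of_edges() else 0.0
    while True:
        coms = sorted(set(partition.values()))
        if len(coms) == 1:
            break
        best_gain = 0.0
        best_pair = None
        for a, b in itertools.combinations(coms, 2):
            trial = {n: (a if c == b else c) for n, c in partition.items()}
            gain = modularity(graph, trial) - q
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        partition = {n: (a if c == b else c) for n, c in partition.items()}
        q += best_gain
    relabel = {old: new + 1 for new, old in enumerate(sorted(set(partition.values())))}
    partition = {n: relabel[c] for n, c in partition.items()}
    return CommunityPartition(partition, modularity(graph, partition))


def concordance_accuracy(
    a: ClusteringResult | dict[str, int],
    b: CommunityPartition | dict[str, int],
) -> ConcordanceSummary:
    """Agreement between two partitions of the same rows.

    Labels are matched one-to-one by maximizing the confusion-matrix trace
    (optimal assignment on the zero-padded square matrix); accuracy is the
    matched trace over the number of rows.
    """
    pa = a.assignment if not isinstance(a, dict) else a
    pb = b.assignment if not isinstance(b, dict) else b
    if set(pa) != set(pb):
        raise ValidationError("partitions cover different row sets")
    rows = sorted(pa)
    labs_a = sorted(set(pa.values()))
    labs_b = sorted(set(pb.values()))
    size = max(len(labs_a), len(labs_b))
    conf = np.zeros((size, size), dtype=int)
    ia = {lab: i for i, lab in enumerate(labs_a)}
    ib = {lab: i for i, lab in enumerate(labs_b)}
    for r in rows:
        conf[ia[pa[r]], ib[pb[r]]] += 1
    ri, ci = linear_sum_assignment(-conf)
    matched = conf[:, ci]  # columns permuted so the optimal match is the diagonal
    accuracy = matched.trace() / len(rows)
    return ConcordanceSummary(matched, float(accuracy))
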