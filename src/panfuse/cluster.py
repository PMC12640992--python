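"""Pseudo-label generation by a five-algorithm voting "scoring network".

Five base clustering algorithms — K-Means, full-covariance Gaussian mixture,
Ward agglomerative clustering, CLARANS and K-Medoids (PAM) — partition the
samples under a common Euclidean metric (the GMM's Gaussian likelihood is the
one documented deviation). Their label spaces are aligned to a reference by
optimal assignment on the k x k contingency table, and each sample receives a
consensus pseudo-label by majority vote, with 2-2-1 style ties broken toward
the tied cluster whose consensus centroid is nearest. The number of clusters
is selected by mean silhouette over a candidate grid.

K-Medoids and CLARANS are implemented here (BUILD initialisation plus
alternating medoid updates, and randomised medoid-swap search respectively);
the remaining base algorithms come from scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .io import ExpressionMatrix

ALGORITHMS = ("kmeans", "gmm", "agglomerative", "clarans", "kmedoids")
N_VOTERS = len(ALGORITHMS)


@dataclass
class BaseClusteringResult:
    algorithm: str
    labels: np.ndarray
    k: int
    seed: int
    converged: bool = True
    degenerate: bool = False  # an empty cluster was produced

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            self.degenerate = True


# ---------------------------------------------------------------------------
# in-repo medoid algorithms
# ---------------------------------------------------------------------------


def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialisation: repeatedly add the point that most
    reduces the total distance to the nearest chosen medoid."""
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    nearest = D[first].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, D[best])
    return np.array(medoids)


def kmedoids_pam(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 100):
    """K-Medoids with BUILD initialisation and alternating medoid updates.

    Assign each point to its nearest medoid, then move every medoid to the
    in-cluster point minimising the summed within-cluster distance; iterate
    to a fixed point. Euclidean distances throughout.
    """
    D = cdist(X, X)
    medoids = _pam_build(D, k)
    for _ in range(max_iter):
        labels = np.argmin(D[medoids], axis=0)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.where(labels == j)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = np.argmin(D[medoids], axis=0)
    return labels, medoids


def clarans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    numlocal: int = 4,
    maxneighbor: Optional[int] = None,
):
    """CLARANS: randomised search over the graph of medoid sets.

    Each node is a set of k medoids; neighbours differ by one medoid swap.
    From a random node, up to ``maxneighbor`` random neighbours are examined;
    any cost improvement moves the search there and resets the counter. After
    ``numlocal`` local optima the best is returned.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if maxneighbor is None:
        maxneighbor = max(250, int(round(0.0125 * k * (n - k))))
    D = cdist(X, X)

    def cost(medoids):
        return D[medoids].min(axis=0).sum()

    best_medoids, best_cost = None, np.inf
    for _ in range(numlocal):
        current = rng.choice(n, size=k, replace=False)
        current_cost = cost(current)
        fails = 0
        while fails < maxneighbor:
            i = rng.integers(k)
            candidates = np.setdiff1d(np.arange(n), current)
            swap = rng.choice(candidates)
            neighbor = current.copy()
            neighbor[i] = swap
            c = cost(neighbor)
            if c < current_cost:
                current, current_cost = neighbor, c
                fails = 0
            else:
                fails += 1
        if current_cost < best_cost:
            best_medoids, best_cost = current, current_cost
    labels = np.argmin(D[best_medoids], axis=0)
    return labels, best_medoids


# ---------------------------------------------------------------------------
# base clusterers
# ---------------------------------------------------------------------------


def derive_seeds(master_seed: int, n: int = N_VOTERS) -> list:
    """Deterministic per-algorithm seeds fanned out from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_base_clusterers(X, k: int, seed: int = 0) -> list:
    """Run the five voters on a samples x features matrix.

    ``X`` may be an ExpressionMatrix (transposed internally so samples are
    the clustering units) or a samples x features ndarray.
    """
    M = X.samples_matrix() if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n = M.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    if not np.all(np.isfinite(M)):
        raise ValueError("clustering input contains non-finite values")

    seeds = derive_seeds(seed)
    results = []

    km = KMeans(n_clusters=k, n_init=10, random_state=seeds[0]).fit(M)
    results.append(BaseClusteringResult("kmeans", km.labels_, k, seeds[0]))

    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-4,
        n_init=3,
        random_state=seeds[1],
    ).fit(M)
    results.append(
        BaseClusteringResult(
            "gmm", gmm.predict(M), k, seeds[1], converged=bool(gmm.converged_)
        )
    )

    agg = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(M)
    results.append(BaseClusteringResult("agglomerative", agg.labels_, k, seeds[2]))

    cl_labels, _ = clarans(M, k, seed=seeds[3])
    results.append(BaseClusteringResult("clarans", cl_labels, k, seeds[3]))

    pam_labels, _ = kmedoids_pam(M, k, seed=seeds[4])
    results.append(BaseClusteringResult("kmedoids", pam_labels, k, seeds[4]))

    return results


# ---------------------------------------------------------------------------
# alignment + voting
# ---------------------------------------------------------------------------


def align_labels(results: Sequence[BaseClusteringResult], reference_index: int = 0):
    """Align every labeling to the reference's label space.

    The permutation for each non-reference labeling maximises total label
    agreement with the reference — optimal assignment on the k x k
    contingency table (Hungarian algorithm).
    """
    ks = {r.k for r in results}
    if len(ks) != 1:
        raise ValueError(f"all results must share k, got {sorted(ks)}")
    k = ks.pop()
    ref = results[reference_index].labels
    aligned, permutations = [], []
    for idx, r in enumerate(results):
        if idx == reference_index:
            perm = np.arange(k)
        else:
            cont = np.zeros((k, k))
            np.add.at(cont, (r.labels, ref), 1)
            rows, cols = linear_sum_assignment(-cont)
            perm = np.empty(k, dtype=int)
            perm[rows] = cols
        permutations.append(perm)
        aligned.append(
            BaseClusteringResult(
                r.algorithm, perm[r.labels], k, r.seed, r.converged, r.degenerate
            )
        )
    return aligned, permutations


@dataclass
class ConsensusLabeling:
    per_algorithm: list
    alignment: list
    votes: np.ndarray  # (n_samples, k)
    consensus: np.ndarray  # (n_samples,)
    agreement: np.ndarray  # (n_samples,), max votes / 5
    k: int
    tie_broken: np.ndarray = field(default=None)  # bool per sample

    def to_frame(self, sample_ids):
        import pandas as pd

        df = pd.DataFrame({"sample_id": list(sample_ids), "label": self.consensus})
        df["agreement"] = self.agreement
        for r in self.per_algorithm:
            df[r.algorithm] = r.labels
        return df


def majority_vote(aligned: Sequence[BaseClusteringResult], X) -> ConsensusLabeling:
    """Consensus pseudo-labels by majority vote over five aligned voters.

    Ties are broken toward the tied cluster whose consensus centroid — the
    mean expression of samples with an unambiguous (untied) majority — is
    nearest in Euclidean distance; any remaining tie goes to the lowest label.
    """
    if len(aligned) != N_VOTERS:
        raise ValueError(f"the scoring network requires {N_VOTERS} voters, got {len(aligned)}")
    k = aligned[0].k
    L = np.stack([r.labels for r in aligned])  # (5, n)
    n = L.shape[1]
    votes = np.zeros((n, k), dtype=int)
    for row in L:
        np.add.at(votes, (np.arange(n), row), 1)

    max_votes = votes.max(axis=1)
    is_tied = (votes == max_votes[:, None]).sum(axis=1) > 1
    consensus = votes.argmax(axis=1)  # lowest index on ties, refined below

    M = X.samples_matrix() if isinstance(X, ExpressionMatrix) else np.asarray(X, float)

    if is_tied.any():
        centroids = np.full((k, M.shape[1]), np.nan)
        for j in range(k):
            members = np.where((consensus == j) & ~is_tied)[0]
            if members.size:
                centroids[j] = M[members].mean(axis=0)
        for i in np.where(is_tied)[0]:
            tied = np.where(votes[i] == max_votes[i])[0]
            dists = np.array(
                [
                    np.linalg.norm(M[i] - centroids[j]) if np.isfinite(centroids[j]).all() else np.inf
                    for j in tied
                ]
            )
            if np.isfinite(dists).any():
                consensus[i] = tied[int(np.argmin(dists))]
            else:
                consensus[i] = tied[0]

    agreement = max_votes / N_VOTERS
    return ConsensusLabeling(
        per_algorithm=list(aligned),
        alignment=None,
        votes=votes,
        consensus=consensus,
        agreement=agreement,
        k=k,
        tie_broken=is_tied,
    )


def consensus_cluster(X, k: int, seed: int = 0) -> ConsensusLabeling:
    """Full scoring-network pass: run the five voters, align, vote.

    The alignment reference is the voter with the highest mean silhouette.
    """
    M = X.samples_matrix() if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    results = run_base_clusterers(M, k, seed)
    sils = []
    for r in results:
        if len(np.unique(r.labels)) < 2:
            sils.append(-np.inf)
        else:
            sils.append(silhouette_score(M, r.labels, metric="euclidean"))
    ref = int(np.argmax(sils))
    aligned, perms = align_labels(results, reference_index=ref)
    labeling = majority_vote(aligned, M)
    labeling.alignment = perms
    return labeling


# ---------------------------------------------------------------------------
# silhouette-guided k
# ---------------------------------------------------------------------------


@dataclass
class SilhouetteReport:
    k_candidates: list
    mean_silhouette: list
    chosen_k: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": self.k_candidates, "mean_silhouette": self.mean_silhouette}
        )


def silhouette_select_k(X, k_candidates: Sequence[int], seed: int = 0) -> SilhouetteReport:
    """Pick k by the mean silhouette of the consensus labeling (ties: smaller k)."""
    k_candidates = list(k_candidates)
    if not k_candidates:
        raise ValueError("k_candidates is empty")
    M = X.samples_matrix() if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n = M.shape[0]
    for k in k_candidates:
        if k < 2 or k >= n:
            raise ValueError(f"candidate k={k} outside [2, n_samples)")
    scores = []
    for k in k_candidates:
        labeling = consensus_cluster(M, k, seed)
        if len(np.unique(labeling.consensus)) < 2:
            scores.append(-1.0)
        else:
            scores.append(float(silhouette_score(M, labeling.consensus, metric="euclidean")))
    best = max(range(len(k_candidates)), key=lambda i: (scores[i], -k_candidates[i]))
    return SilhouetteReport(k_candidates, scores, k_candidates[best])


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class ConsensusClusterer:
    """Subtype discovery model over an expression cohort.

    Parameters
    ----------
    k : int, optional
        Number of subtypes. If None, selected by silhouette over
        ``k_candidates``.
    k_candidates : sequence of int
        Grid scanned when ``k`` is None (default 2..6).
    zscore : bool
        Standardise each gene to zero mean / unit variance before clustering
        (default True; Euclidean distance over raw expression is dominated by
        high-magnitude genes).
    gene_set : sequence of str, optional
        Restrict clustering to these genes (e.g. a programmed-cell-death
        panel). If None, the ``n_top_genes`` most variable genes are used.
    n_top_genes : int
        Top-variance gene count when no gene set is supplied (default 2000,
        capped at the matrix size).
    """

    def __init__(
        self,
        k: Optional[int] = None,
        k_candidates: Sequence[int] = (2, 3, 4, 5, 6),
        zscore: bool = True,
        gene_set: Optional[Sequence[str]] = None,
        n_top_genes: int = 2000,
        seed: int = 0,
    ):
        self.k = k
        self.k_candidates = list(k_candidates)
        self.zscore = zscore
        self.gene_set = list(gene_set) if gene_set is not None else None
        self.n_top_genes = n_top_genes
        self.seed = seed

    def _features(self, X: ExpressionMatrix) -> np.ndarray:
        if self.gene_set is not None:
            present = [g for g in self.gene_set if g in set(X.gene_ids)]
            if not present:
                raise ValueError("no gene of the supplied set is present in the matrix")
            X = X.subset_genes(present)
        elif X.n_genes > self.n_top_genes:
            var = X.values.var(axis=1)
            top = np.argsort(var)[::-1][: self.n_top_genes]
            X = ExpressionMatrix(
                [X.gene_ids[i] for i in sorted(top)],
                X.sample_ids,
                X.values[np.sort(top)],
            )
        M = X.samples_matrix()
        if self.zscore:
            sd = M.std(axis=0)
            sd[sd == 0] = 1.0
            M = (M - M.mean(axis=0)) / sd
        return M

    def fit(self, X: ExpressionMatrix) -> "ConsensusClusteringResults":
        M = self._features(X)
        report = None
        k = self.k
        if k is None:
            report = silhouette_select_k(M, self.k_candidates, self.seed)
            k = report.chosen_k
        labeling = consensus_cluster(M, k, self.seed)
        sil = (
            float(silhouette_score(M, labeling.consensus, metric="euclidean"))
            if len(np.unique(labeling.consensus)) > 1
            else float("nan")
        )
        return ConsensusClusteringResults(
            model=self, sample_ids=list(X.sample_ids), labeling=labeling,
            k=k, silhouette_report=report, mean_silhouette=sil, features=M,
        )


@dataclass
class ConsensusClusteringResults:
    model: ConsensusClusterer
    sample_ids: list
    labeling: ConsensusLabeling
    k: int
    silhouette_report: Optional[SilhouetteReport]
    mean_silhouette: float
    features: np.ndarray

    @property
    def consensus(self) -> np.ndarray:
        return self.labeling.consensus

    @property
    def agreement(self) -> np.ndarray:
        return self.labeling.agreement

    def to_frame(self):
        return self.labeling.to_frame(self.sample_ids)

    def summary(self) -> str:
        lines = [
            "Consensus subtype clustering (5-voter scoring network)",
            f"  samples: {len(self.sample_ids)}    k: {self.k}",
            f"  mean silhouette of consensus: {self.mean_silhouette:.4f}",
            f"  mean voter agreement: {self.agreement.mean():.3f}",
            f"  ties broken by centroid: {int(self.labeling.tie_broken.sum())}",
        ]
        counts = np.bincount(self.consensus, minlength=self.k)
        lines.append("  cluster sizes: " + ", ".join(f"{j}:{c}" for j, c in enumerate(counts)))
        if self.silhouette_report is not None:
            pairs = zip(self.silhouette_report.k_candidates, self.silhouette_report.mean_silhouette)
            lines.append(
                "  k scan (mean silhouette): "
                + ", ".join(f"k={k}:{s:.3f}" for k, s in pairs)
            )
        return "\n".join(lines)
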