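"""Bootstrap-NMF consensus extraction of mutational signatures.

The pipeline, for a catalog M and a chosen number of signatures N:

1. *Dimension reduction* — drop the largest set of mutation-type rows
   that together account for at most 1% of all mutations.
2. *Bootstrap* — resample each genome's mutations multinomially,
   preserving its total.
3. *NMF* — factorize the bootstrapped matrix by multiplicative updates.
4. *Iterate* — repeat steps 2–3 for I iterations.
5. *Cluster* — partition the I×N signatures into N consensus clusters by
   a k-means variant in which each NMF run's N signatures occupy N
   distinct clusters (optimal one-to-one matching per run under cosine
   similarity); centroids are cluster averages. Exposures follow their
   signatures into the clusters.
6. *Evaluate* — per-cluster and overall average silhouette widths
   (distance = 1 − cosine similarity) measure reproducibility;
   ‖Ṁ − P̄×Ē‖²_F measures reconstruction accuracy.

Signatures in the result are ordered by decreasing reproducibility
(per-cluster silhouette width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_samples

from .catalog import CatalogMatrix
from .nmf import (
    ExposureMatrix,
    NMFConfig,
    SignatureMatrix,
    frobenius_error,
    nmf_multiplicative,
)

__all__ = [
    "DecipherConfig",
    "ReducedCatalog",
    "DecipherResult",
    "reduce_dimensions",
    "bootstrap_catalog",
    "cosine_similarity",
    "cluster_signatures",
    "silhouette_widths",
    "decipher_signatures",
]


@dataclass
class DecipherConfig:
    """Settings for one full decipher run.

    ``I`` is the number of bootstrap-NMF iterations, or ``"auto"`` to add
    batches of ``auto_I_batch`` iterations until the consensus signatures
    stop moving (max centroid shift, measured as 1 − cosine, below
    ``auto_I_tol`` between consecutive batch averages).
    """

    N: int
    I: int | str = 500
    removal_threshold: float = 0.01
    nmf: NMFConfig = field(default_factory=NMFConfig)
    auto_I_batch: int = 100
    auto_I_tol: float = 1e-3
    max_auto_batches: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be ≥ 1")
        if not 0.0 <= self.removal_threshold < 1.0:
            raise ValueError("removal_threshold must be in [0, 1)")
        if self.I != "auto" and (not isinstance(self.I, int) or self.I < 1):
            raise ValueError("I must be a positive integer or 'auto'")


@dataclass
class ReducedCatalog:
    """Catalog after removal of rarely mutated type rows."""

    M_dot: np.ndarray
    kept_rows: np.ndarray
    removed_rows: np.ndarray
    source: CatalogMatrix


@dataclass
class DecipherResult:
    P_bar: SignatureMatrix
    E_bar: ExposureMatrix
    P_sd: np.ndarray  # K×N per-entry SD across cluster members
    per_cluster_silhouette: np.ndarray
    avg_silhouette: float
    reconstruction_error: float
    I_used: int
    cluster_members: np.ndarray  # (I, N) cluster index of each run's signatures
    reduced: ReducedCatalog
    stable: bool = True


def reduce_dimensions(M: CatalogMatrix, threshold: float = 0.01) -> ReducedCatalog:
    """Remove the largest set of mutation-type rows totalling ≤ threshold
    of all mutations.

    Rows are taken in ascending order of their totals; this greedy order
    maximizes the number of removed rows for a given budget. Kept rows
    preserve their original order. Raises if every row would be removed.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    counts = np.asarray(M.counts, dtype=np.float64)
    row_totals = counts.sum(axis=1)
    grand = row_totals.sum()
    if grand <= 0:
        raise ValueError("catalog is empty; nothing to factorize")
    budget = threshold * grand
    order = np.argsort(row_totals, kind="stable")
    removed = []
    acc = 0.0
    for r in order:
        if acc + row_totals[r] <= budget:
            acc += row_totals[r]
            removed.append(r)
        else:
            break
    removed_rows = np.array(sorted(removed), dtype=np.intp)
    kept_rows = np.setdiff1d(np.arange(M.K), removed_rows)
    if kept_rows.size == 0:
        raise ValueError("dimension reduction removed every mutation type")
    return ReducedCatalog(
        M_dot=counts[kept_rows, :], kept_rows=kept_rows, removed_rows=removed_rows, source=M
    )


def bootstrap_catalog(
    M_dot: ReducedCatalog | np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Monte Carlo bootstrap of a catalog, genome by genome.

    Each genome's mutations are redrawn multinomially with type
    probabilities proportional to its observed counts; the genome's total
    is preserved exactly. Zero-total genomes are an error.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = M_dot.M_dot if isinstance(M_dot, ReducedCatalog) else np.asarray(M_dot, dtype=np.float64)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot bootstrap a genome with zero mutations")
    out = np.empty_like(X)
    for g in range(X.shape[1]):
        out[:, g] = rng.multinomial(int(round(totals[g])), X[:, g] / totals[g])
    return out


def cosine_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """Cosine similarity Σ A_k B_k / (‖A‖‖B‖); in [0, 1] for nonnegative
    vectors — 1 for identical signatures, 0 for disjoint ones."""
    A = np.asarray(A, dtype=np.float64).ravel()
    B = np.asarray(B, dtype=np.float64).ravel()
    if A.shape != B.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(A @ B / (na * nb))


def _cosine_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between the columns of X and of Y."""
    Xn = X / np.maximum(np.linalg.norm(X, axis=0), 1e-300)
    Yn = Y / np.maximum(np.linalg.norm(Y, axis=0), 1e-300)
    return Xn.T @ Yn


def cluster_signatures(
    S_P: list[np.ndarray],
    S_E: list[np.ndarray],
    N: int,
    max_rounds: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Consensus-cluster I runs of N signatures into N clusters.

    A k-means variation with the constraint that the N signatures of each
    run are assigned one-to-one to the N clusters (optimal bipartite
    matching maximizing total cosine similarity to the current
    centroids). Centroids are member averages renormalized to sum 1, and
    exposures follow their signatures. Initialized from the first run's
    signatures; deterministic. Returns (centroids K̇×N, exposure
    centroids N×G, memberships (I, N), converged flag).
    """
    I = len(S_P)
    if I == 0:
        raise ValueError("no NMF iterations to cluster")
    if any(P.shape[1] != N for P in S_P):
        raise ValueError("every signature matrix must have exactly N columns")
    centroids = S_P[0].astype(np.float64).copy()
    assign = np.zeros((I, N), dtype=np.intp)  # assign[i, n] = cluster of run i's column n
    converged = False
    for round_idx in range(max_rounds):
        new_assign = np.empty_like(assign)
        for i in range(I):
            sim = _cosine_matrix(S_P[i], centroids)  # N columns × N centroids
            rows, cols = linear_sum_assignment(-sim)
            new_assign[i, rows] = cols
        if round_idx > 0 and np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        for c in range(N):
            members = [S_P[i][:, n] for i in range(I) for n in range(N) if assign[i, n] == c]
            m = np.mean(members, axis=0)
            s = m.sum()
            centroids[:, c] = m / s if s > 0 else m
    exposure_centroids = np.zeros((N, S_E[0].shape[1]))
    for c in range(N):
        rows = [S_E[i][n, :] for i in range(I) for n in range(N) if assign[i, n] == c]
        exposure_centroids[c, :] = np.mean(rows, axis=0)
    return centroids, exposure_centroids, assign, converged


def silhouette_widths(
    vectors: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Average silhouette width per cluster and overall, with distance
    1 − cosine similarity.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)), where a is the mean distance
    to the point's own cluster and b the mean distance to the nearest
    other cluster. Requires ≥ 2 clusters with ≥ 2 members each.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette width requires at least two clusters")
    if np.min(np.bincount(np.searchsorted(uniq, labels))) < 2:
        raise ValueError("silhouette width requires ≥ 2 members per cluster")
    D = 1.0 - _cosine_matrix(vectors.T, vectors.T)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    s = silhouette_samples(D, labels, metric="precomputed")
    per_cluster = np.array([s[labels == c].mean() for c in uniq])
    return per_cluster, float(s.mean())


def decipher_signatures(M: CatalogMatrix, cfg: DecipherConfig) -> DecipherResult:
    """Run the full six-step extraction on a catalog at rank ``cfg.N``.

    Consensus signatures are expanded back to the full alphabet with
    zeros at the removed rows (preserving unit column sums), per-entry
    SDs are taken across each cluster's members, exposures are the means
    of each cluster's (product-preserving rescaled) exposure rows, and
    clusters are ordered by decreasing silhouette width. The
    reconstruction error is measured against the reduced matrix Ṁ — the
    matrix actually factorized; it differs from the full-matrix error by
    at most the removal threshold's worth of mutations.
    """
    reduced = reduce_dimensions(M, cfg.removal_threshold)
    Kdot, G = reduced.M_dot.shape
    N = cfg.N
    if N > min(Kdot, G):
        raise ValueError(f"N={N} exceeds min(K̇={Kdot}, G={G})")
    ss = np.random.SeedSequence(cfg.seed)

    S_P: list[np.ndarray] = []
    S_E: list[np.ndarray] = []

    def run_batch(count: int) -> None:
        for child in ss.spawn(count):
            rng = np.random.default_rng(child)
            Mb = bootstrap_catalog(reduced, rng)
            P, E, _ = nmf_multiplicative(Mb, N, cfg.nmf, rng=rng)
            S_P.append(P.P)
            S_E.append(E.E)

    if N == 1:
        # rank-1 consensus: single signature ∝ normalized row sums
        run_batch(cfg.auto_I_batch if cfg.I == "auto" else int(cfg.I))
        centroids = np.mean(S_P, axis=0)
        centroids /= centroids.sum(axis=0)
        exposure_centroids = np.mean(S_E, axis=0)
        assign = np.zeros((len(S_P), 1), dtype=np.intp)
        per_cluster = np.array([1.0])  # convention: no second cluster exists
        avg_sil = 1.0
        stable = True
    else:
        if cfg.I == "auto":
            prev_centroids = None
            stable_auto = False
            for _ in range(cfg.max_auto_batches):
                run_batch(cfg.auto_I_batch)
                centroids, exposure_centroids, assign, _conv = cluster_signatures(S_P, S_E, N)
                if prev_centroids is not None:
                    sim = _cosine_matrix(prev_centroids, centroids)
                    rows, cols = linear_sum_assignment(-sim)
                    if (1.0 - sim[rows, cols]).max() < cfg.auto_I_tol:
                        stable_auto = True
                        break
                prev_centroids = centroids.copy()
            stable = stable_auto
        else:
            run_batch(int(cfg.I))
            centroids, exposure_centroids, assign, stable = cluster_signatures(S_P, S_E, N)

        all_vectors = np.vstack([P.T for P in S_P])  # (I*N, K̇) points
        all_labels = assign.ravel()
        per_cluster, avg_sil = silhouette_widths(all_vectors, all_labels)

    I_used = len(S_P)

    # order clusters by decreasing reproducibility
    order = np.argsort(-per_cluster, kind="stable")
    centroids = centroids[:, order]
    exposure_centroids = exposure_centroids[order, :]
    per_cluster = per_cluster[order]
    relabel = np.empty(N, dtype=np.intp)
    relabel[order] = np.arange(N)
    assign = relabel[assign]

    # per-entry SD across cluster members, in reduced space
    sd_reduced = np.zeros((Kdot, N))
    for c in range(N):
        members = [S_P[i][:, n] for i in range(I_used) for n in range(N) if assign[i, n] == c]
        if len(members) > 1:
            sd_reduced[:, c] = np.std(np.column_stack(members), axis=1, ddof=0)

    recon = frobenius_error(reduced.M_dot, centroids, exposure_centroids)

    K = M.K
    P_full = np.zeros((K, N))
    P_full[reduced.kept_rows, :] = centroids
    sd_full = np.zeros((K, N))
    sd_full[reduced.kept_rows, :] = sd_reduced

    names = [f"S{i + 1}" for i in range(N)]
    return DecipherResult(
        P_bar=SignatureMatrix(P=P_full, names=names, alphabet=M.alphabet),
        E_bar=ExposureMatrix(E=exposure_centroids, names=names, samples=list(M.samples)),
        P_sd=sd_full,
        per_cluster_silhouette=per_cluster,
        avg_silhouette=float(avg_sil),
        reconstruction_error=recon,
        I_used=I_used,
        cluster_members=assign,
        reduced=reduced,
        stable=bool(stable),
    )
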