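"""De novo mutational signature extraction and exposure refitting.

Extraction uses nonnegative matrix factorization minimizing generalized
Kullback-Leibler divergence with multiplicative updates (the Brunet variant),
best-of-n random restarts. Refitting solves, per sample, a nonnegative least
squares problem (the quadratic-programming formulation of signature
attribution). Bootstrap confidence intervals resample each sample's
mutations over channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment, nnls
from scipy.spatial.distance import squareform

from .channels import ChannelMatrix

__all__ = [
    "SignatureSet",
    "ExposureMatrix",
    "RankDiagnostics",
    "nmf_extract",
    "rank_survey",
    "cosine_similarity",
    "profile_mds",
    "hier_cluster",
    "dendrogram_to_newick",
    "refit_exposures",
    "bootstrap_exposures",
    "match_signatures",
]

_EPS = np.finfo(float).tiny


@dataclass
class SignatureSet:
    """K nonnegative per-channel profiles, each column summing to 1."""

    scheme: str
    profiles: pd.DataFrame  # channels x K

    def __post_init__(self):
        cols = self.profiles.sum(axis=0)
        if not np.allclose(cols, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1")

    @property
    def K(self) -> int:
        return self.profiles.shape[1]

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="channel")


@dataclass
class ExposureMatrix:
    """Samples x K nonnegative signature contributions (mutation counts)."""

    exposures: pd.DataFrame

    def fractions(self) -> pd.DataFrame:
        totals = self.exposures.sum(axis=1)
        return self.exposures.div(totals.where(totals > 0, np.nan), axis=0)

    def to_tsv(self, path) -> None:
        self.exposures.to_csv(path, sep="\t", index_label="sample")


@dataclass
class RankDiagnostics:
    """Per-candidate-rank fit diagnostics across restarts."""

    table: pd.DataFrame  # index K; columns rss, explained_variance, cophenetic


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _nmf_mu_kl(V, K, rng, max_iter=500, tol=1e-6):
    """Multiplicative-update KL NMF; returns W, H, objective trace."""
    n, m = V.shape
    avg = np.sqrt(V.mean() / K)
    W = avg * rng.random((n, K)) + _EPS
    H = avg * rng.random((K, m)) + _EPS
    prev = np.inf
    trace = []
    for _ in range(max_iter):
        WH = W @ H
        W *= ((V / np.maximum(WH, _EPS)) @ H.T) / np.maximum(H.sum(axis=1), _EPS)
        WH = W @ H
        H *= (W.T @ (V / np.maximum(WH, _EPS))) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        obj = _kl_divergence(V, W @ H)
        trace.append(obj)
        if obj > prev + 1e-8 * max(1.0, abs(prev)):
            raise AssertionError("KL objective increased during multiplicative updates")
        if prev - obj < tol * max(1.0, abs(prev)):
            break
        prev = obj
    return W, H, np.array(trace)


def nmf_extract(
    matrix: ChannelMatrix,
    K: int,
    n_runs: int = 50,
    seed: int | None = None,
    objective: str = "kl",
    max_iter: int = 500,
) -> tuple[SignatureSet, ExposureMatrix, float]:
    """Extract K signatures from a channel matrix; best of ``n_runs`` random
    initializations. Signatures are column-normalized with exposures rescaled
    so the reconstruction is unchanged."""
    if seed is None:
        raise ValueError("seed is mandatory")
    counts = matrix.counts
    nonzero = counts.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"excluding {int((~nonzero).sum())} all-zero samples from NMF")
        counts = counts.loc[nonzero]
    V = counts.to_numpy(dtype=float).T  # channels x samples
    if K > min(V.shape):
        raise ValueError(f"K={K} exceeds min(channels, samples)={min(V.shape)}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_runs):
        if objective == "kl":
            W, H, _ = _nmf_mu_kl(V, K, rng, max_iter=max_iter)
            obj = _kl_divergence(V, W @ H)
        elif objective == "frobenius":
            W, H = _nmf_mu_frobenius(V, K, rng, max_iter=max_iter)
            obj = float(((V - W @ H) ** 2).sum())
        else:
            raise ValueError(f"unknown objective {objective!r}")
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, obj = best
    scale = W.sum(axis=0)
    W = W / np.maximum(scale, _EPS)
    H = H * scale[:, None]
    sig_names = [f"S{i + 1}" for i in range(K)]
    sigs = SignatureSet(
        scheme=matrix.scheme,
        profiles=pd.DataFrame(W, index=counts.columns, columns=sig_names),
    )
    expo = ExposureMatrix(pd.DataFrame(H.T, index=counts.index, columns=sig_names))
    return sigs, expo, obj


def _nmf_mu_frobenius(V, K, rng, max_iter=500, tol=1e-6):
    n, m = V.shape
    avg = np.sqrt(V.mean() / K)
    W = avg * rng.random((n, K)) + _EPS
    H = avg * rng.random((K, m)) + _EPS
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
        W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        obj = float(((V - W @ H) ** 2).sum())
        if prev - obj < tol * max(1.0, prev):
            break
        prev = obj
    return W, H


def rank_survey(
    matrix: ChannelMatrix,
    K_range,
    n_runs: int = 20,
    seed: int | None = None,
) -> RankDiagnostics:
    """Fit repeatedly at each candidate rank, reporting best-of-restarts RSS,
    explained variance, and the cophenetic coefficient of the restart
    consensus matrix (sample co-assignment stability, Brunet style)."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be nonempty")
    if seed is None:
        raise ValueError("seed is mandatory")
    V = matrix.counts.to_numpy(dtype=float).T
    ss_tot = float(((V - V.mean()) ** 2).sum())
    rows = []
    rng = np.random.default_rng(seed)
    for K in K_range:
        best_rss = np.inf
        consensus = np.zeros((V.shape[1], V.shape[1]))
        for _ in range(n_runs):
            W, H, _ = _nmf_mu_kl(V, K, rng)
            rss = float(((V - W @ H) ** 2).sum())
            best_rss = min(best_rss, rss)
            assign = H.argmax(axis=0)
            consensus += assign[:, None] == assign[None, :]
        consensus /= n_runs
        coph = _cophenetic_coefficient(consensus)
        rows.append(
            {"K": K, "rss": best_rss,
             "explained_variance": 1.0 - best_rss / ss_tot,
             "cophenetic": coph}
        )
    return RankDiagnostics(pd.DataFrame(rows).set_index("K"))


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        return 1.0
    Z = hierarchy.linkage(condensed, method="average")
    coph, _ = hierarchy.cophenet(Z, condensed)
    return float(coph)


def cosine_similarity(p, q) -> float:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must share a scheme (same length)")
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(p, q) / (np_ * nq))


def _cosine_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(profiles, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero profile in distance computation")
    sim = (profiles @ profiles.T) / np.outer(norms, norms)
    return np.clip(1.0 - sim, 0.0, None)


def profile_mds(profiles, method: str = "torgerson") -> np.ndarray:
    """2-D embedding of profiles from pairwise cosine distances.

    ``torgerson``: classical scaling (double-centered squared-distance
    eigendecomposition). ``pca``: principal components of the raw distance
    matrix rows, the alternate convention some pipelines use."""
    P = np.asarray(profiles, dtype=float)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 profiles")
    D = _cosine_distance_matrix(P)
    if np.allclose(D, 0.0):
        warnings.warn("all profiles identical; MDS collapses to the origin")
        return np.zeros((P.shape[0], 2))
    if method == "torgerson":
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][:2]
        lam = np.maximum(vals[order], 0.0)
        return vecs[:, order] * np.sqrt(lam)
    elif method == "pca":
        Dc = D - D.mean(axis=0)
        _, _, Vt = np.linalg.svd(Dc, full_matrices=False)
        return Dc @ Vt[:2].T
    raise ValueError(f"unknown MDS method {method!r}")


def hier_cluster(profiles, names, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of profiles on cosine distance; returns the
    scipy linkage matrix (see :func:`dendrogram_to_newick` for export)."""
    P = np.asarray(profiles, dtype=float)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if len(names) != P.shape[0]:
        raise ValueError("one name per profile required")
    D = _cosine_distance_matrix(P)
    return hierarchy.linkage(squareform(D, checks=False), method=linkage)


def dendrogram_to_newick(Z: np.ndarray, names) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def refit_exposures(matrix: ChannelMatrix, signatures: SignatureSet) -> tuple[ExposureMatrix, pd.Series]:
    """Fixed-signature exposure estimation: per sample solve
    min ||m - S x||^2 subject to x >= 0. Returns exposures and residual norms."""
    if signatures.scheme != matrix.scheme:
        raise ValueError("signature scheme does not match matrix scheme")
    S = signatures.profiles.to_numpy(dtype=float)
    rows, resid = [], []
    for _, m in matrix.counts.iterrows():
        x, r = nnls(S, m.to_numpy(dtype=float))
        rows.append(x)
        resid.append(r)
    expo = pd.DataFrame(rows, index=matrix.counts.index, columns=signatures.profiles.columns)
    return ExposureMatrix(expo), pd.Series(resid, index=matrix.counts.index, name="residual")


def bootstrap_exposures(
    sample_counts: pd.Series,
    signatures: SignatureSet,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Percentile confidence intervals for one sample's signature fractions,
    resampling its mutations multinomially over channels and refitting each
    replicate."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory")
    counts = sample_counts.to_numpy(dtype=float)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty sample")
    p = counts / counts.sum()
    S = signatures.profiles.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    fracs = np.empty((n_boot, S.shape[1]))
    for b in range(n_boot):
        resampled = rng.multinomial(n, p).astype(float)
        x, _ = nnls(S, resampled)
        tot = x.sum()
        fracs[b] = x / tot if tot > 0 else 0.0
    x0, _ = nnls(S, counts)
    point = x0 / x0.sum() if x0.sum() > 0 else np.zeros(S.shape[1])
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(fracs, alpha, axis=0)
    hi = np.quantile(fracs, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {"fraction": point, "ci_low": lo, "ci_high": hi},
        index=signatures.profiles.columns,
    )


def match_signatures(est: pd.DataFrame, truth: pd.DataFrame) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Hungarian matching of estimated to true signatures on cosine
    similarity; returns matched name pairs and their similarities."""
    E = est.to_numpy(dtype=float).T
    T = truth.to_numpy(dtype=float).T
    sim = np.zeros((E.shape[0], T.shape[0]))
    for i, e in enumerate(E):
        for j, t in enumerate(T):
            sim[i, j] = cosine_similarity(e, t)
    ri, ci = linear_sum_assignment(-sim)
    pairs = [(est.columns[i], truth.columns[j]) for i, j in zip(ri, ci)]
    return pairs, sim[ri, ci]
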