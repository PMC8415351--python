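"""Cluster analysis of time evolution (CAT).

Voxels with similar magnitude decay shapes are grouped before model
fitting, which raises the effective SNR of the inverse problem: the
cluster-mean signal is fit once and its parameters seed every member
voxel.  Features are the G-corrected, first-echo-normalized log decays,

    f_j = ln[ (S(t_j)/G(t_j)) / (S(t_1)/G(t_1)) ],

so a pure exponential voxel maps to the line -R2*(t_j - t_1) and the
arbitrary scale S0 drops out.

The number of clusters is chosen by X-means: recursive 2-means splits,
each accepted only if the Bayesian information criterion (BIC) of the
two-cluster model on the parent's points beats the one-cluster model.
The BIC uses the hard-assignment spherical-Gaussian likelihood with
pooled variance MLE sigma^2 = sum ||x_i - mu_c(i)||^2 / (d (N - K)) and
p = (K - 1) + d*K + 1 free parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import EchoSeries, MacroFieldModel, g_macro

__all__ = [
    "DecayFeatureSet",
    "ClusterModel",
    "decay_features",
    "kmeans_fit",
    "bic_score",
    "xmeans",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass
class DecayFeatureSet:
    """Per-voxel decay-shape features with a map back to volume coordinates."""

    features: np.ndarray          # (n_voxels, n_te)
    voxel_index: np.ndarray       # (n_voxels, ndim) integer coordinates
    dropped: int = 0              # voxels excluded for nonpositive magnitudes


@dataclass
class ClusterModel:
    """Hard partition of voxels into K decay clusters."""

    K: int
    centroids: np.ndarray         # (K, d)
    assignment: np.ndarray        # (n_voxels,) labels in [0, K)
    bic: float
    seed: int
    voxel_index: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        labels = np.unique(self.assignment)
        if labels.min() < 0 or labels.max() >= self.K:
            raise ValueError("assignment labels must lie in [0, K)")


def decay_features(echoes: EchoSeries, gmodel: MacroFieldModel | None = None,
                   brain_mask: np.ndarray | None = None) -> DecayFeatureSet:
    """Build normalized log-decay features for every brain voxel.

    ``echoes.magnitudes`` may be a 4-D volume (x, y, z, echo) with a 3-D
    ``brain_mask``, or already a 2-D (n_voxels, n_te) array (mask omitted).
    Voxels with a nonpositive magnitude at any echo are dropped and counted.
    """
    if gmodel is None:
        gmodel = MacroFieldModel()
    mags = echoes.magnitudes
    if mags.ndim == 2 and brain_mask is None:
        data = mags
        coords = np.arange(len(data))[:, None]
    else:
        if brain_mask is None:
            raise ValueError("brain_mask required for volumetric magnitudes")
        brain_mask = np.asarray(brain_mask, dtype=bool)
        data = mags[brain_mask]          # (n_voxels, n_te)
        coords = np.argwhere(brain_mask)
    g = g_macro(gmodel, echoes.echo_times)
    corrected = data / np.asarray(g)[None, :]
    good = np.all(corrected > 0, axis=1)
    dropped = int((~good).sum())
    if dropped:
        logger.info("decay_features: dropped %d voxels with nonpositive magnitude", dropped)
    logs = np.log(corrected[good])
    feats = logs - logs[:, :1]
    return DecayFeatureSet(features=feats, voxel_index=coords[good], dropped=dropped)


# ----------------------------------------------------------------------
# seeded k-means (Lloyd + k-means++), with the deterministic contracts
# the recursion relies on: nearest-centroid ties break to the lowest
# centroid index, empty clusters are re-seeded at the farthest point.
# ----------------------------------------------------------------------

def _kmeanspp_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centroids = np.empty((K, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centroids[k:] = X[rng.integers(n, size=K - k)]
            break
        probs = d2 / total
        centroids[k] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centroids[k]) ** 2, axis=1))
    return centroids


def kmeans_fit(features: np.ndarray, K: int, seed: int,
               max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Lloyd k-means from k-means++ initialization.

    Returns (centroids, assignment).  Deterministic under ``seed``.
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if not 1 <= K <= n:
        raise ValueError(f"K must lie in [1, {n}], got {K}")
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(X, K, rng)
    assignment = np.full(n, -1)
    for _ in range(max_iter):
        # argmin breaks ties toward the lowest centroid index
        d2 = np.sum((X[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        new_assignment = np.argmin(d2, axis=1)
        for k in range(K):
            members = new_assignment == k
            if not members.any():
                far = int(np.argmax(d2[np.arange(n), new_assignment]))
                centroids[k] = X[far]
                new_assignment[far] = k
                logger.debug("kmeans: re-seeded empty cluster %d at farthest point", k)
                members = new_assignment == k
            centroids[k] = X[members].mean(axis=0)
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
    return centroids, assignment


def bic_score(features: np.ndarray, centroids: np.ndarray,
              assignment: np.ndarray) -> float:
    """BIC of a hard-assignment spherical-Gaussian clustering.

    Higher is better.  Undefined (raises) when N <= K.
    """
    X = np.asarray(features, dtype=float)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    assignment = np.asarray(assignment)
    n, d = X.shape
    K = len(centroids)
    if n <= K:
        raise ValueError(f"BIC undefined for N = {n} <= K = {K}")
    resid2 = np.sum((X - centroids[assignment]) ** 2)
    sigma2 = max(resid2 / (d * (n - K)), _VAR_FLOOR)
    counts = np.bincount(assignment, minlength=K).astype(float)
    counts = counts[counts > 0]
    loglik = (
        float(np.sum(counts * np.log(counts / n)))
        - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
        - 0.5 * d * (n - K)
    )
    p = (K - 1) + d * K + 1
    return loglik - 0.5 * p * np.log(n)


def _child_seed(seed: int, label: int) -> int:
    # deterministic, collision-spread derivation; kept below 2**31
    return int((seed * 1_000_003 + 7919 * (label + 1)) % 2_147_483_647)


def _bic_full(pts: np.ndarray, assignment: np.ndarray, K: int) -> float:
    """Full-covariance hard-assignment Gaussian BIC (higher is better).

    Used for the X-means split decision: decay features carry strongly
    correlated noise (every component shares the first-echo term), and a
    spherical criterion would split homogeneous clusters along the
    correlated directions.  The full-covariance likelihood is affine
    invariant, so only genuine multi-modality (large Mahalanobis
    separation) justifies a split.  Requires each cluster to have at
    least d + 2 members; returns -inf when degenerate.
    """
    n, d = pts.shape
    loglik = 0.0
    for k in range(K):
        members = pts[assignment == k]
        n_k = len(members)
        if n_k < d + 2:
            return -np.inf
        cov = np.cov(members, rowvar=False, ddof=0)
        cov = np.atleast_2d(cov) + np.eye(d) * max(np.trace(np.atleast_2d(cov)), 1.0) * 1e-10
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return -np.inf
        loglik += n_k * (np.log(n_k / n)
                         - 0.5 * (d * np.log(2.0 * np.pi) + logdet + d))
    p = (K - 1) + K * (d + d * (d + 1) / 2)
    return loglik - 0.5 * p * np.log(n)


def xmeans(features: np.ndarray, k_max: int = 50, seed: int = 0,
           min_split_size: int = 4) -> ClusterModel:
    """X-means: BIC-guided recursive 2-means splitting, starting at K = 1.

    Each cluster is split by a seeded 2-means (best of a few seeded
    restarts) on its own points; the split is kept iff the local
    full-covariance BIC of the two-cluster model beats the one-cluster
    model.  Degenerate directions (the identically-zero first feature)
    are dropped locally before the decision.  Stops when no split is
    accepted or ``k_max`` is reached.
    """
    X = np.asarray(features, dtype=float)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = len(X)
    centroids = [X.mean(axis=0)]
    assignment = np.zeros(n, dtype=int)
    cluster_seeds = {0: int(seed) % 2_147_483_647}

    improved = True
    while improved and len(centroids) < k_max:
        improved = False
        for label in sorted(cluster_seeds):
            if len(centroids) >= k_max:
                break
            members = np.flatnonzero(assignment == label)
            if len(members) < min_split_size:
                continue
            pts = X[members]
            # drop globally degenerate directions (zero spread within cluster)
            spread = pts.std(axis=0)
            live = spread > max(float(spread.max()), 0.0) * 1e-9
            if not live.any():
                continue                      # identical points: nothing to split
            local = pts[:, live]
            child_seed = _child_seed(cluster_seeds[label], label)
            parent_bic = _bic_full(local, np.zeros(len(local), dtype=int), 1)
            # a single 2-means try can land in a poor partition; take the
            # best of a few seeded restarts (deterministic)
            split_bic, child_assign = -np.inf, None
            for trial in range(3):
                _, ca = kmeans_fit(local, 2, _child_seed(child_seed, 100 + trial))
                if len(np.unique(ca)) < 2:
                    continue
                trial_bic = _bic_full(local, ca, 2)
                if trial_bic > split_bic:
                    split_bic, child_assign = trial_bic, ca
            if child_assign is None or len(pts) <= 2:
                continue
            if parent_bic == -np.inf and split_bic == -np.inf:
                # too small / duplicated for the full model: fall back to the
                # spherical criterion on the live directions
                parent_bic = bic_score(local, local.mean(axis=0)[None, :],
                                       np.zeros(len(local), dtype=int))
                cent2 = np.array([local[child_assign == 0].mean(axis=0),
                                  local[child_assign == 1].mean(axis=0)])
                split_bic = bic_score(local, cent2, child_assign)
            if split_bic > parent_bic:
                child_cent = np.array([pts[child_assign == 0].mean(axis=0),
                                       pts[child_assign == 1].mean(axis=0)])
                new_label = len(centroids)
                centroids[label] = child_cent[0]
                centroids.append(child_cent[1])
                assignment[members[child_assign == 1]] = new_label
                cluster_seeds[label] = _child_seed(child_seed, 0)
                cluster_seeds[new_label] = _child_seed(child_seed, 1)
                improved = True

    centroids_arr = np.array(centroids)
    final_bic = bic_score(X, centroids_arr, assignment) if n > len(centroids) else float("nan")
    return ClusterModel(K=len(centroids), centroids=centroids_arr,
                        assignment=assignment, bic=final_bic, seed=int(seed))
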