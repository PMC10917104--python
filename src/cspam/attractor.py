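"""Attractor-metagene (AM) feature weighting, ranking and minimal-k subset
selection.

The AM algorithm is unsupervised: starting from random nonnegative weights w
over the p features, it iterates

    M   <- w G                       (the "metagene": a weighted feature mix)
    w_j <- NMI(M, G_j)^alpha   if Pearson(M, G_j) > 0, else 0

until the largest weight change drops below a tolerance.  Features that
co-vary strongly (by normalized mutual information) with the emergent
attractor keep high weights; anti- or un-correlated features are driven to
zero.  The exponent alpha sharpens the attractor: larger alpha concentrates
weight on the dominant feature cluster.

The final weights are used only for *ranking*; a downstream classifier then
searches k = 1..p prefixes of the ranked list and keeps the smallest k that
attains the best training fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 5.0
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100


class DegenerateAttractorError(RuntimeError):
    """All weights collapsed to zero (no feature positively correlated)."""


@dataclass
class AMRanking:
    """Converged attractor weights and the descending-weight feature order."""

    weights: np.ndarray          # (p,), values in [0, 1]
    order: np.ndarray            # permutation of 0..p-1, descending weight
    iterations_used: int
    converged: bool
    alpha: float
    seed: int | None


@dataclass
class SubsetSelection:
    """Smallest ranked-prefix size k attaining the best classifier score."""

    k: int
    indices: np.ndarray          # first k entries of AMRanking.order
    score: float
    scores_by_k: np.ndarray      # score at every candidate k (NaN = failed fit)


# ---------------------------------------------------------------------------
# Normalized mutual information
# ---------------------------------------------------------------------------

def _n_bins(n: int) -> int:
    return max(2, int(np.floor(np.sqrt(n / 5.0))))


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to an equal-frequency (quantile) bin."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def normalized_mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int | None = None
) -> float:
    """Histogram NMI in [0, 1], symmetric in its arguments.

    Both variables are discretized into B = max(2, floor(sqrt(n/5)))
    equal-frequency bins; mutual information of the joint histogram is
    normalized by min(H(X), H(Y)), which bounds the value by 1.  A constant
    input has zero entropy and returns 0 (with a warning).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 4:
        raise InvalidInputError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input to NMI; returning 0")
        return 0.0
    B = n_bins or _n_bins(x.size)
    bx = _equal_freq_bins(x, B)
    by = _equal_freq_bins(y, B)
    joint = np.zeros((B, B))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    hx = -float(np.sum(px[px > 0] * np.log(px[px > 0])))
    hy = -float(np.sum(py[py > 0] * np.log(py[py > 0])))
    h_min = min(hx, hy)
    if h_min <= 0:
        logger.warning("degenerate binning in NMI; returning 0")
        return 0.0
    return float(np.clip(mi / h_min, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Attractor iteration
# ---------------------------------------------------------------------------

def am_weights(
    G: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    init: str = "random",
) -> AMRanking:
    """Iterate the attractor-metagene update to convergence.

    Parameters
    ----------
    G
        Feature matrix, features (p) x samples (n).
    alpha
        Nonnegative exponent applied to the NMI similarity.
    tol
        Convergence threshold on the max absolute weight change.
    max_iter
        Iteration cap; ``converged`` is False if reached.
    seed
        Seeds the random weight initialization.
    init
        ``"random"`` (uniform(0,1) normalized to sum 1) or ``"equal"``
        (deterministic all-equal start).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 1 or G.shape[1] < 2:
        raise InvalidInputError("G must be p x n with p >= 1, n >= 2")
    if alpha < 0 or tol <= 0 or max_iter < 1:
        raise InvalidInputError("require alpha >= 0, tol > 0, max_iter >= 1")
    p, n = G.shape

    rng = np.random.default_rng(seed)
    if init == "random":
        w = rng.uniform(0.0, 1.0, size=p)
        w /= w.sum()
    elif init == "equal":
        w = np.full(p, 1.0 / p)
    else:
        raise InvalidInputError(f"unknown init {init!r}")

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = w @ G
        if np.ptp(M) == 0:
            raise DegenerateAttractorError(
                f"metagene constant at iteration {it}: weights collapsed"
            )
        w_new = np.zeros(p)
        Mc = M - M.mean()
        m_norm = np.sqrt(np.sum(Mc**2))
        for j in range(p):
            gj = G[j]
            gc = gj - gj.mean()
            g_norm = np.sqrt(np.sum(gc**2))
            if g_norm == 0 or m_norm == 0:
                continue
            r = float(np.dot(Mc, gc) / (m_norm * g_norm))
            if r > 0:
                w_new[j] = normalized_mutual_information(M, gj) ** alpha
        if not np.any(w_new > 0):
            raise DegenerateAttractorError(
                f"all weights zero at iteration {it}: no positively "
                "correlated feature"
            )
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        if delta < tol:
            converged = True
            break

    order = rank_features(w)
    return AMRanking(
        weights=w,
        order=order,
        iterations_used=it,
        converged=converged,
        alpha=alpha,
        seed=seed,
    )


def rank_features(weights: np.ndarray) -> np.ndarray:
    """Indices sorting weights descending; ties broken by ascending index."""
    w = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise InvalidInputError("weights must be finite and nonnegative")
    # stable sort on -w keeps ascending index order within ties
    return np.argsort(-w, kind="stable")


# ---------------------------------------------------------------------------
# Minimal-k incremental subset selection
# ---------------------------------------------------------------------------

def incremental_subset_selection(
    G_ranked: np.ndarray,
    labels: np.ndarray,
    classifier_factory,
    order: np.ndarray | None = None,
) -> SubsetSelection:
    """Search k = 1..p ranked-feature prefixes; keep the smallest best k.

    ``G_ranked`` is features x samples, already in rank order (or pass
    ``order`` to apply a ranking).  For each k a fresh classifier from
    ``classifier_factory()`` is fit on the first k features and scored by
    training accuracy; the smallest k attaining the maximum score wins.
    Failed fits at individual k are skipped with a warning.
    """
    G = np.asarray(G_ranked, dtype=float)
    if order is not None:
        G = G[np.asarray(order)]
    labels = np.asarray(labels)
    p, n = G.shape
    if labels.size != n:
        raise InvalidInputError("labels length must match sample count")

    scores = np.full(p, np.nan)
    for k in range(1, p + 1):
        X = G[:k].T
        try:
            clf = classifier_factory()
            clf.fit(X, labels)
            scores[k - 1] = float(np.mean(clf.predict(X) == labels))
        except Exception as exc:  # pragma: no cover - classifier-dependent
            logger.warning("subset fit failed at k=%d: %s", k, exc)
    if np.all(np.isnan(scores)):
        raise RuntimeError("classifier failed at every subset size")

    best = np.nanmax(scores)
    k_best = int(np.nanargmax(scores)) + 1  # first (=smallest) k at the max
    idx = (np.asarray(order) if order is not None else np.arange(p))[:k_best]
    return SubsetSelection(
        k=k_best, indices=np.asarray(idx), score=float(best), scores_by_k=scores
    )
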