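"""Common spatial pattern estimation and log-variance feature extraction.

For a two-class problem, CSP finds spatial filters w maximizing the variance
ratio between the classes: generalized eigenvectors of

    S_x w = lambda (S_x + S_y) w,

where S_x, S_y are the class-average trace-normalized trial covariance
matrices.  lambda in (0, 1) is the fraction of composite variance captured
for class x; the eigenvalue of S_y under the same (composite-whitened) filter
is 1 - lambda.  Filters from both ends of the spectrum are discriminative:
high lambda -> high variance for class x, low lambda -> high variance for
class y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .preprocess import InvalidInputError

logger = logging.getLogger(__name__)

#: Floor applied to composite-covariance eigenvalues during whitening.
WHITEN_EIG_FLOOR = 1e-12
#: Ridge added (relative to trace) when the composite covariance is
#: numerically rank deficient.
RIDGE_REL = 1e-8


@dataclass
class CSPModel:
    """Fitted spatial filters for one class pair in one frequency band.

    ``filters`` has 2m rows (m = ``n_pairs``): rows 0..m-1 are the top-m
    generalized eigenvectors (largest lambda), rows m..2m-1 the bottom-m, with
    eigenvalues in strictly descending order across all rows.  ``patterns``
    holds the corresponding spatial patterns (columns of the inverse of the
    full filter matrix, transposed to rows) — the channel-space footprint of
    each filtered component.
    """

    band: tuple[float, float] | None
    filters: np.ndarray          # (2m, n_channels)
    eigenvalues: np.ndarray      # (2m,), descending, in (0, 1)
    patterns: np.ndarray         # (2m, n_channels)
    class_pair: tuple[str, str] | None = None

    @property
    def n_pairs(self) -> int:
        return self.filters.shape[0] // 2

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]


def normalized_trial_covariance(E: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance S = E E^T / tr(E E^T) of one trial.

    The output is symmetric PSD with trace exactly 1, making trials
    comparable regardless of their overall amplitude.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise InvalidInputError("E must be channels x samples with >= 2 channels")
    C = E @ E.T
    tr = np.trace(C)
    if tr <= 0 or not np.isfinite(tr):
        raise InvalidInputError("zero-trace covariance: all-zero or invalid trial")
    S = C / tr
    return 0.5 * (S + S.T)


def mean_class_covariance(trial_covs) -> np.ndarray:
    """Elementwise mean of per-trial normalized covariances (trace stays 1)."""
    covs = list(trial_covs)
    if not covs:
        raise InvalidInputError("empty covariance list")
    return np.mean(np.stack(covs, axis=0), axis=0)


def fit_csp_pair(
    S_x: np.ndarray,
    S_y: np.ndarray,
    n_pairs: int = 4,
    band: tuple[float, float] | None = None,
    class_pair: tuple[str, str] | None = None,
) -> CSPModel:
    """Solve S_x w = lambda (S_x + S_y) w and keep n_pairs filters per end.

    The numerical path whitens by the composite covariance (eigendecomposition
    with an eigenvalue floor) and then symmetrically eigendecomposes the
    whitened S_x — stable and equivalent to the generalized problem.  Selected
    filters satisfy W (S_x + S_y) W^T = I.  If the composite is numerically
    rank deficient a small ridge is added and a warning logged.
    """
    S_x = np.asarray(S_x, dtype=float)
    S_y = np.asarray(S_y, dtype=float)
    n_ch = S_x.shape[0]
    if S_x.shape != S_y.shape or S_x.shape != (n_ch, n_ch):
        raise InvalidInputError("covariance shape mismatch")
    if 2 * n_pairs > n_ch:
        raise InvalidInputError(f"2*n_pairs={2 * n_pairs} exceeds {n_ch} channels")

    composite = S_x + S_y
    evals, evecs = linalg.eigh(composite)
    if evals.min() < WHITEN_EIG_FLOOR * evals.max():
        ridge = RIDGE_REL * np.trace(composite)
        logger.warning(
            "composite covariance rank deficient (min eig %.3e); adding ridge %.3e",
            evals.min(), ridge,
        )
        composite = composite + ridge * np.eye(n_ch)
        evals, evecs = linalg.eigh(composite)
    evals = np.maximum(evals, WHITEN_EIG_FLOOR)
    # whitening transform P: P composite P^T = I
    P = (evecs / np.sqrt(evals)).T

    Sw = P @ S_x @ P.T
    lam, U = linalg.eigh(0.5 * (Sw + Sw.T))
    order = np.argsort(lam)[::-1]          # descending lambda
    lam, U = lam[order], U[:, order]

    W_full = U.T @ P                        # full filter matrix, (n_ch, n_ch)
    A_full = linalg.inv(W_full).T           # rows are spatial patterns

    sel = np.r_[np.arange(n_pairs), np.arange(n_ch - n_pairs, n_ch)]
    filters = W_full[sel]
    patterns = A_full[sel]
    # remove sign ambiguity jointly so patterns stay the inverse-transpose rows
    for i, row in enumerate(filters):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            filters[i] = -row
            patterns[i] = -patterns[i]
    return CSPModel(
        band=band,
        filters=filters,
        eigenvalues=np.clip(lam[sel], 0.0, 1.0),
        patterns=patterns,
        class_pair=class_pair,
    )


def csp_features(E: np.ndarray, model: CSPModel) -> np.ndarray:
    """Normalized log-variance features of one band-limited trial.

    f_i = log( var(w_i E) / sum_j var(w_j E) ) over the model's 2m
    components, so sum_i exp(f_i) = 1.  A zero-variance component is floored
    at machine epsilon (warning logged) to keep values finite.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[0] != model.n_channels:
        raise InvalidInputError(
            f"trial has {E.shape[0]} channels, model expects {model.n_channels}"
        )
    Z = model.filters @ E
    v = Z.var(axis=1)
    if np.any(v <= 0):
        logger.warning("zero-variance projected component; flooring at eps")
        v = np.maximum(v, np.finfo(float).eps)
    return np.log(v / v.sum())


def filterbank_features(banded_trial, models) -> np.ndarray:
    """Concatenate per-band CSP features in band order (5 bands x 2m = 40)."""
    models = list(models)
    if len(banded_trial) != len(models):
        raise InvalidInputError(
            f"{len(banded_trial)} band signals but {len(models)} models"
        )
    pair = models[0].class_pair
    for m in models[1:]:
        if m.class_pair != pair:
            raise InvalidInputError("models must share the class pair")
    return np.concatenate([csp_features(E, m) for E, m in zip(banded_trial, models)])
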