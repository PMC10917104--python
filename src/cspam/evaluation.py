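"""Accuracy metrics, permutation significance and band-usage counting.

The permutation test follows the standard fixed-model reading: the trained
model's predictions are held fixed and the true labels are shuffled
``n_perm`` times; the p-value uses the +1-corrected finite-sample formula

    p = (1 + #{null >= observed}) / (1 + n_perm),

which is a valid p-value and can never be exactly zero.  The model is *not*
retrained inside the permutation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import InvalidInputError

DEFAULT_N_PERM = 10_000


@dataclass
class PermutationResult:
    """Observed accuracy against its label-shuffled null distribution."""

    observed: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None

    def significant(self, q: float = 0.05) -> bool:
        """True when the observed accuracy beats the (1-q) null quantile."""
        return self.p_value < q


@dataclass
class BandUsage:
    """Per-band count of features selected into the optimal subsets."""

    bands: list[tuple[float, float]]
    counts: np.ndarray


def accuracy(predicted, true) -> float:
    """Fraction of trials where predicted == true."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size == 0 or predicted.size != true.size:
        raise InvalidInputError("predicted/true must be equal nonzero length")
    return float(np.mean(predicted == true))


def per_class_accuracy(predicted, true) -> dict[str, float]:
    """Recall per class: correct within class / class count."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size != true.size or true.size == 0:
        raise InvalidInputError("predicted/true must be equal nonzero length")
    out = {}
    for c in np.unique(true):
        mask = true == c
        out[str(c)] = float(np.mean(predicted[mask] == c))
    return out


def permutation_test(
    predicted,
    true,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationResult:
    """Nonparametric significance of decoding accuracy by label shuffling.

    For each of ``n_perm`` seeded draws the true labels are permuted and the
    accuracy of the fixed predictions recomputed; the observed accuracy is
    significant at level q iff it exceeds the (1-q) null quantile,
    equivalently p < q.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size != true.size or true.size < 2:
        raise InvalidInputError("predicted/true must be equal length >= 2")
    if n_perm < 100:
        raise InvalidInputError("n_perm must be >= 100")
    obs = accuracy(predicted, true)
    rng = np.random.default_rng(seed)
    n = true.size
    # one shuffled copy of the labels per permutation, accuracy vectorized
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    null = (true[perm_idx] == predicted[None, :]).mean(axis=1)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return PermutationResult(
        observed=obs, null_accuracies=null, p_value=float(p),
        n_perm=n_perm, seed=seed,
    )


def band_selection_counts(model, bands=None) -> BandUsage:
    """How often each band's features entered the optimal subsets.

    Counts, per frequency band, the selected feature indices falling in that
    band's contiguous block of the concatenated layout, summed over the
    model's pair models.  At defaults (5 bands x 4 filter pairs x 3 pairs)
    each count lies in [0, 24].
    """
    pair_models = model.pair_models
    n_bands = len(pair_models[0].csp_models)
    block = pair_models[0].n_features // n_bands
    counts = np.zeros(n_bands, dtype=int)
    for pm in pair_models:
        for idx in pm.subset.indices:
            counts[int(idx) // block] += 1
    band_edges = bands or [m.band for m in pair_models[0].csp_models]
    return BandUsage(bands=list(band_edges), counts=counts)
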