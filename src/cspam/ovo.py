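"""One-versus-one decomposition, per-pair CSP-AM training, temporally ordered
splitting and single-trial prediction with vote / confidence aggregation.

Each unordered class pair gets its own model: per-band CSP filters, a
40-dimensional filter-bank feature layout, an attractor-metagene ranking, the
minimal best-fit feature subset, and a binary classifier refit on that
subset.  At test time the three pair classifiers each cast one vote; the
class with most votes wins, and a three-way 1-1-1 tie falls back to the
largest confidence among the votes cast.  With three classes the vote totals
can only be 2-1-0 or 1-1-1, so no other tie shape exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .attractor import (
    AMRanking,
    SubsetSelection,
    am_weights,
    incremental_subset_selection,
)
from .csp import CSPModel, fit_csp_pair, filterbank_features, mean_class_covariance, \
    normalized_trial_covariance
from .preprocess import BandedEpochSet, EpochSet, InvalidInputError

logger = logging.getLogger(__name__)


class DegenerateSplitError(ValueError):
    """A class is absent from the training split."""


class UndertrainedPairError(ValueError):
    """Too few trials of a class to fit the requested CSP filters."""


# ---------------------------------------------------------------------------
# Classifier adapters
# ---------------------------------------------------------------------------

#: Default hyperparameters for the seven supported classifier families.
CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "tree": {"max_depth": None, "min_samples_leaf": 1},
    "knn": {"n_neighbors": 5},
    "lda": {"solver": "svd"},
    "logistic": {"C": 1.0, "max_iter": 1000},
    "mlp": {"hidden_layer_sizes": (50,), "max_iter": 500},
    "random_forest": {"n_estimators": 100},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier family plus hyperparameter overrides and a seed."""

    name: str = "lda"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_DEFAULTS:
            raise InvalidInputError(
                f"unknown classifier {self.name!r}; "
                f"choose from {sorted(CLASSIFIER_DEFAULTS)}"
            )

    def resolved_params(self) -> dict:
        p = dict(CLASSIFIER_DEFAULTS[self.name])
        p.update(self.params)
        return p


def make_classifier(spec: ClassifierSpec):
    """Instantiate a fresh scikit-learn estimator for a spec."""
    p = spec.resolved_params()
    seed = spec.seed
    if spec.name == "svm":
        return SVC(random_state=seed, **p)
    if spec.name == "tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.name == "knn":
        return KNeighborsClassifier(**p)
    if spec.name == "lda":
        return LinearDiscriminantAnalysis(**p)
    if spec.name == "logistic":
        return LogisticRegression(random_state=seed, **p)
    if spec.name == "mlp":
        return MLPClassifier(random_state=seed, **p)
    if spec.name == "random_forest":
        return RandomForestClassifier(random_state=seed, **p)
    raise InvalidInputError(spec.name)


class PairClassifier:
    """Binary classifier adapter exposing a confidence in [0, 1].

    Confidence for the predicted label is its probability estimate where the
    estimator provides one; otherwise the decision margin is passed through a
    logistic link calibrated on the training margins.
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.estimator = make_classifier(spec)
        self._calibrator = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PairClassifier":
        self.estimator.fit(X, y)
        self.classes_ = np.asarray(self.estimator.classes_)
        if not hasattr(self.estimator, "predict_proba"):
            margins = self.estimator.decision_function(X).reshape(-1, 1)
            cal = LogisticRegression(max_iter=1000)
            try:
                cal.fit(margins, y)
                self._calibrator = cal
            except ValueError:   # e.g. a single class in y slipped through
                self._calibrator = None
        return self

    def predict_with_confidence(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels and the confidence of each prediction."""
        pred = self.estimator.predict(X)
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(X)
            conf = proba.max(axis=1)
        elif self._calibrator is not None:
            margins = self.estimator.decision_function(X).reshape(-1, 1)
            proba = self._calibrator.predict_proba(margins)
            conf = proba.max(axis=1)
        else:
            conf = np.full(len(pred), 0.5)
        return pred, np.clip(conf, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Splitting and pair decomposition
# ---------------------------------------------------------------------------

def temporal_split(
    epochs: EpochSet | BandedEpochSet, train_fraction: float = 2.0 / 3.0
) -> tuple:
    """First floor(N * train_fraction) trials train, the rest test.

    Order of acquisition is preserved and nothing is shuffled: in an online
    setting only past trials may inform predictions about future ones.
    """
    if not 0 < train_fraction < 1:
        raise InvalidInputError("train_fraction must be in (0, 1)")
    n = epochs.n_trials
    if n < 3:
        raise InvalidInputError("need >= 3 trials to split")
    n_train = int(np.floor(n * train_fraction))
    train = epochs.subset(np.arange(n_train))
    test = epochs.subset(np.arange(n_train, n))
    train_labels = train.labels
    if len(np.unique(train_labels)) < len(np.unique(epochs.labels)):
        missing = set(np.unique(epochs.labels)) - set(np.unique(train_labels))
        raise DegenerateSplitError(f"classes absent from training split: {missing}")
    return train, test


def decompose_pairs(labels) -> list[tuple[str, str]]:
    """All N(N-1)/2 unordered class pairs in lexicographic order."""
    classes = sorted(set(str(c) for c in labels))
    if len(classes) < 2:
        raise InvalidInputError("need >= 2 distinct classes")
    return list(combinations(classes, 2))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class PairModel:
    """Everything learned for one class pair."""

    class_pair: tuple[str, str]
    csp_models: list[CSPModel]       # one per band, in band order
    ranking: AMRanking
    subset: SubsetSelection
    classifier: PairClassifier
    n_features: int                  # full concatenated feature length


@dataclass
class OVOModel:
    """Trained one-versus-one ensemble: one PairModel per unordered pair."""

    classes: tuple[str, ...]
    pair_models: list[PairModel]
    n_train_trials: int
    seed: int | None


@dataclass
class PredictionResult:
    """Per-trial OVO outcome."""

    labels: np.ndarray               # predicted label per trial
    pair_votes: list[dict]           # per trial: {pair: (vote, confidence)}
    tie_break: np.ndarray            # True where the 1-1-1 tie rule fired


def _pair_feature_matrix(banded: BandedEpochSet, csp_models) -> np.ndarray:
    """Concatenated filter-bank features for every trial: (n_trials, 40)."""
    feats = [
        filterbank_features(banded.trial(i), csp_models)
        for i in range(banded.n_trials)
    ]
    return np.asarray(feats)


def train_pair(
    train: BandedEpochSet,
    class_pair: tuple[str, str],
    classifier_spec: ClassifierSpec | None = None,
    n_filter_pairs: int = 4,
    alpha: float = 5.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    am_seed: int | None = None,
) -> PairModel:
    """Fit the full CSP -> AM -> subset -> classifier chain for one pair.

    ``train`` must already be restricted to the pair's two classes.
    """
    classifier_spec = classifier_spec or ClassifierSpec()
    labels = train.labels
    for c in class_pair:
        n_c = int(np.sum(labels == c))
        if n_c < 2 * n_filter_pairs:
            raise UndertrainedPairError(
                f"class {c!r} has {n_c} trials; need >= {2 * n_filter_pairs}"
            )

    csp_models = []
    for band, es in zip(train.bands, train.epoch_sets):
        covs = {
            c: mean_class_covariance(
                normalized_trial_covariance(es.data[i])
                for i in np.flatnonzero(labels == c)
            )
            for c in class_pair
        }
        csp_models.append(
            fit_csp_pair(
                covs[class_pair[0]],
                covs[class_pair[1]],
                n_pairs=n_filter_pairs,
                band=band,
                class_pair=class_pair,
            )
        )

    F = _pair_feature_matrix(train, csp_models)          # (n_trials, p)
    G = F.T                                              # features x samples
    ranking = am_weights(G, alpha=alpha, tol=tol, max_iter=max_iter, seed=am_seed)
    subset = incremental_subset_selection(
        G,
        labels,
        classifier_factory=lambda: make_classifier(classifier_spec),
        order=ranking.order,
    )
    clf = PairClassifier(classifier_spec).fit(F[:, subset.indices], labels)
    return PairModel(
        class_pair=class_pair,
        csp_models=csp_models,
        ranking=ranking,
        subset=subset,
        classifier=clf,
        n_features=F.shape[1],
    )


def train_ovo(
    train: BandedEpochSet,
    classifier_spec: ClassifierSpec | None = None,
    seed: int | None = None,
    **pair_kwargs,
) -> OVOModel:
    """Train one PairModel per unordered class pair, independently.

    ``seed`` spawns independent sub-seeds for each pair's AM initialization
    (and is recorded on the model).
    """
    classes = tuple(sorted(set(str(c) for c in train.labels)))
    pairs = decompose_pairs(classes)
    ss = np.random.SeedSequence(seed)
    am_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(pairs))]

    pair_models = []
    for pair, am_seed in zip(pairs, am_seeds):
        mask = np.isin(train.labels, pair)
        restricted = train.subset(mask)
        try:
            pair_models.append(
                train_pair(
                    restricted,
                    pair,
                    classifier_spec=classifier_spec,
                    am_seed=am_seed if seed is not None else None,
                    **pair_kwargs,
                )
            )
        except (UndertrainedPairError, DegenerateSplitError) as exc:
            raise type(exc)(f"pair {pair}: {exc}") from exc
    return OVOModel(
        classes=classes,
        pair_models=pair_models,
        n_train_trials=train.n_trials,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _pair_trial_features(banded_trial, pm: PairModel) -> np.ndarray:
    full = filterbank_features(banded_trial, pm.csp_models)
    return full[pm.subset.indices]


def aggregate_votes(
    pair_votes: dict, classes: tuple[str, ...]
) -> tuple[str, bool]:
    """Majority vote over pair predictions; 1-1-1 ties fall to confidence.

    ``pair_votes`` maps each class pair to its (voted label, confidence).
    The winner is the class with most votes.  When every class holds exactly
    one vote, the class whose cast vote carries the largest summed confidence
    wins (only confidences of votes cast *for* a class count).  Residual
    exact-confidence ties resolve to the earlier class in ``classes``.
    """
    votes: dict[str, float] = {c: 0.0 for c in classes}
    conf_sum: dict[str, float] = {c: 0.0 for c in classes}
    for lab, c in pair_votes.values():
        if lab not in votes:
            raise InvalidInputError(f"vote for unknown class {lab!r}")
        votes[lab] += 1
        conf_sum[lab] += c
    max_votes = max(votes.values())
    leaders = [c for c in classes if votes[c] == max_votes]
    tie = len(leaders) > 1
    if tie:
        winner = max(leaders, key=lambda c: (conf_sum[c], -list(classes).index(c)))
    else:
        winner = leaders[0]
    return winner, tie


def predict_trial(banded_trial, model: OVOModel) -> tuple[str, dict, bool]:
    """Classify one banded trial; returns (label, per-pair votes, tie_break)."""
    pair_votes = {}
    for pm in model.pair_models:
        x = _pair_trial_features(banded_trial, pm).reshape(1, -1)
        pred, conf = pm.classifier.predict_with_confidence(x)
        pair_votes[pm.class_pair] = (str(pred[0]), float(conf[0]))
    winner, tie = aggregate_votes(pair_votes, model.classes)
    return winner, pair_votes, tie


def predict(banded: BandedEpochSet, model: OVOModel) -> PredictionResult:
    """Predict every trial independently (no information flows between trials)."""
    labels, pv, ties = [], [], []
    for i in range(banded.n_trials):
        lab, votes, tie = predict_trial(banded.trial(i), model)
        labels.append(lab)
        pv.append(votes)
        ties.append(tie)
    return PredictionResult(
        labels=np.asarray(labels), pair_votes=pv, tie_break=np.asarray(ties)
    )
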