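"""Trial exclusion, epoch rejection, window extraction and filter-bank band
splitting.

The pipeline's universal currency is the :class:`EpochSet`: a stack of
fixed-length single-trial windows (trials x channels x samples, µV) with
per-trial labels, reaction times and the original acquisition order.

Re-referencing and ICA-based ocular correction are **not** performed here;
inputs are assumed to be referenced and artifact-corrected upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

#: Default filter bank: five 4-Hz-wide bands covering 1-20 Hz.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 16.0),
    (16.0, 20.0),
)


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass
class EpochSet:
    """Labeled single-trial multichannel windows.

    Attributes
    ----------
    data
        Array of shape (n_trials, n_channels, n_samples), in µV.
    labels
        Per-trial class identifier (strings), length n_trials.
    sample_rate
        Sampling frequency in Hz.
    channel_names
        One name per channel.
    reaction_times
        Optional per-trial reaction time in seconds.
    trial_order
        Original acquisition indices, strictly increasing.
    """

    data: np.ndarray
    labels: np.ndarray
    sample_rate: float
    channel_names: list[str] = field(default_factory=list)
    reaction_times: np.ndarray | None = None
    trial_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"data must be trials x channels x samples, got ndim={self.data.ndim}"
            )
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.n_trials:
            raise InvalidInputError(
                f"labels length {len(self.labels)} != n_trials {self.n_trials}"
            )
        if not self.channel_names:
            self.channel_names = [f"CH{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise InvalidInputError("channel_names length mismatch")
        if self.reaction_times is not None:
            self.reaction_times = np.asarray(self.reaction_times, dtype=float)
            if len(self.reaction_times) != self.n_trials:
                raise InvalidInputError("reaction_times length mismatch")
        if self.trial_order is None:
            self.trial_order = np.arange(self.n_trials)
        else:
            self.trial_order = np.asarray(self.trial_order, dtype=int)
            if len(self.trial_order) != self.n_trials:
                raise InvalidInputError("trial_order length mismatch")
            if self.n_trials > 1 and not np.all(np.diff(self.trial_order) > 0):
                raise InvalidInputError("trial_order must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, mask_or_idx) -> "EpochSet":
        """Return a new EpochSet restricted to a boolean mask or index array."""
        idx = np.asarray(mask_or_idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            sample_rate=self.sample_rate,
            channel_names=list(self.channel_names),
            reaction_times=None
            if self.reaction_times is None
            else self.reaction_times[idx],
            trial_order=self.trial_order[idx],
        )


@dataclass(frozen=True)
class BandSpec:
    """Ordered list of non-overlapping ascending (low, high) Hz intervals."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = -np.inf
        for low, high in self.bands:
            if not low < high:
                raise InvalidInputError(f"band ({low}, {high}): low must be < high")
            if low < prev_high:
                raise InvalidInputError("bands must be ascending and non-overlapping")
            prev_high = high

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


@dataclass
class BandedEpochSet:
    """One band-pass filtered EpochSet per band of a BandSpec.

    All member EpochSets share labels and trial order exactly.
    """

    bands: BandSpec
    epoch_sets: list[EpochSet]

    def __post_init__(self) -> None:
        if len(self.epoch_sets) != len(self.bands):
            raise InvalidInputError("one EpochSet per band required")
        ref = self.epoch_sets[0]
        for es in self.epoch_sets[1:]:
            if not np.array_equal(es.labels, ref.labels) or not np.array_equal(
                es.trial_order, ref.trial_order
            ):
                raise InvalidInputError("member EpochSets must share labels/order")

    @property
    def labels(self) -> np.ndarray:
        return self.epoch_sets[0].labels

    @property
    def trial_order(self) -> np.ndarray:
        return self.epoch_sets[0].trial_order

    @property
    def n_trials(self) -> int:
        return self.epoch_sets[0].n_trials

    def subset(self, mask_or_idx) -> "BandedEpochSet":
        return BandedEpochSet(
            bands=self.bands,
            epoch_sets=[es.subset(mask_or_idx) for es in self.epoch_sets],
        )

    def trial(self, i: int) -> list[np.ndarray]:
        """The i-th trial as one (channels x samples) array per band."""
        return [es.data[i] for es in self.epoch_sets]


# ---------------------------------------------------------------------------
# Trial / epoch exclusion
# ---------------------------------------------------------------------------

def rt_exclusion_mask(reaction_times: Sequence[float]) -> np.ndarray:
    """Keep-mask for reaction times within 3 SD of the mean.

    Mean and SD are computed once over all supplied values (single pass, not
    iterative).  With SD = 0 nothing is excluded.
    """
    rts = np.asarray(reaction_times, dtype=float)
    if rts.size < 2:
        raise InvalidInputError("need at least two reaction times")
    mean, sd = rts.mean(), rts.std()
    return np.abs(rts - mean) <= 3.0 * sd


def amplitude_rejection_mask(epochs: EpochSet, limit: float = 75.0) -> np.ndarray:
    """Keep-mask rejecting epochs with any sample outside [-limit, +limit] µV.

    The bound is inclusive: a sample at exactly ±limit is kept.
    """
    if limit <= 0:
        raise InvalidInputError("limit must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    return peak <= limit


def participant_retention(n_kept: int, n_total: int) -> bool:
    """Whether a participant keeps enough trials to stay in the analysis.

    A participant is retained iff at least one third of their trials survive
    exclusion (boundary inclusive: exactly n_total/3 retains).
    """
    if n_total <= 0 or not 0 <= n_kept <= n_total:
        raise InvalidInputError("require 0 <= n_kept <= n_total, n_total > 0")
    return n_kept >= n_total / 3.0


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_pre_response_window(
    continuous: np.ndarray,
    response_samples: Sequence[int],
    sample_rate: float,
    labels: Sequence,
    window: float = 1.5,
    reaction_times: Sequence[float] | None = None,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Cut fixed-length windows ending immediately before each response.

    Each epoch covers the ``round(window * sample_rate)`` samples preceding
    (and exclusive of) the response sample: the half-open interval
    ``[resp - n_win, resp)``.
    """
    if window <= 0:
        raise InvalidInputError("window must be positive")
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise InvalidInputError("continuous must be channels x samples")
    n_win = int(round(window * sample_rate))
    resp = np.asarray(response_samples, dtype=int)
    epochs = np.empty((len(resp), continuous.shape[0], n_win))
    for i, r in enumerate(resp):
        if r < n_win:
            raise InvalidInputError(
                f"trial {i}: response sample {r} precedes a full {window} s window"
            )
        if r > continuous.shape[1]:
            raise InvalidInputError(f"trial {i}: response sample {r} beyond record end")
        epochs[i] = continuous[:, r - n_win : r]
    return EpochSet(
        data=epochs,
        labels=np.asarray(labels),
        sample_rate=sample_rate,
        channel_names=channel_names or [],
        reaction_times=None if reaction_times is None else np.asarray(reaction_times),
    )


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

def _design_bandpass(low: float, high: float, sample_rate: float, order: int = 4):
    nyq = sample_rate / 2.0
    if high >= nyq:
        raise InvalidInputError(f"band edge {high} Hz >= Nyquist {nyq} Hz")
    return butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")


def bandpass_filter_bank(
    epochs: EpochSet, bands: BandSpec | None = None, order: int = 4
) -> BandedEpochSet:
    """Split epochs into band-limited copies with zero-phase Butterworth filters.

    Each band is a 4th-order Butterworth band-pass applied forward-backward
    (``sosfiltfilt``), so the output has no group delay and pre-response
    timing is preserved.  Labels and trial order are untouched.
    """
    bands = bands or BandSpec()
    out = []
    for low, high in bands:
        sos = _design_bandpass(low, high, epochs.sample_rate, order=order)
        filtered = sosfiltfilt(sos, epochs.data, axis=-1)
        out.append(replace(epochs, data=filtered))
    return BandedEpochSet(bands=bands, epoch_sets=out)
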