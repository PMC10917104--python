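"""Synthetic EEG session generator with planted class-dependent spatial
structure.

Each simulated session mimics a 34-channel, 512-Hz recording of ~330
fixed-length (1.5 s) pre-response trials of a balanced three-choice task.
Per trial the signal is

    X = background noise + sum over source bands of  A * a_c * s(t),

where ``a_c`` is the trial's class-specific unit-norm spatial mixing vector
for that band and ``s(t)`` an amplitude-modulated sinusoid at the band
midpoint with random phase.  The background is spatially correlated Gaussian
noise (a random full-rank mixing matrix drawn once per session, average
channel SD 10 µV) so that CSP whitening is genuinely exercised.

``snr`` is the expected ratio of planted-source power to background-noise
power *within the source band*; snr = 0 plants nothing, so signals are
statistically independent of the labels.

The generator does not emulate ocular/muscle artifacts, volume conduction or
across-block nonstationarity; its noise model is a plain stand-in, not a
claim about any real recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet, InvalidInputError

DEFAULT_CLASSES = ("paper", "rock", "scissors")

#: Background channel standard deviation, µV.
NOISE_SD_UV = 10.0
#: Depth and rate of the source amplitude modulation.
AM_DEPTH = 0.5
AM_RATE_HZ = 0.5


@dataclass
class SyntheticConfig:
    """Parameters of one simulated session.

    ``class_patterns`` maps (class index, band index) to a unit-norm spatial
    mixing vector over channels; if None, mutually orthonormal vectors are
    drawn from the seed.  ``source_bands`` lists the (low, high) Hz bands
    where each class's discriminative source oscillates.
    """

    n_trials: int = 330
    n_channels: int = 34
    sample_rate: float = 512.0
    window_length: float = 1.5
    n_classes: int = 3
    class_labels: tuple[str, ...] = DEFAULT_CLASSES
    class_patterns: np.ndarray | None = None   # (n_classes, n_bands, n_channels)
    source_bands: tuple[tuple[float, float], ...] = ((8.0, 12.0),)
    snr: float = 3.0
    amplitude_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_channels <= 0 or self.sample_rate <= 0:
            raise InvalidInputError(
                "n_trials, n_channels and sample_rate must be positive"
            )
        if self.window_length <= 0:
            raise InvalidInputError("window_length must be positive")
        if self.snr < 0:
            raise InvalidInputError("snr must be >= 0")
        if self.n_classes < 2:
            raise InvalidInputError("need >= 2 classes")
        if len(self.class_labels) != self.n_classes:
            self.class_labels = tuple(f"class{i}" for i in range(self.n_classes))
        if self.class_patterns is not None:
            pats = np.asarray(self.class_patterns, dtype=float)
            expect = (self.n_classes, len(self.source_bands), self.n_channels)
            if pats.shape != expect:
                raise InvalidInputError(
                    f"class_patterns shape {pats.shape} != {expect}"
                )
            norms = np.linalg.norm(pats, axis=-1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise InvalidInputError("class_patterns rows must be unit norm")
            self.class_patterns = pats

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.window_length))


@dataclass
class GroundTruth:
    """Exactly what the simulator planted, for downstream validation."""

    patterns: np.ndarray           # (n_classes, n_bands, n_channels), unit norm
    source_bands: tuple[tuple[float, float], ...]
    class_labels: tuple[str, ...]
    trial_amplitudes: np.ndarray   # (n_trials, n_bands) realized source SDs, µV
    noise_mixing: np.ndarray       # (n_channels, n_channels)
    snr: float
    seed: int


def _orthonormal_patterns(rng, n_classes: int, n_bands: int, n_ch: int) -> np.ndarray:
    pats = np.empty((n_classes, n_bands, n_ch))
    for b in range(n_bands):
        q, _ = np.linalg.qr(rng.standard_normal((n_ch, n_classes)))
        pats[:, b, :] = q[:, :n_classes].T
    return pats


def simulate_session(config: SyntheticConfig) -> tuple[EpochSet, GroundTruth]:
    """Generate one session; identical config+seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n_tr, n_ch, n_s = config.n_trials, config.n_channels, config.n_samples
    fs = config.sample_rate
    n_bands = len(config.source_bands)

    # balanced, seed-shuffled label sequence (counts differ by <= 1)
    reps = -(-n_tr // config.n_classes)
    label_idx = np.tile(np.arange(config.n_classes), reps)[:n_tr]
    rng.shuffle(label_idx)
    labels = np.asarray(config.class_labels)[label_idx]

    if config.class_patterns is not None:
        patterns = config.class_patterns
    else:
        patterns = _orthonormal_patterns(rng, config.n_classes, n_bands, n_ch)

    # session-wide spatially correlated background noise
    mixing = rng.standard_normal((n_ch, n_ch))
    noise_cov_diag = np.sum(mixing**2, axis=1)
    mixing *= NOISE_SD_UV / np.sqrt(noise_cov_diag.mean())
    noise_power = float(np.sum(mixing**2))          # total variance over channels

    t = np.arange(n_s) / fs
    data = np.empty((n_tr, n_ch, n_s))
    trial_amplitudes = np.zeros((n_tr, n_bands))

    # E[envelope^2]/2 converts peak amplitude to sinusoid variance
    env_ms = 1.0 + AM_DEPTH**2 / 2.0
    jitter_ms = 1.0 + config.amplitude_jitter**2 / 3.0  # E[U(1-j,1+j)^2]

    for i in range(n_tr):
        X = mixing @ rng.standard_normal((n_ch, n_s))
        if config.snr > 0:
            for b, (low, high) in enumerate(config.source_bands):
                # noise power falling inside this band (flat white spectrum)
                band_noise = noise_power * (high - low) / (fs / 2.0)
                target_var = config.snr * band_noise
                A = np.sqrt(2.0 * target_var / (env_ms * jitter_ms))
                amp = A * rng.uniform(
                    1.0 - config.amplitude_jitter, 1.0 + config.amplitude_jitter
                )
                phase = rng.uniform(0.0, 2.0 * np.pi)
                mod_phase = rng.uniform(0.0, 2.0 * np.pi)
                f_mid = 0.5 * (low + high)
                env = 1.0 + AM_DEPTH * np.cos(2.0 * np.pi * AM_RATE_HZ * t + mod_phase)
                s = amp * env * np.sin(2.0 * np.pi * f_mid * t + phase)
                X += np.outer(patterns[label_idx[i], b], s)
                trial_amplitudes[i, b] = s.std()
        data[i] = X

    # plausible reaction times, clipped to stay positive
    rts = np.clip(rng.normal(0.55, 0.12, size=n_tr), 0.15, None)

    epochs = EpochSet(
        data=data,
        labels=labels,
        sample_rate=fs,
        channel_names=[f"CH{i:02d}" for i in range(n_ch)],
        reaction_times=rts,
        trial_order=np.arange(n_tr),
    )
    truth = GroundTruth(
        patterns=patterns.copy(),
        source_bands=config.source_bands,
        class_labels=tuple(config.class_labels),
        trial_amplitudes=trial_amplitudes,
        noise_mixing=mixing,
        snr=config.snr,
        seed=config.seed,
    )
    return epochs, truth


def pattern_recovery_score(
    estimated_pattern: np.ndarray,
    truth: GroundTruth,
    class_label: str,
    band: int | tuple[float, float] = 0,
) -> float:
    """|Pearson correlation| between an estimated and the planted pattern.

    Sign- and scale-invariant, in [0, 1].  ``band`` may be an index into the
    planted source bands or the (low, high) tuple itself.
    """
    est = np.asarray(estimated_pattern, dtype=float).ravel()
    if isinstance(band, tuple):
        band = truth.source_bands.index(band)
    ci = truth.class_labels.index(class_label)
    planted = truth.patterns[ci, band]
    if est.size != planted.size:
        raise InvalidInputError("pattern length mismatch")
    if np.ptp(est) == 0 or np.ptp(planted) == 0:
        raise InvalidInputError("zero-variance pattern: correlation undefined")
    return float(np.abs(np.corrcoef(est, planted)[0, 1]))
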