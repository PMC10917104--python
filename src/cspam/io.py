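"""File formats: epoch bundles, model bundles, continuous EDF/BDF input,
event tables and result tables.

An *epoch bundle* is a ``.npy`` array (trials x channels x samples, µV) plus
a JSON sidecar carrying sample rate, channel names, labels, reaction times,
trial order and provenance (config hash + seed).  Continuous EDF/BDF
recordings are read through :mod:`mne`; a minimal EDF/BDF writer is included
so the simulator can export continuous recordings (no maintained Python
EDF-writing package is bundled with the reader).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet, InvalidInputError

BUNDLE_VERSION = 1
MODEL_VERSION = 1


class FormatError(ValueError):
    """A file does not match its declared format or sidecar."""


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Epoch bundles
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path, provenance: dict | None = None) -> None:
    """Write an epoch bundle: ``<path>.npy`` + ``<path>.json`` sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), epochs.data)
    sidecar = {
        "version": BUNDLE_VERSION,
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "sample_rate": epochs.sample_rate,
        "channel_names": list(epochs.channel_names),
        "labels": [str(x) for x in epochs.labels],
        "reaction_times": None
        if epochs.reaction_times is None
        else epochs.reaction_times.tolist(),
        "trial_order": epochs.trial_order.tolist(),
        "provenance": provenance or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path) -> EpochSet:
    """Read an epoch bundle, validating sidecar dimensions and version."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("version") != BUNDLE_VERSION:
        raise FormatError(f"unsupported bundle version {sidecar.get('version')}")
    data = np.load(path.with_suffix(".npy"))
    expect = (sidecar["n_trials"], sidecar["n_channels"], sidecar["n_samples"])
    if data.shape != expect:
        raise FormatError(f"array shape {data.shape} != sidecar {expect}")
    if len(sidecar["labels"]) != data.shape[0]:
        raise FormatError("sidecar labels length mismatch")
    return EpochSet(
        data=data,
        labels=np.asarray(sidecar["labels"]),
        sample_rate=sidecar["sample_rate"],
        channel_names=sidecar["channel_names"],
        reaction_times=None
        if sidecar["reaction_times"] is None
        else np.asarray(sidecar["reaction_times"]),
        trial_order=np.asarray(sidecar["trial_order"]),
    )


def write_ground_truth(truth, path) -> None:
    """Write a GroundTruth sidecar as structured JSON."""
    payload = {
        "patterns": truth.patterns.tolist(),
        "source_bands": [list(b) for b in truth.source_bands],
        "class_labels": list(truth.class_labels),
        "trial_amplitudes": truth.trial_amplitudes.tolist(),
        "noise_mixing": truth.noise_mixing.tolist(),
        "snr": truth.snr,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Continuous EDF/BDF + event tables
# ---------------------------------------------------------------------------

def read_continuous(path, event_table_path=None):
    """Read a continuous EDF/BDF recording (and optional event table).

    Returns ``(data_uV, sample_rate, channel_names, events)`` where
    ``data_uV`` is channels x samples in µV and ``events`` a DataFrame with
    columns (trial, response_sample, label, rt) or None.  Events beyond the
    record end raise a validation error.
    """
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne uses volts internally
    rate = float(raw.info["sfreq"])
    names = list(raw.ch_names)

    events = None
    if event_table_path is not None:
        events = read_event_table(event_table_path)
        if (events["response_sample"] > data.shape[1]).any():
            bad = events.loc[events["response_sample"] > data.shape[1], "trial"]
            raise FormatError(
                f"events beyond record end ({data.shape[1]} samples): "
                f"trials {bad.tolist()}"
            )
    return data, rate, names, events


def read_event_table(path) -> pd.DataFrame:
    """Plain-text delimited event table: trial, response_sample, label, rt."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"trial", "response_sample", "label", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns {sorted(missing)}")
    return df


def _edf_header_records(n_ch, n_records, record_len_s, rate, names, bdf):
    n_samp = int(round(rate * record_len_s))
    version = b"\xffBIOSEMI" if bdf else b"0" + b" " * 7
    hdr = bytearray()
    hdr += version
    hdr += b" " * 80                               # patient id
    hdr += b" " * 80                               # recording id
    hdr += b"01.01.00"                             # start date
    hdr += b"00.00.00"                             # start time
    hdr += f"{256 * (n_ch + 1):<8d}".encode()      # header bytes
    hdr += (b"24BIT" + b" " * 39) if bdf else b" " * 44
    hdr += f"{n_records:<8d}".encode()
    hdr += f"{record_len_s:<8g}".encode()
    hdr += f"{n_ch:<4d}".encode()
    for nm in names:
        hdr += f"{nm:<16.16s}".encode()
    hdr += b" " * (80 * n_ch)                      # transducer
    for _ in names:
        hdr += f"{'uV':<8s}".encode()
    pmin, pmax = (-262144, 262143) if bdf else (-3276, 3276)
    dmin, dmax = (-8388608, 8388607) if bdf else (-32768, 32767)
    for _ in names:
        hdr += f"{pmin:<8d}".encode()
    for _ in names:
        hdr += f"{pmax:<8d}".encode()
    for _ in names:
        hdr += f"{dmin:<8d}".encode()
    for _ in names:
        hdr += f"{dmax:<8d}".encode()
    hdr += b" " * (80 * n_ch)                      # prefiltering
    for _ in names:
        hdr += f"{n_samp:<8d}".encode()
    hdr += b" " * (32 * n_ch)                      # reserved
    return bytes(hdr), n_samp, (pmin, pmax, dmin, dmax)


def write_continuous(data_uV: np.ndarray, sample_rate: float, path,
                     channel_names=None) -> None:
    """Write a continuous multichannel signal as EDF (16-bit) or BDF (24-bit).

    The physical range is fixed (±3276 µV EDF, ±262144 µV BDF) and data are
    clipped to it; one data record per second, zero-padded to a whole number
    of records.  Minimal but standard-conforming, so the file round-trips
    through any EDF/BDF reader.
    """
    path = Path(path)
    bdf = path.suffix.lower() == ".bdf"
    data = np.asarray(data_uV, dtype=float)
    if data.ndim != 2:
        raise InvalidInputError("data must be channels x samples")
    n_ch, n_total = data.shape
    names = channel_names or [f"CH{i:02d}" for i in range(n_ch)]
    record_len_s = 1.0
    n_per_rec = int(round(sample_rate * record_len_s))
    n_records = -(-n_total // n_per_rec)
    hdr, n_samp, (pmin, pmax, dmin, dmax) = _edf_header_records(
        n_ch, n_records, record_len_s, sample_rate, names, bdf
    )
    padded = np.zeros((n_ch, n_records * n_per_rec))
    padded[:, :n_total] = data
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((np.clip(padded, pmin, pmax) - pmin) * scale + dmin)
    digital = np.clip(digital, dmin, dmax).astype(np.int32)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = digital[:, r * n_per_rec : (r + 1) * n_per_rec]
            if bdf:
                flat = block.reshape(n_ch * n_per_rec)
                b = np.empty((flat.size, 3), dtype=np.uint8)
                u = flat.astype(np.int64) & 0xFFFFFF
                b[:, 0] = u & 0xFF
                b[:, 1] = (u >> 8) & 0xFF
                b[:, 2] = (u >> 16) & 0xFF
                fh.write(b.tobytes())
            else:
                fh.write(block.astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

def write_model(model, path, provenance: dict | None = None) -> None:
    """Serialize an OVOModel: ``<path>.json`` metadata + ``<path>.npz`` arrays.

    Fitted classifier parameters are not serialized generically; the bundle
    records the classifier spec so the model can be refit deterministically,
    plus all CSP filters, eigenvalues, AM weights and subsets.
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "version": MODEL_VERSION,
        "classes": list(model.classes),
        "n_train_trials": model.n_train_trials,
        "seed": model.seed,
        "provenance": provenance or {},
        "pairs": [],
    }
    for pi, pm in enumerate(model.pair_models):
        pair_meta = {
            "class_pair": list(pm.class_pair),
            "bands": [list(m.band) for m in pm.csp_models],
            "subset_k": int(pm.subset.k),
            "subset_score": pm.subset.score,
            "classifier": {
                "name": pm.classifier.spec.name,
                "params": pm.classifier.spec.resolved_params(),
                "seed": pm.classifier.spec.seed,
            },
            "am": {
                "alpha": pm.ranking.alpha,
                "iterations_used": pm.ranking.iterations_used,
                "converged": pm.ranking.converged,
                "seed": pm.ranking.seed,
            },
        }
        meta["pairs"].append(pair_meta)
        for bi, m in enumerate(pm.csp_models):
            arrays[f"pair{pi}_band{bi}_filters"] = m.filters
            arrays[f"pair{pi}_band{bi}_eigenvalues"] = m.eigenvalues
            arrays[f"pair{pi}_band{bi}_patterns"] = m.patterns
        arrays[f"pair{pi}_am_weights"] = pm.ranking.weights
        arrays[f"pair{pi}_am_order"] = pm.ranking.order
        arrays[f"pair{pi}_subset_indices"] = pm.subset.indices
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    np.savez(path.with_suffix(".npz"), **arrays)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_predictions_table(result, true_labels, path) -> None:
    """Per-trial predictions as a tidy delimited table."""
    df = pd.DataFrame(
        {
            "trial": np.arange(len(result.labels)),
            "predicted": result.labels,
            "true": np.asarray(true_labels),
            "tie_break": result.tie_break,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_summary_table(rows: list[dict], path) -> None:
    """Per-subject summary rows (accuracy, p-value, band usage...)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
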