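"""Standard resting-state EEG preprocessing.

Band-pass filtering (2-20 Hz, zero-phase Butterworth), common-average
re-referencing, segmentation into nonoverlapping 5-s epochs, and one-pass
variance-based rejection of outlier epochs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import EpochSet, Recording

__all__ = [
    "bandpass_filter",
    "average_reference",
    "epoch_signal",
    "reject_outlier_epochs",
    "preprocess",
]


def bandpass_filter(
    rec: Recording, low: float = 2.0, high: float = 20.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and
    there is no phase distortion — topographies at any instant are not
    mixed across time asymmetrically.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(sps.sosfiltfilt(sos, rec.data, axis=1))


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: zero mean across channels."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def epoch_signal(rec: Recording, length_s: float = 5.0) -> EpochSet:
    """Cut into nonoverlapping epochs; the trailing remainder is dropped."""
    spe = int(round(rec.fs * length_s))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording ({rec.duration:.1f} s) shorter than one epoch "
            f"({length_s} s)"
        )
    cut = rec.data[:, : n_epochs * spe]
    epochs = cut.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(), fs=rec.fs, epoch_length=length_s,
        montage=rec.montage, subject_id=rec.subject_id, group=rec.group,
    )


def reject_outlier_epochs(es: EpochSet, n_sd: float = 3.0) -> EpochSet:
    """Mark epochs whose pooled variance exceeds mean + ``n_sd`` SD.

    One scalar variance per epoch is computed over all channels and
    samples; the threshold is derived once from the full within-subject
    distribution (no iterative re-thresholding). Returns a new EpochSet
    with an updated ``retained`` mask.
    """
    if es.n_epochs < 3:
        raise ValueError("need at least 3 epochs for a variance threshold")
    v = es.epochs.var(axis=(1, 2))
    thresh = v.mean() + n_sd * v.std()
    return EpochSet(
        epochs=es.epochs, fs=es.fs, epoch_length=es.epoch_length,
        montage=es.montage, retained=v <= thresh,
        subject_id=es.subject_id, group=es.group,
    )


def preprocess(
    rec: Recording,
    low: float = 2.0,
    high: float = 20.0,
    epoch_length: float = 5.0,
    reject: bool = True,
) -> EpochSet:
    """Full preprocessing chain: filter, re-reference, epoch, reject."""
    out = average_reference(bandpass_filter(rec, low, high))
    es = epoch_signal(out, epoch_length)
    if reject and es.n_epochs >= 3:
        es = reject_outlier_epochs(es)
    return es
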