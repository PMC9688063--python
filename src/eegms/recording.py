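"""Core data containers: multichannel recordings and epoch sets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` potentials in microvolts.
    fs
        Sampling rate in Hz.
    montage
        Electrode montage; its size must match the channel axis.
    subject_id, group
        Provenance metadata (group is e.g. ``"HC"`` / ``"SZ"``).
    """

    data: np.ndarray = field(repr=False)
    fs: float
    montage: Montage
    subject_id: str = "subj"
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Nonoverlapping, temporally ordered epochs cut from one recording.

    ``epochs`` has shape ``(n_epochs, n_channels, samples_per_epoch)``;
    ``retained`` is a boolean mask updated by artifact rejection.
    """

    epochs: np.ndarray = field(repr=False)
    fs: float
    epoch_length: float
    montage: Montage
    retained: np.ndarray = field(default=None, repr=False)
    subject_id: str = "subj"
    group: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D")
        expected = int(round(self.fs * self.epoch_length))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {self.epochs.shape[2]} != fs x length "
                f"({expected})"
            )
        if self.retained is None:
            self.retained = np.ones(self.epochs.shape[0], dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
            if self.retained.shape != (self.epochs.shape[0],):
                raise ValueError("retained mask length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_epochs(self) -> np.ndarray:
        """The data of retained epochs only."""
        return self.epochs[self.retained]
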