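"""Core in-memory containers: multichannel recordings and measurements."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import ProtocolSpec

#: Fixed per-modality sampling rates of the acquisition hardware.  The
#: chest sensor samples at 1 kHz internally but the consumable series is
#: the derived beats-per-minute trace, carried here at 1 Hz.
SAMPLING_RATES = {"EEG": 500.0, "EMG": 1600.0, "HR": 1.0}

N_EEG_CHANNELS = 64


@dataclass
class Recording:
    """One modality's channels x time series.

    samples are microvolts for EEG/EMG and beats/min for HR; ``rate`` is
    in Hz and ``labels`` names the rows of ``samples``.
    """

    samples: np.ndarray
    rate: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains NaN/Inf samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Measurement:
    """One subject x one protocol: the three recordings plus metadata."""

    subject_id: str
    protocol: ProtocolSpec
    eeg: Recording
    emg: Recording
    hr: Recording
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eeg.n_channels != N_EEG_CHANNELS:
            raise ValueError(f"EEG must have {N_EEG_CHANNELS} channels")
        if self.emg.n_channels != 2:
            raise ValueError("EMG must have exactly two channels (L/R)")
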