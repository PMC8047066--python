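"""Extraction of the 19 biometric parameters from one measurement.

Per measurement the pipeline computes:

* 5 EEG features — relative power of delta (0.5-4 Hz), theta (4-8),
  alpha (8-13), beta (13-35) and low gamma (35-40), from Welch PSDs of
  30-s epochs after common-average referencing, 0.1-40 Hz band-pass
  filtering, bad-channel rejection/interpolation and baseline
  correction against the static (0-Hz) recording;
* 12 EMG features — per leg, the mean rectified amplitude ("area") and
  the relative PSD in five equal bands spanning 40-500 Hz
  (40-132, 132-224, 224-316, 316-408, 408-500), after a 50th-order FIR
  band-pass at 40-500 Hz;
* 2 HR features — mean and standard deviation of the beats/min series.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import N_EEG_CHANNELS, Measurement, Recording

EEG_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (4.0, 8.0),
    (8.0, 13.0),
    (13.0, 35.0),
    (35.0, 40.0),
)
EMG_BANDS: tuple[tuple[float, float], ...] = (
    (40.0, 132.0),
    (132.0, 224.0),
    (224.0, 316.0),
    (316.0, 408.0),
    (408.0, 500.0),
)

_EMG_BAND_TAGS = ("40_132", "132_224", "224_316", "316_408", "408_500")

#: The 19 feature names, in the order of the study's parameter table.
FEATURE_NAMES: tuple[str, ...] = (
    "eeg_delta",
    "eeg_theta",
    "eeg_alpha",
    "eeg_beta",
    "eeg_lg",
    "emg_L_area",
    "emg_R_area",
    *(f"emg_L_{t}" for t in _EMG_BAND_TAGS),
    *(f"emg_R_{t}" for t in _EMG_BAND_TAGS),
    "hr_average",
    "hr_std",
)

EEG_FEATURES = FEATURE_NAMES[:5]

EPOCH_SECONDS = 30.0
BAD_CHANNEL_UV = 300.0
TRIAL_REJECT_FRACTION = 0.20
WELCH_WINDOW_SECONDS = 2.0


# --------------------------------------------------------------------
# elementary operations


def bandpass_fir(
    x: np.ndarray,
    rate: float,
    low: float = 40.0,
    high: float = 500.0,
    order: int = 50,
    clip_high: bool = True,
) -> np.ndarray:
    """Linear-phase FIR band-pass (Hamming-windowed sinc, ``order``
    taps + 1), applied along the last axis with the group delay of
    ``order/2`` samples compensated so output aligns with input.

    ``high`` is clipped to 0.99 x Nyquist for nonstandard rates when
    ``clip_high`` is set; with clipping disabled a cutoff at or above
    Nyquist raises.
    """
    if order % 2:
        raise ValueError("FIR order must be even (linear phase, integer delay)")
    nyq = rate / 2.0
    if high >= nyq:
        if not clip_high:
            raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
        high = 0.99 * nyq
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high after clipping")
    taps = design_bandpass(rate, low, high, order)
    x = np.asarray(x, dtype=float)
    # 'same' convolution centres the symmetric kernel: delay-compensated
    if x.ndim == 1:
        return sps.fftconvolve(x, taps, mode="same")
    return np.stack([sps.fftconvolve(row, taps, mode="same") for row in x])


@functools.lru_cache(maxsize=32)
def design_bandpass(rate: float, low: float, high: float, order: int) -> np.ndarray:
    """The tap vector of :func:`bandpass_fir` (cached)."""
    return sps.firwin(order + 1, [low, high], fs=rate, pass_zero=False, window="hamming")


def emg_area(x: np.ndarray) -> float:
    """Mean rectified amplitude: integral of |x| divided by the sample
    count."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.mean(np.abs(x)))


def _band_shares(freqs: np.ndarray, psd: np.ndarray, bands) -> np.ndarray:
    """Integrate a PSD over bands and normalise by the union's power.
    ``psd`` may be (..., n_freqs); bands are half-open [lo, hi) with the
    last band closed at its upper edge."""
    shares = []
    for i, (lo, hi) in enumerate(bands):
        if i == len(bands) - 1:
            sel = (freqs >= lo) & (freqs <= hi)
        else:
            sel = (freqs >= lo) & (freqs < hi)
        shares.append(psd[..., sel].sum(axis=-1))
    shares = np.stack(shares, axis=-1)
    total = shares.sum(axis=-1, keepdims=True)
    return shares / total


def relative_band_power(
    x: np.ndarray,
    rate: float,
    bands=EMG_BANDS,
    method: str = "periodogram",
) -> np.ndarray:
    """Relative power in each band: band-integrated PSD divided by the
    total power over the union of the bands (shares sum to 1).

    ``method='periodogram'`` takes one FFT of the whole trace (EMG
    convention here); ``method='welch'`` averages 2-s Hann windows with
    50 % overlap (EEG convention).
    """
    x = np.asarray(x, dtype=float)
    prev_hi = 0.0
    for lo, hi in bands:
        if not 0.0 <= lo < hi <= rate / 2.0:
            raise ValueError(f"band ({lo}, {hi}) outside [0, Nyquist]")
        if lo < prev_hi:
            raise ValueError("bands must be ordered and non-overlapping")
        prev_hi = hi
    if method == "periodogram":
        freqs, psd = sps.periodogram(x, fs=rate, axis=-1)
    elif method == "welch":
        nper = int(WELCH_WINDOW_SECONDS * rate)
        if x.shape[-1] < nper:
            raise ValueError("signal shorter than one Welch window")
        freqs, psd = sps.welch(x, fs=rate, nperseg=nper, noverlap=nper // 2, axis=-1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _band_shares(freqs, psd, bands)


def hr_stats(hr: Recording | np.ndarray) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of the HR series."""
    x = hr.samples.ravel() if isinstance(hr, Recording) else np.asarray(hr, float).ravel()
    if x.size == 0:
        raise ValueError("empty HR series")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), sd


# --------------------------------------------------------------------
# EEG preprocessing


@functools.lru_cache(maxsize=1)
def eeg_layout() -> pd.DataFrame:
    """Standard 10-10 positions of the 64-channel cap (label, x, y, z)."""
    with resources.files("wavesick.data").joinpath("layout_64ch.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class EpochSet:
    """Preprocessed EEG cut into 30-s epochs.

    An empty ``epochs`` list with a ``rejected_reason`` marks a trial
    rejected outright (too many bad channels); this is a typed result,
    not an exception, so downstream stages can flag the EEG features
    missing and keep the row.
    """

    epochs: list[np.ndarray]
    rate: float
    kept_channels: tuple[str, ...]
    rejected_channels: tuple[str, ...] = ()
    rejected_epochs: tuple[int, ...] = ()
    rejected_reason: str | None = None

    @property
    def rejected(self) -> bool:
        return self.rejected_reason is not None


@functools.lru_cache(maxsize=4)
def _eeg_sos(rate: float) -> np.ndarray:
    # applied forward-backward (zero phase), so effectively 4th order
    return sps.butter(2, [0.1, 40.0], btype="bandpass", fs=rate, output="sos")


def _interpolation_weights(
    bad: str, kept: list[str], n_neighbors: int = 4
) -> tuple[list[str], np.ndarray]:
    layout = eeg_layout().set_index("label")
    pos = layout.loc[bad, ["x", "y", "z"]].to_numpy(dtype=float)
    others = layout.loc[kept, ["x", "y", "z"]].to_numpy(dtype=float)
    dist = np.linalg.norm(others - pos, axis=1)
    order = np.argsort(dist)[:n_neighbors]
    w = 1.0 / dist[order]
    return [kept[i] for i in order], w / w.sum()


def eeg_preprocess(
    eeg: Recording,
    baseline: Recording,
    *,
    bad_channel_uv: float = BAD_CHANNEL_UV,
    trial_reject_fraction: float = TRIAL_REJECT_FRACTION,
) -> EpochSet:
    """Full EEG preprocessing chain for one recording.

    Order of operations: common-average re-reference; zero-phase 0.1-40
    Hz band-pass; mark channels whose absolute voltage ever exceeds
    ``bad_channel_uv``; reject the whole trial if more than
    ``trial_reject_fraction`` of channels are bad, else reconstruct bad
    channels by inverse-distance interpolation from their four nearest
    neighbours on the 10-10 layout; subtract per-channel offsets
    estimated from the (re-referenced) static baseline recording; cut
    consecutive 30-s epochs and drop any epoch in which a channel still
    exceeds the voltage bound.
    """
    if eeg.n_channels != N_EEG_CHANNELS:
        raise ValueError(f"expected {N_EEG_CHANNELS} EEG channels, got {eeg.n_channels}")
    if baseline.n_channels != N_EEG_CHANNELS or baseline.rate != eeg.rate:
        raise ValueError("baseline must match the EEG channel count and rate")

    x = eeg.samples - eeg.samples.mean(axis=0, keepdims=True)  # CAR
    x = sps.sosfiltfilt(_eeg_sos(eeg.rate), x, axis=1)

    bad_mask = np.abs(x).max(axis=1) > bad_channel_uv
    labels = list(eeg.labels)
    rejected = tuple(l for l, b in zip(labels, bad_mask) if b)
    if bad_mask.mean() > trial_reject_fraction:
        return EpochSet(
            epochs=[],
            rate=eeg.rate,
            kept_channels=tuple(l for l, b in zip(labels, bad_mask) if not b),
            rejected_channels=rejected,
            rejected_reason=(
                f"{bad_mask.sum()}/{len(labels)} channels exceeded "
                f"{bad_channel_uv} uV (> {trial_reject_fraction:.0%})"
            ),
        )

    kept = [l for l, b in zip(labels, bad_mask) if not b]
    for ch in rejected:
        neigh, w = _interpolation_weights(ch, kept)
        idx = [labels.index(n) for n in neigh]
        x[labels.index(ch)] = w @ x[idx]

    # baseline offset from the 0-Hz recording (after CAR, matching the
    # reference of the trial data)
    b = baseline.samples - baseline.samples.mean(axis=0, keepdims=True)
    x = x - b.mean(axis=1, keepdims=True)

    n_epoch = int(EPOCH_SECONDS * eeg.rate)
    n_full = x.shape[1] // n_epoch
    epochs, dropped = [], []
    for i in range(n_full):
        ep = x[:, i * n_epoch : (i + 1) * n_epoch]
        if np.abs(ep).max() > bad_channel_uv:
            dropped.append(i)
        else:
            epochs.append(ep)
    return EpochSet(
        epochs=epochs,
        rate=eeg.rate,
        kept_channels=tuple(labels),
        rejected_channels=rejected,
        rejected_epochs=tuple(dropped),
    )


def eeg_band_relpower(epochset: EpochSet) -> np.ndarray:
    """Five relative band powers: per epoch and channel, Welch PSD band
    shares; averaged over channels, then over epochs."""
    if not epochset.epochs:
        raise ValueError("no usable epochs: EEG features are missing for this trial")
    per_epoch = []
    for ep in epochset.epochs:
        shares = relative_band_power(ep, epochset.rate, bands=EEG_BANDS, method="welch")
        per_epoch.append(shares.mean(axis=0))  # average over channels
    return np.mean(per_epoch, axis=0)


# --------------------------------------------------------------------
# per-measurement feature vector


def extract_features(
    measurement: Measurement,
    baseline_eeg: Recording | None = None,
) -> pd.Series:
    """The 19-parameter feature vector of one measurement.

    ``baseline_eeg`` is the subject's static (0-Hz) EEG used for
    baseline correction; the measurement's own EEG is used when it *is*
    the static protocol (or when no baseline is supplied).  If EEG
    preprocessing rejects the trial, the five EEG features are NaN and
    the remaining 14 are still produced.
    """
    if baseline_eeg is None:
        baseline_eeg = measurement.eeg
    out: dict[str, float] = {}

    epochset = eeg_preprocess(measurement.eeg, baseline_eeg)
    if epochset.rejected:
        for name in EEG_FEATURES:
            out[name] = np.nan
    else:
        for name, share in zip(EEG_FEATURES, eeg_band_relpower(epochset)):
            out[name] = float(share)

    filtered = bandpass_fir(measurement.emg.samples, measurement.emg.rate)
    for row, side in zip(filtered, ("L", "R")):
        out[f"emg_{side}_area"] = emg_area(row)
        shares = relative_band_power(row, measurement.emg.rate, EMG_BANDS, "periodogram")
        for tag, share in zip(_EMG_BAND_TAGS, shares):
            out[f"emg_{side}_{tag}"] = float(share)

    out["hr_average"], out["hr_std"] = hr_stats(measurement.hr)
    s = pd.Series(out).reindex(list(FEATURE_NAMES))
    s.attrs["eeg_rejected"] = epochset.rejected
    return s


def extract_cohort(measurements: list[Measurement]) -> pd.DataFrame:
    """Feature table for a cohort: subject_id, protocol + 19 features.

    Each subject's P0 EEG serves as the baseline for that subject's
    wave-protocol trials (and for the P0 trial itself).
    """
    baselines = {m.subject_id: m.eeg for m in measurements if m.protocol.name == "P0"}
    rows = []
    for m in measurements:
        feats = extract_features(m, baselines.get(m.subject_id))
        rows.append({"subject_id": m.subject_id, "protocol": m.protocol.name, **feats})
    return pd.DataFrame(rows)
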