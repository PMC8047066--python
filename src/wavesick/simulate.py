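"""Synthetic cohort generator with controllable signal-symptom coupling.

The study's raw recordings are not deposited, so every downstream stage
is exercised on simulated cohorts that reproduce the study layout
(28 subjects x 3 protocols with one subject missing the 3-Hz protocol,
i.e. 83 measurements) and carry a *known*, tunable statistical coupling
between a latent motion-sickness susceptibility, the biosignals, and
the ordinal symptom scores.

Generative model (all constructs are the simulator's own; the stimulus
``intensity`` is the protocol's wave frequency times its mean platform
amplitude fraction, 0 for the static baseline):

EEG
    Per channel: 1/f background plus band-limited oscillators (delta,
    theta, alpha, beta, low gamma), synthesised in the frequency domain.
    The beta oscillator's amplitude is scaled by
    ``(1 + eeg_beta_effect * susceptibility * intensity)``.
EMG
    Gaussian noise spectrally shaped to the 40-500 Hz envelope, one
    30-s segment per platform step.  Both the overall amplitude and the
    low-band (40-132 Hz) share grow with
    ``s = platform_fraction * (1 + emg_amp_effect * susceptibility)``.
HR
    A 1-Hz beats/min series: subject baseline plus
    ``hr_effect * susceptibility * intensity`` plus AR(1) drift.
Questionnaire
    Ordinal threshold model: each symptom score counts how many of its
    two cut points lie below ``symptom_gain * susceptibility *
    intensity`` + noise.  The null preset sets every effect *and*
    ``symptom_gain`` to zero: protocol intensity raises EMG amplitude by
    construction (the platform moves), so symptoms must be severed from
    the protocol too for features and indexes to be truly independent.

A single integer seed drives a hierarchical ``SeedSequence`` scheme
(subject -> protocol -> modality/questionnaire), so identical configs
give bit-identical cohorts and partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .indexes import SYMPTOMS, QuestionnaireResponse
from .protocols import PROTOCOLS, ProtocolSpec
from .recording import N_EEG_CHANNELS, SAMPLING_RATES, Measurement, Recording

# --------------------------------------------------------------------
# configuration

#: Extra spectral weight given to the EMG low band per unit of the
#: coupling scalar s (see module docstring).
EMG_LOWBAND_GAIN = 0.6

#: AR(1) coefficient of the heart-rate drift.
HR_AR_COEF = 0.9

#: SD of the per-measurement lognormal jitter applied to each EEG
#: oscillator's power (and the background).  Emulates the large
#: trial-to-trial spectral variability of dry-electrode EEG; drawn
#: independently of the latent state, so it is pure measurement noise.
EEG_BAND_JITTER_SD = 0.4

_DEFAULT_CUTS: dict[str, tuple[float, float]] = {s: (0.35, 0.90) for s in SYMPTOMS}
# rarer vegetative symptoms get higher cut points
_DEFAULT_CUTS["salivation"] = (0.60, 1.40)
_DEFAULT_CUTS["burping"] = (0.80, 1.60)

_DEFAULT_NOISE = {"eeg": 15.0, "emg": 0.15, "hr": 1.5, "symptom": 0.30}


@dataclass(frozen=True)
class LatentState:
    """Per-subject latent traits (generative stand-in for individual
    differences in motion-sickness susceptibility and physiology)."""

    susceptibility: float  # in [0, 1]
    hr_baseline: float  # beats/min
    emg_tone: float  # muscle-noise RMS scale, microvolt, > 0
    eeg_beta_gain: float  # baseline beta-oscillator gain, > 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.susceptibility <= 1.0:
            raise ValueError("susceptibility must lie in [0, 1]")
        for name in ("hr_baseline", "emg_tone", "eeg_beta_gain"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


@dataclass(frozen=True)
class CouplingConfig:
    """Effect sizes, noise levels and the seed of one simulation."""

    emg_amp_effect: float = 0.0
    hr_effect: float = 0.0  # beats/min per unit susceptibility*intensity
    eeg_beta_effect: float = 0.0
    #: multiplies the symptom drive g = susceptibility * intensity; 0
    #: severs the questionnaire from protocol and latent state entirely
    symptom_gain: float = 1.0
    symptom_cuts: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CUTS)
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    seed: int = 0

    def __post_init__(self) -> None:
        for s, (lo, hi) in self.symptom_cuts.items():
            if s not in SYMPTOMS:
                raise ValueError(f"unknown symptom {s!r} in cut points")
            if not lo < hi:
                raise ValueError(f"cut points for {s} must be strictly increasing")
        if set(self.symptom_cuts) != set(SYMPTOMS):
            raise ValueError("cut points required for all 13 symptoms")
        for k in ("eeg", "emg", "hr", "symptom"):
            if self.noise_sd.get(k, 0.0) <= 0:
                raise ValueError(f"noise_sd[{k!r}] must be positive")


#: Named effect-size presets.  ``null`` decouples signals from the
#: latent susceptibility entirely (calibration runs); ``strong`` gives
#: the muscle channel a dominant, heart rate a strong and EEG beta a
#: modest coupling, mirroring the qualitative pattern the paradigm
#: reports (EMG >> EEG in both screening and feature importance).
PRESETS: dict[str, dict[str, float]] = {
    "null": dict(emg_amp_effect=0.0, hr_effect=0.0, eeg_beta_effect=0.0,
                 symptom_gain=0.0),
    "weak": dict(emg_amp_effect=0.6, hr_effect=6.0, eeg_beta_effect=0.15),
    "strong": dict(emg_amp_effect=2.0, hr_effect=20.0, eeg_beta_effect=0.3),
}


def preset_config(name: str, seed: int = 0) -> CouplingConfig:
    """Build a :class:`CouplingConfig` from a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = CouplingConfig(seed=seed, **PRESETS[name])
    if name == "strong":
        cfg = replace(cfg, noise_sd={**_DEFAULT_NOISE, "symptom": 0.25})
    return cfg


# --------------------------------------------------------------------
# latent traits


def draw_latent(rng: np.random.Generator) -> LatentState:
    """Draw one subject's latent traits (independent components)."""
    return LatentState(
        susceptibility=float(rng.uniform(0.0, 1.0)),
        hr_baseline=float(np.clip(rng.normal(70.0, 8.0), 45.0, 110.0)),
        emg_tone=float(30.0 * rng.lognormal(0.0, 0.25)),
        eeg_beta_gain=float(rng.lognormal(0.0, 0.2)),
    )


# --------------------------------------------------------------------
# modality generators


def _spectral_noise(
    rng: np.random.Generator, amp: np.ndarray, n: int, n_channels: int
) -> np.ndarray:
    """Real noise with target amplitude spectrum via frequency-domain
    synthesis (one irfft per channel block)."""
    nf = amp.size
    spec = amp * (
        rng.standard_normal((n_channels, nf)) + 1j * rng.standard_normal((n_channels, nf))
    )
    spec[:, 0] = 0.0
    return np.fft.irfft(spec, n, axis=1)


def _eeg_channel_names() -> tuple[str, ...]:
    from .features import eeg_layout  # local import to avoid a cycle

    return tuple(eeg_layout()["label"])


#: EEG oscillator bumps: (band, centre Hz, width Hz, relative power).
_EEG_BUMPS = (
    ("delta", 2.0, 1.2, 3.0),
    ("theta", 6.0, 1.5, 1.5),
    ("alpha", 10.0, 1.5, 4.0),
    ("beta", 21.0, 6.0, 0.8),
    ("lg", 37.5, 1.5, 0.4),
)


def generate_eeg(
    latent: LatentState,
    protocol: ProtocolSpec,
    config: CouplingConfig,
    rng: np.random.Generator,
) -> Recording:
    rate = SAMPLING_RATES["EEG"]
    n = int(round(protocol.duration * rate))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)

    beta_scale = latent.eeg_beta_gain * (
        1.0 + config.eeg_beta_effect * latent.susceptibility * protocol.intensity
    )
    # per-measurement spectral variability (background + 5 oscillators)
    jit = np.exp(EEG_BAND_JITTER_SD * rng.standard_normal(6))
    gains = {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": beta_scale**2, "lg": 1.0}
    # relative PSD profile: pink background + five oscillator bumps
    psd = jit[0] / (freqs + 0.5)
    for j, (name, center, width, power) in zip(jit[1:], _EEG_BUMPS):
        psd = psd + j * gains[name] * power * np.exp(
            -0.5 * ((freqs - center) / width) ** 2
        )
    amp = np.sqrt(psd)

    # calibrate the *uncoupled* spectrum to the configured RMS so that
    # beta coupling raises absolute (and relative) beta power
    psd0 = 1.0 / (freqs + 0.5)
    for _name, center, width, power in _EEG_BUMPS:
        psd0 = psd0 + power * np.exp(-0.5 * ((freqs - center) / width) ** 2)
    expected_rms = 2.0 * np.sqrt(psd0[1:].sum()) / n
    k = config.noise_sd["eeg"] / expected_rms

    x = _spectral_noise(rng, amp * k, n, N_EEG_CHANNELS)
    return Recording(x, rate, _eeg_channel_names())


def _emg_segment(
    rng: np.random.Generator,
    n: int,
    rate: float,
    rms: float,
    lowband_weight: float,
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    psd = np.where((freqs >= 40.0) & (freqs <= 500.0), 1.0, 1e-6)
    psd = np.where((freqs >= 40.0) & (freqs < 132.0), psd * lowband_weight, psd)
    x = _spectral_noise(rng, np.sqrt(psd), n, 2)
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def generate_emg(
    latent: LatentState,
    protocol: ProtocolSpec,
    config: CouplingConfig,
    rng: np.random.Generator,
) -> Recording:
    rate = SAMPLING_RATES["EMG"]
    segments = protocol.segments or (None,)
    parts = []
    for seg in segments:
        dur = seg.duration if seg is not None else protocol.duration
        frac = (seg.platform_amplitude / 100.0) if seg is not None else 0.0
        s = frac * (1.0 + config.emg_amp_effect * latent.susceptibility)
        # independent lognormal amplitude jitter per leg and segment
        jitter = np.exp(config.noise_sd["emg"] * rng.standard_normal((2, 1)))
        rms = latent.emg_tone * (1.0 + s) * jitter
        parts.append(
            _emg_segment(
                rng,
                int(round(dur * rate)),
                rate,
                rms,
                1.0 + EMG_LOWBAND_GAIN * s,
            )
        )
    return Recording(np.concatenate(parts, axis=1), rate, ("EMG_L", "EMG_R"))


def generate_hr(
    latent: LatentState,
    protocol: ProtocolSpec,
    config: CouplingConfig,
    rng: np.random.Generator,
) -> Recording:
    rate = SAMPLING_RATES["HR"]
    n = int(round(protocol.duration * rate))
    sd = config.noise_sd["hr"]
    drift = np.empty(n)
    drift[0] = rng.normal(0.0, sd / np.sqrt(1.0 - HR_AR_COEF**2))
    eps = rng.normal(0.0, sd, n - 1)
    for t in range(1, n):
        drift[t] = HR_AR_COEF * drift[t - 1] + eps[t - 1]
    level = latent.hr_baseline + config.hr_effect * latent.susceptibility * protocol.intensity
    return Recording(level + drift, rate, ("HR",))


_GENERATORS = {"EEG": generate_eeg, "EMG": generate_emg, "HR": generate_hr}


def generate_recording(
    latent: LatentState,
    protocol: ProtocolSpec,
    modality: str,
    config: CouplingConfig,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Generate one modality's recording for one measurement."""
    if modality not in _GENERATORS:
        raise KeyError(f"unknown modality {modality!r}; choose from {sorted(_GENERATORS)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _GENERATORS[modality](latent, protocol, config, rng)


def generate_questionnaire(
    latent: LatentState,
    protocol: ProtocolSpec,
    config: CouplingConfig,
    rng: np.random.Generator | None = None,
) -> QuestionnaireResponse:
    """Ordinal threshold model: score = #cut points below g + noise,
    with g = symptom_gain * susceptibility * intensity."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = config.symptom_gain * latent.susceptibility * protocol.intensity
    scores = {}
    for s in SYMPTOMS:
        z = g + rng.normal(0.0, config.noise_sd["symptom"])
        lo, hi = config.symptom_cuts[s]
        scores[s] = int(z > lo) + int(z > hi)
    return QuestionnaireResponse(scores)


# --------------------------------------------------------------------
# cohorts


def default_missing(n_subjects: int) -> list[tuple[str, str]]:
    """Default cohort layout: the last subject skips the 3-Hz protocol,
    mirroring the (n x 3) - 1 study design."""
    return [(subject_id(n_subjects, n_subjects), "P3")]


def subject_id(i: int, n_subjects: int) -> str:
    width = max(2, len(str(n_subjects)))
    return f"S{i:0{width}d}"


def iter_subject_measurements(
    n_subjects: int,
    missing: Sequence[tuple[str, str]] | None = None,
    config: CouplingConfig | None = None,
):
    """Yield one subject at a time as a list of
    (Measurement, QuestionnaireResponse) pairs.

    Full-size EEG is ~30 MB per measurement, so cohorts of hundreds of
    subjects must be consumed subject-by-subject (features extracted,
    recordings discarded) rather than materialised; this iterator is
    the streaming core behind :func:`generate_cohort`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or CouplingConfig()
    if missing is None:
        missing = default_missing(n_subjects)
    valid_ids = {subject_id(i, n_subjects) for i in range(1, n_subjects + 1)}
    seen = set()
    for pair in missing:
        sid, prot = pair
        if sid not in valid_ids or prot not in PROTOCOLS:
            raise ValueError(f"missing pair {pair!r} refers to no valid subject/protocol")
        if pair in seen:
            raise ValueError(f"duplicate missing pair {pair!r}")
        seen.add(pair)

    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(n_subjects)
    for i, sseq in enumerate(subject_seqs, start=1):
        sid = subject_id(i, n_subjects)
        latent_seq, *proto_seqs = sseq.spawn(1 + len(PROTOCOLS))
        latent = draw_latent(np.random.default_rng(latent_seq))
        out: list[tuple[Measurement, QuestionnaireResponse]] = []
        for pname, pseq in zip(PROTOCOLS, proto_seqs):
            if (sid, pname) in seen:
                continue
            protocol = PROTOCOLS[pname]
            eeg_s, emg_s, hr_s, q_s = pseq.spawn(4)
            meas = Measurement(
                subject_id=sid,
                protocol=protocol,
                eeg=generate_eeg(latent, protocol, config, np.random.default_rng(eeg_s)),
                emg=generate_emg(latent, protocol, config, np.random.default_rng(emg_s)),
                hr=generate_hr(latent, protocol, config, np.random.default_rng(hr_s)),
                meta={
                    "susceptibility": latent.susceptibility,
                    "intensity": protocol.intensity,
                },
            )
            resp = generate_questionnaire(
                latent, protocol, config, np.random.default_rng(q_s)
            )
            out.append((meas, resp))
        yield out


def generate_cohort(
    n_subjects: int,
    missing: Sequence[tuple[str, str]] | None = None,
    config: CouplingConfig | None = None,
) -> list[tuple[Measurement, QuestionnaireResponse]]:
    """Generate a full cohort: one (Measurement, QuestionnaireResponse)
    pair per subject x protocol, minus the ``missing`` pairs.

    ``missing`` defaults to the study layout (last subject missing P3);
    pass ``[]`` for a complete grid.  Identical config (including seed)
    yields a bit-identical cohort.  For large cohorts prefer
    :func:`iter_subject_measurements` — this materialises every
    recording at once.
    """
    return [
        pair
        for subject in iter_subject_measurements(n_subjects, missing, config)
        for pair in subject
    ]
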