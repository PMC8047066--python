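"""Measurement protocols for the wave-platform paradigm.

Each subject stands on a motion platform synchronized with a VR sea
scene and is measured under three protocols: a static 60-s baseline
(P0), and two 120-s wave protocols at 1 Hz (P1) and 3 Hz (P3).  The
wave protocols are divided into four 30-s segments whose platform
movement amplitude follows the fixed staircase 25 / 50 / 75 / 25 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Segment:
    """One constant-amplitude stretch of a protocol."""

    duration: float  # s
    platform_amplitude: float  # percent of full platform excursion


@dataclass(frozen=True)
class ProtocolSpec:
    """Immutable description of one acquisition protocol.

    Parameters
    ----------
    name : {"P0", "P1", "P3"}
    wave_frequency : float
        Simulated wave frequency in Hz (0, 1 or 3).
    wave_amplitude : float
        Unitless wave amplitude set in the simulator (0, 0.6, 0.5).
    duration : float
        Total protocol duration in seconds (60 or 120).
    segments : tuple of Segment
        Empty for the static baseline; four 30-s segments otherwise.
    """

    name: str
    wave_frequency: float
    wave_amplitude: float
    duration: float
    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.name not in ("P0", "P1", "P3"):
            raise ValueError(f"unknown protocol name {self.name!r}")
        if self.segments:
            if len(self.segments) != 4 or any(s.duration != 30.0 for s in self.segments):
                raise ValueError("wave protocols need exactly four 30-s segments")
            if abs(sum(s.duration for s in self.segments) - self.duration) > 1e-9:
                raise ValueError("segment durations must total the protocol duration")
            amps = tuple(s.platform_amplitude for s in self.segments)
            if amps != (25.0, 50.0, 75.0, 25.0):
                raise ValueError("platform amplitudes must follow 25/50/75/25 %")
        elif self.duration != 60.0:
            raise ValueError("the static baseline lasts 60 s")

    @property
    def mean_platform_fraction(self) -> float:
        """Mean platform amplitude over the protocol, as a fraction of 1."""
        if not self.segments:
            return 0.0
        total = sum(s.duration * s.platform_amplitude / 100.0 for s in self.segments)
        return total / self.duration

    @property
    def intensity(self) -> float:
        """Scalar stimulus intensity: wave frequency x mean platform fraction.

        The product ranks the protocols the way the paradigm treats them
        (static < 1 Hz < 3 Hz); it is the simulator's own construct, used
        to couple latent susceptibility to signals and symptoms.
        """
        return self.wave_frequency * self.mean_platform_fraction


def _wave_segments() -> tuple[Segment, ...]:
    return tuple(Segment(30.0, a) for a in (25.0, 50.0, 75.0, 25.0))


PROTOCOLS: dict[str, ProtocolSpec] = {
    "P0": ProtocolSpec("P0", 0.0, 0.0, 60.0),
    "P1": ProtocolSpec("P1", 1.0, 0.6, 120.0, _wave_segments()),
    "P3": ProtocolSpec("P3", 3.0, 0.5, 120.0, _wave_segments()),
}

PROTOCOL_NAMES = tuple(PROTOCOLS)
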