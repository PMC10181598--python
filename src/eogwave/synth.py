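"""Synthetic two-channel EOG generator emulating the study acquisition protocol.

The emulated session is five 10-s movement periods (down, up, blink, left,
right) of 6500 samples each at 650 Hz — 32,500 samples per channel — with
voltages inside a −0.3 … 0.5 V envelope, band-limited to 0.5–50 Hz and
quantized to 11 bits, as a Biopac-style recording chain would produce.

Each movement period is the superposition of

* a saccade pulse: sigmoid rise, plateau, sigmoid return to rest, with
  class-specific signed amplitude on the class's channel (positive for
  right/up, negative for left/down); blinks instead carry a train of
  biphasic difference-of-Gaussians spikes on the vertical channel with a
  small horizontal crosstalk;
* a sinusoidal activity carrier whose amplitude is class-specific.  The
  carrier stands in for the sustained oculomotor activity of holding the
  gaze and makes every short analysis window carry class information, not
  only the windows containing a saccade edge (see docs/methods.md for what
  this idealization does and does not emulate);
* additive white noise, band-limited together with everything else by the
  final zero-phase 0.5–50 Hz Butterworth filter.

Identical seeds produce bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, sosfilt

from .io import (
    CLASS_IDS,
    DEFAULT_SAMPLES_PER_SEGMENT,
    DEFAULT_SAMPLING_RATE,
    DEFAULT_SEGMENT_ORDER,
    EOGRecording,
    apply_segment_table,
    default_segment_table,
)

__all__ = [
    "ClassWave",
    "SyntheticConfig",
    "generate_recording",
    "perturb_separability",
    "DEFAULT_AMPLITUDE_MAP",
]


@dataclass(frozen=True)
class ClassWave:
    """Per-class waveform amplitudes.

    ``pulse_volts`` is the signed saccade (or blink-spike) peak; its sign is
    the action-potential polarity of the movement.  ``carrier_volts`` is the
    peak amplitude of the sustained activity carrier.  ``channel`` names the
    electrode pair the movement projects onto.
    """

    channel: str  # "horizontal" | "vertical"
    pulse_volts: float
    carrier_volts: float


# Pulse amplitudes follow the published per-movement voltage thresholds
# (right +0.25 V / left −0.25 V horizontal; up +0.2 V / down −0.1 V vertical;
# blink spikes approaching +0.45 V vertical). Carrier amplitudes are spaced
# by a factor >= 3 between classes sharing a channel so that 4-sample
# windows of 20–40 Hz content discriminate the classes reliably.
DEFAULT_AMPLITUDE_MAP: Mapping[str, ClassWave] = {
    "down": ClassWave("vertical", -0.10, 0.020),
    "up": ClassWave("vertical", 0.20, 0.070),
    "blink": ClassWave("vertical", 0.45, 0.220),
    "left": ClassWave("horizontal", -0.25, 0.045),
    "right": ClassWave("horizontal", 0.25, 0.150),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic acquisition session."""

    samples_per_segment: int = DEFAULT_SAMPLES_PER_SEGMENT
    segment_order: Sequence[str] = DEFAULT_SEGMENT_ORDER
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    amplitude_map: Mapping[str, ClassWave] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_MAP)
    )
    noise_sd: float = 0.004
    band_limits: tuple[float, float] = (0.5, 50.0)
    quantization_bits: int = 11
    seed: int = 4
    carrier_hz: float = 26.0
    blink_crosstalk: float = 0.15
    envelope: tuple[float, float] = (-0.3, 0.5)

    @property
    def n_samples(self) -> int:
        return self.samples_per_segment * len(self.segment_order)

    def validate(self) -> None:
        if self.samples_per_segment <= 0:
            raise ValueError("samples_per_segment must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.band_limits
        if hi <= lo or lo <= 0:
            raise ValueError(f"band_limits must be an ordered Hz pair, got {self.band_limits}")
        if hi >= self.sampling_rate / 2:
            raise ValueError("band upper edge must lie below the Nyquist frequency")
        if self.quantization_bits < 1:
            raise ValueError("quantization_bits must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.envelope[1] <= self.envelope[0]:
            raise ValueError("envelope must be an ordered voltage pair")
        for name in self.segment_order:
            if name not in CLASS_IDS:
                raise ValueError(f"unknown movement {name!r} in segment_order")
            if name not in self.amplitude_map:
                raise ValueError(f"amplitude_map is missing movement {name!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _segment_wave(
    cls: str, wave: ClassWave, t: np.ndarray, duration: float, phase: float, carrier_hz: float
) -> np.ndarray:
    """Deterministic waveform of one movement period on its own channel."""
    if cls == "blink":
        sig = np.zeros_like(t)
        # spike train: people blink repeatedly during a blink-recording period
        for frac in (0.15, 0.30, 0.45, 0.60, 0.75):
            tc = frac * duration
            narrow = np.exp(-0.5 * ((t - tc) / (0.008 * duration)) ** 2)
            wide = np.exp(-0.5 * ((t - tc) / (0.020 * duration)) ** 2)
            sig += wave.pulse_volts * (narrow - 0.6 * wide) / 0.4
    else:
        # fast saccade onset (~80 ms transition), slower return to rest:
        # the outward deflection dominates the trace as in real
        # per-movement recordings
        rise, fall = 0.2 * duration, 0.7 * duration
        sig = wave.pulse_volts * (
            _sigmoid((t - rise) / 0.01) - _sigmoid((t - fall) / (0.08 * duration))
        )
    sig += wave.carrier_volts * np.sin(2.0 * np.pi * carrier_hz * t + phase)
    return sig


def generate_recording(config: SyntheticConfig | None = None) -> EOGRecording:
    """Generate a labelled two-channel recording under the study protocol.

    The per-sample labels follow ``config.segment_order`` with the standard
    class ids; all voltages lie inside ``config.envelope`` and are quantized
    to ``2**quantization_bits`` uniform levels across it.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    sps = config.samples_per_segment
    duration = sps / config.sampling_rate
    t = np.arange(sps) / config.sampling_rate

    h_parts, v_parts = [], []
    for cls in config.segment_order:
        wave = config.amplitude_map[cls]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sig = _segment_wave(cls, wave, t, duration, phase, config.carrier_hz)
        cross = config.blink_crosstalk * sig if cls == "blink" else np.zeros_like(sig)
        if wave.channel == "vertical":
            v_parts.append(sig)
            h_parts.append(cross)
        else:
            h_parts.append(sig)
            v_parts.append(cross)
    h = np.concatenate(h_parts)
    v = np.concatenate(v_parts)
    n = h.size
    h = h + rng.normal(0.0, config.noise_sd, n) if config.noise_sd else h
    v = v + rng.normal(0.0, config.noise_sd, n) if config.noise_sd else v

    # acquisition chain: causal analogue band-pass (AC coupling preserves
    # deflection polarity but droops plateaus), saturation, uniform quantizer
    sos = butter(4, config.band_limits, btype="band", fs=config.sampling_rate, output="sos")
    h = sosfilt(sos, h)
    v = sosfilt(sos, v)
    lo, hi = config.envelope
    step = (hi - lo) / 2**config.quantization_bits
    h = np.clip(np.round(np.clip(h, lo, hi) / step) * step, lo, hi)
    v = np.clip(np.round(np.clip(v, lo, hi) / step) * step, lo, hi)

    recording = EOGRecording(h, v, config.sampling_rate)
    table = default_segment_table(sps, config.segment_order)
    return apply_segment_table(recording, table)


def perturb_separability(
    recording: EOGRecording, overlap: float, seed: int = 0
) -> EOGRecording:
    """Blend each sample toward a class-agnostic pool to control separability.

    With mixing fraction ``overlap`` f, every output sample is
    ``(1-f)*own + f*pooled`` where ``pooled`` is the voltage of a uniformly
    random class at a uniformly random position inside that class's samples
    (the same draw on both channels, preserving the H/V coupling).  At f=0
    the recording is returned unchanged; at f=1 every class has the same
    (pooled) amplitude distribution and no temporal alignment survives, so
    feature windows of different classes are statistically indistinguishable.

    Requires a labelled recording with equally many samples per class.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap}")
    if recording.labels is None:
        raise ValueError("perturb_separability requires a labelled recording")
    if overlap == 0.0:
        return recording.copy()

    classes = np.unique(recording.labels)
    index_by_class = [np.flatnonzero(recording.labels == c) for c in classes]
    counts = {len(idx) for idx in index_by_class}
    if len(counts) != 1:
        raise ValueError("classes must have equal sample counts to pool them")
    per_class = counts.pop()
    positions = np.vstack(index_by_class)  # (n_classes, per_class)

    rng = np.random.default_rng(seed)
    n = recording.n_samples
    src_class = rng.integers(0, len(classes), size=n)
    src_pos = rng.integers(0, per_class, size=n)
    pooled = positions[src_class, src_pos]

    h = (1.0 - overlap) * recording.horizontal + overlap * recording.horizontal[pooled]
    v = (1.0 - overlap) * recording.vertical + overlap * recording.vertical[pooled]
    return replace(recording.copy(), horizontal=h, vertical=v)
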