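"""Tone-cloud and white-noise stimulus synthesis.

A tone cloud is a rapid stream of brief, overlapping pure tones. Tones are
drawn from three octaves (low C7..B7, middle C8..B8, high C9..B9); the
*stimulus strength* is the percentage of tones drawn from the dominant
octave, the remainder being sampled uniformly from the 24 pitches of the
other two octaves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.io import wavfile

__all__ = [
    "PitchTable",
    "ToneCloudSpec",
    "Waveform",
    "pitch_frequency",
    "octave_pitches",
    "build_pitch_table",
    "sample_cloud_events",
    "n_cloud_events",
    "pure_tone",
    "apply_ramps",
    "synthesize_cloud",
    "white_noise",
    "write_wav",
    "read_wav",
]

# Semitone offset of each pitch class relative to C.
_NOTE_OFFSETS = {
    "C": 0, "C#": 1, "D": 2, "D#": 3, "E": 4, "F": 5,
    "F#": 6, "G": 7, "G#": 8, "A": 9, "A#": 10, "B": 11,
}
_PITCH_CLASSES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]
_PITCH_RE = re.compile(r"^([A-G]#?)(-?\d+)$")

#: Octave labels -> octave number of the 12 pitches spanning it.
OCTAVE_NUMBERS = {"low": 7, "middle": 8, "high": 9}
OCTAVE_NAMES = ("low", "middle", "high")

A4_FREQUENCY = 440.0  # 12-TET anchor


def pitch_frequency(pitch_name: str) -> float:
    """12-tone equal-temperament frequency (Hz) of a pitch, A4 = 440 Hz.

    Parameters
    ----------
    pitch_name : str
        Note letter A-G, optional ``#``, followed by an octave number,
        e.g. ``"C7"`` or ``"A#4"``.

    Returns
    -------
    float
        Frequency in Hz at full precision (round only for display).
    """
    m = _PITCH_RE.match(pitch_name)
    if m is None:
        raise ValueError(f"malformed pitch name: {pitch_name!r}")
    note, octave = m.group(1), int(m.group(2))
    # semitone distance from A4
    semitones = (octave - 4) * 12 + _NOTE_OFFSETS[note] - _NOTE_OFFSETS["A"]
    return A4_FREQUENCY * 2.0 ** (semitones / 12.0)


def octave_pitches(octave: str) -> list[str]:
    """The 12 pitch names (C..B) of a named octave (low/middle/high)."""
    if octave not in OCTAVE_NUMBERS:
        raise ValueError(f"unknown octave {octave!r}; expected one of {OCTAVE_NAMES}")
    n = OCTAVE_NUMBERS[octave]
    return [f"{pc}{n}" for pc in _PITCH_CLASSES]


@dataclass(frozen=True)
class PitchTable:
    """Mapping from pitch names to 12-TET frequencies in Hz."""

    entries: Mapping[str, float]

    def __getitem__(self, pitch_name: str) -> float:
        return self.entries[pitch_name]

    def octave(self, octave: str) -> dict[str, float]:
        return {p: self.entries[p] for p in octave_pitches(octave)}


def build_pitch_table(extra_pitches: tuple[str, ...] = ("A4",)) -> PitchTable:
    """Pitch table over the three stimulus octaves plus reference pitches."""
    entries: dict[str, float] = {}
    for octave in OCTAVE_NAMES:
        for p in octave_pitches(octave):
            entries[p] = pitch_frequency(p)
    for p in extra_pitches:
        entries.setdefault(p, pitch_frequency(p))
    return PitchTable(entries)


@dataclass(frozen=True)
class ToneCloudSpec:
    """Parametric description of one tone-cloud stimulus.

    ``strength`` percent of tones come from ``dominant_octave``; the rest are
    sampled uniformly from the 24 pitches of the two other octaves.
    """

    strength: float = 100.0
    dominant_octave: str = "middle"
    duration: float = 0.51
    rate: float = 100.0
    tone_duration: float = 0.030
    ramp_duration: float = 0.003
    sample_rate: int = 44100
    seed: int | None = None
    amplitude: float = 0.9

    def __post_init__(self) -> None:
        if not (50.0 <= self.strength <= 100.0):
            raise ValueError(f"strength must be in [50, 100], got {self.strength}")
        if self.dominant_octave not in OCTAVE_NUMBERS:
            raise ValueError(f"unknown dominant_octave {self.dominant_octave!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.ramp_duration > self.tone_duration / 2:
            raise ValueError("ramp_duration must be <= tone_duration / 2")
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ToneCloudSpec":
        return cls(**dict(d))


@dataclass
class Waveform:
    """Rendered audio samples plus their sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def n_cloud_events(duration: float, rate: float) -> int:
    """Number of tone onsets in [0, duration) at fixed inter-onset 1/rate.

    Onsets sit at k/rate for k = 0, 1, ...; an onset exactly at ``duration``
    is excluded. Robust to float representation of duration*rate.
    """
    n = duration * rate
    nearest = round(n)
    if abs(n - nearest) < 1e-9:
        return int(nearest)
    return int(np.ceil(n))


def sample_cloud_events(
    spec: ToneCloudSpec, rng: np.random.Generator
) -> list[tuple[float, str]]:
    """Draw the (onset_time, pitch_name) events of one tone cloud.

    Each pitch comes from the dominant octave with probability
    ``strength/100``, otherwise uniformly from the 24 pitches of the other
    two octaves.
    """
    n = n_cloud_events(spec.duration, spec.rate)
    dominant = octave_pitches(spec.dominant_octave)
    others = [
        p
        for name in OCTAVE_NAMES
        if name != spec.dominant_octave
        for p in octave_pitches(name)
    ]
    p_dom = spec.strength / 100.0
    events: list[tuple[float, str]] = []
    for k in range(n):
        onset = k / spec.rate
        if rng.random() < p_dom:
            pitch = dominant[rng.integers(len(dominant))]
        else:
            pitch = others[rng.integers(len(others))]
        events.append((onset, pitch))
    return events


def pure_tone(
    frequency: float, duration: float, sample_rate: int, amplitude: float = 1.0
) -> Waveform:
    """Unramped sinusoid of the given frequency and duration."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return Waveform(amplitude * np.sin(2 * np.pi * frequency * t), sample_rate)


def apply_ramps(tone: Waveform, ramp_duration: float) -> Waveform:
    """Apply raised-cosine (Hann half-window) rise and decay ramps.

    The first and last samples end up at amplitude zero; the middle of the
    tone is left untouched.
    """
    n = len(tone)
    n_ramp = int(round(ramp_duration * tone.sample_rate))
    if n_ramp == 0:
        return Waveform(tone.samples.copy(), tone.sample_rate)
    if 2 * n_ramp > n:
        raise ValueError("ramp_duration must be <= half the tone duration")
    env = np.ones(n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / max(n_ramp - 1, 1)))
    env[:n_ramp] = ramp
    env[n - n_ramp:] = ramp[::-1]
    return Waveform(tone.samples * env, tone.sample_rate)


def synthesize_cloud(
    spec: ToneCloudSpec, rng: np.random.Generator | None = None
) -> Waveform:
    """Render a tone cloud to samples.

    Tones whose tail would exceed the nominal duration are truncated at the
    boundary with the decay ramp applied inside it, so the waveform length is
    exactly round(duration * sample_rate). Peak-normalized to
    ``spec.amplitude``. Identical seeds give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n_total = int(round(spec.duration * sr))
    buf = np.zeros(n_total)
    for onset, pitch in sample_cloud_events(spec, rng):
        i0 = int(round(onset * sr))
        n_tone = int(round(spec.tone_duration * sr))
        n_avail = min(n_tone, n_total - i0)
        if n_avail <= 0:
            continue
        tone = pure_tone(pitch_frequency(pitch), n_avail / sr, sr)
        # ramp within the (possibly truncated) extent so edges are clickless
        ramp = min(spec.ramp_duration, (n_avail / sr) / 2)
        tone = apply_ramps(tone, ramp)
        buf[i0 : i0 + n_avail] += tone.samples
    peak = np.max(np.abs(buf))
    if peak > 0:
        buf *= spec.amplitude / peak
    return Waveform(buf, sr)


def white_noise(
    duration: float,
    sample_rate: int = 44100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    amplitude: float = 0.9,
) -> Waveform:
    """Zero-mean Gaussian noise, peak-normalized, seeded."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    if n == 0:
        return Waveform(np.empty(0), sample_rate)
    x = rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= amplitude / peak
    return Waveform(x, sample_rate)


def write_wav(waveform: Waveform, path, subtype: str = "float32") -> None:
    """Write a waveform as RIFF/WAV (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        data = waveform.samples.astype(np.float32)
    elif subtype == "pcm16":
        data = np.clip(np.round(waveform.samples * 32767.0), -32768, 32767).astype(
            np.int16
        )
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(str(path), waveform.sample_rate, data)


def read_wav(path) -> Waveform:
    """Read a WAV file back into a float waveform in [-1, 1]."""
    sr, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, int(sr))
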