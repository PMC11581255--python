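"""Synthetic motor-imagery EEG generator.

Emulates the class signal that motor-imagery classifiers exploit:
event-related desynchronization (ERD), the contralateral attenuation of
the sensorimotor mu (8-13 Hz) and beta (13-30 Hz) rhythms during
imagined hand movement.  Each channel carries 1/f^a "pink" background
noise plus mu and beta oscillations at random frequency and phase; for
the imagined hand's *contralateral* lateral channel group the
oscillation amplitude is scaled by ``1 - erd_depth``.

The channel layout is a minimal three-group proxy of the sensorimotor
strip: one left-hemisphere group, a midline group and a
right-hemisphere group (C3 / Cz / C4 by default), which is the smallest
layout on which "contralateral ERD" is well defined.  Volume conduction
and ocular/muscular artifacts are deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .epochs import EEGEpoch, save_dataset

#: maps class label -> hemisphere whose lateral group shows ERD
CONTRALATERAL = {"left_hand": "right", "right_hand": "left"}


@dataclass
class SynthConfig:
    """Generator settings; defaults are a plausible two-class MI setup.

    ``snr_db`` is the oscillation-to-noise power ratio per channel
    before any ERD attenuation; ``erd_depth`` in [0, 1] is the
    fractional amplitude attenuation on the contralateral group (0 = no
    class signal, 1 = rhythm fully suppressed).
    """

    fs: float = 250.0
    n_channels: int = 3
    epoch_seconds: float = 2.0
    classes: tuple[str, ...] = ("left_hand", "right_hand")
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    erd_depth: float = 0.6
    noise_exponent: float = 1.0
    snr_db: float = 10.0
    erd_onset_ramp: bool = False
    seed: int = 0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if not self.fs > 2 * max(self.beta_band):
            raise ValueError("fs must exceed twice the top beta frequency")
        if not self.channel_names:
            if self.n_channels == 3:
                self.channel_names = ("C3", "Cz", "C4")
            else:
                self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))

    def channel_groups(self) -> dict[str, list[int]]:
        """Split channel indices into left / midline / right groups."""
        n = self.n_channels
        third = max(1, n // 3)
        return {"left": list(range(third)),
                "mid": list(range(third, n - third)),
                "right": list(range(n - third, n))}


def pink_noise(n_samples: int, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^exponent.

    White Gaussian noise is shaped in the frequency domain by
    ``f^(-exponent/2)`` (DC bin untouched) and renormalized.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samples)
    return x / x.std()


def _oscillation(band: tuple[float, float], n_samples: int, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS sinusoid at a random frequency in ``band``, random phase."""
    freq = rng.uniform(*band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_samples) / fs
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * freq * t + phase)


def generate_epoch(class_label: str, config: SynthConfig,
                   rng: np.random.Generator) -> EEGEpoch:
    """One labeled epoch: pink noise + (possibly attenuated) rhythms."""
    if class_label not in config.classes:
        raise ValueError(f"unknown class {class_label!r}")
    if class_label in CONTRALATERAL:
        erd_group = CONTRALATERAL[class_label]
    else:  # classes beyond hand MI alternate over lateral groups
        erd_group = ("left", "right")[list(config.classes).index(class_label) % 2]
    groups = config.channel_groups()
    n = config.n_samples
    # per-band amplitude so that total oscillation power matches snr_db
    # against unit-variance noise (two bands, equal split)
    osc_amp = np.sqrt(10.0 ** (config.snr_db / 10.0) / 2.0)
    if config.erd_onset_ramp:
        ramp = np.clip(np.arange(n) / (0.25 * config.fs), 0.0, 1.0)
    else:
        ramp = np.ones(n)
    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        noise = pink_noise(n, config.noise_exponent, rng)
        osc = osc_amp * (_oscillation(config.mu_band, n, config.fs, rng)
                         + _oscillation(config.beta_band, n, config.fs, rng))
        if ch in groups[erd_group]:
            atten = 1.0 - config.erd_depth * ramp
            osc = osc * atten
        data[ch] = noise + osc
    return EEGEpoch(data=data, fs=config.fs, label=class_label,
                    channel_names=list(config.channel_names))


def generate_dataset(config: SynthConfig, n_per_class: int,
                     shuffle: bool = False) -> list[EEGEpoch]:
    """Balanced labeled epoch list; bit-identical for identical seeds."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    epochs = [generate_epoch(cls, config, rng)
              for cls in config.classes for _ in range(n_per_class)]
    if shuffle:
        order = rng.permutation(len(epochs))
        epochs = [epochs[i] for i in order]
    return epochs


def write_dataset(config: SynthConfig, n_per_class: int,
                  out_dir: str | Path, shuffle: bool = False) -> Path:
    """Generate and persist a dataset; the manifest records the full
    generator configuration and seed for reproducibility."""
    epochs = generate_dataset(config, n_per_class, shuffle=shuffle)
    extra = {"generator": "mihawk.synth", "n_per_class": n_per_class,
             "shuffle": shuffle, "config": _jsonable(asdict(config))}
    return save_dataset(epochs, out_dir, manifest_extra=extra)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
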