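"""Synthetic motor-imagery EEG with planted band-limited structure.

Each trial is a 1/f (pink-ish) background plus white noise, with a
class-dependent narrowband source mixed into a configured electrode set.
Because the source is *shared* across the electrodes of the set, it
raises their pairwise waveform similarity — exactly the quantity the
Gaussian-kernel connectivity estimator measures — while also raising
band power.  Lateralized mu/beta effects over left vs. right central
electrodes therefore emulate the class structure of motor-imagery
recordings at the level the pipeline is sensitive to, without
pretending to model cortical physiology (no lead fields, no dipoles, no
artifacts).

Defaults follow the desk-scale study conditions: 8 sensorimotor
channels, fs = 128 Hz, 2 s trials (256 samples), 2 balanced classes,
class 0 loaded on left central electrodes and class 1 on the right, in
the mu and low-beta bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import Montage, TrialSet, load_montage, save_montage, save_trials

__all__ = [
    "EffectSpec",
    "SynthConfig",
    "default_montage8",
    "simulate_trials",
    "make_fixture_suite",
]

#: compact sensorimotor subset of the 10-10 system used by the fixtures
MONTAGE8_LABELS: tuple[str, ...] = ("F3", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")

LEFT_CENTRAL: tuple[str, ...] = ("F3", "C3", "P3")
RIGHT_CENTRAL: tuple[str, ...] = ("F4", "C4", "P4")


@dataclass(frozen=True)
class EffectSpec:
    """One planted class effect: a shared narrowband source on a set."""

    class_idx: int
    f_lo: float
    f_hi: float
    electrodes: tuple[str, ...]
    amplitude: float = 2.0     # per-electrode gain of the shared source
    coupling: float = 1.0      # fraction of the source shared (1 = identical)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator."""

    n_per_class: int = 100
    n_classes: int = 2
    n_channels: int = 8
    fs: float = 128.0
    duration: float = 2.0
    effects: tuple[EffectSpec, ...] = field(default_factory=tuple)
    one_over_f_exponent: float = 1.0
    noise_floor: float = 0.2   # white-noise std relative to 1/f background (std 1)
    seed: int = 0

    @staticmethod
    def binary_lateralized(
        n_per_class: int = 100, amplitude: float = 2.0, seed: int = 0
    ) -> "SynthConfig":
        """Binary task: mu + low-beta sources on left vs. right electrodes."""
        effects = (
            EffectSpec(0, 8.0, 12.0, LEFT_CENTRAL, amplitude),
            EffectSpec(0, 12.0, 15.0, LEFT_CENTRAL, amplitude),
            EffectSpec(1, 8.0, 12.0, RIGHT_CENTRAL, amplitude),
            EffectSpec(1, 12.0, 15.0, RIGHT_CENTRAL, amplitude),
        )
        return SynthConfig(n_per_class=n_per_class, effects=effects, seed=seed)

    @staticmethod
    def five_class(n_per_class: int = 40, amplitude: float = 2.0, seed: int = 0) -> "SynthConfig":
        """Five classes with distinct electrode-set / band signatures."""
        effects = (
            EffectSpec(0, 8.0, 12.0, LEFT_CENTRAL, amplitude),
            EffectSpec(1, 8.0, 12.0, RIGHT_CENTRAL, amplitude),
            EffectSpec(2, 12.0, 15.0, ("C3", "Cz", "C4"), amplitude),
            EffectSpec(3, 15.0, 20.0, ("P3", "Pz", "P4"), amplitude),
            # class 4: rest — background only
        )
        return SynthConfig(n_per_class=n_per_class, n_classes=5, effects=effects, seed=seed)


def default_montage8() -> Montage:
    """The 8-channel sensorimotor fixture montage."""
    return load_montage("standard_10_10_64").subset(list(MONTAGE8_LABELS))


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, tau: int, fs: float, exponent: float
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f^exponent, unit std."""
    freqs = np.fft.rfftfreq(tau, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spec, n=tau, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _narrowband_source(
    rng: np.random.Generator, tau: int, fs: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Random-phase narrowband signal (flat spectrum inside the band), unit std."""
    freqs = np.fft.rfftfreq(tau, d=1.0 / fs)
    keep = (freqs >= f_lo) & (freqs < f_hi)
    spec = np.zeros(freqs.size, dtype=complex)
    spec[keep] = rng.standard_normal(keep.sum()) + 1j * rng.standard_normal(keep.sum())
    x = np.fft.irfft(spec, n=tau)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_trials(cfg: SynthConfig, m: Montage | None = None) -> tuple[TrialSet, dict]:
    """Generate a balanced TrialSet plus a ground-truth descriptor.

    The descriptor records, per effect, the planted electrode indices,
    band and amplitude, so tests can verify recovery.
    """
    if m is None:
        m = default_montage8()
    if m.n_channels != cfg.n_channels:
        raise ValueError("montage size does not match configured channel count")
    nyq = cfg.fs / 2
    for eff in cfg.effects:
        if eff.f_hi > nyq:
            raise ValueError(f"effect band ({eff.f_lo}, {eff.f_hi}) above Nyquist {nyq}")
        if eff.amplitude < 0 or not 0 <= eff.coupling <= 1:
            raise ValueError("amplitude must be >= 0 and coupling in [0, 1]")
        if not set(eff.electrodes) <= set(m.labels):
            raise ValueError(f"effect electrodes {eff.electrodes} not all in montage")
    rng = np.random.default_rng(cfg.seed)
    tau = int(round(cfg.duration * cfg.fs))
    n = cfg.n_per_class * cfg.n_classes
    label_idx = np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)
    chan_index = {lab: i for i, lab in enumerate(m.labels)}

    trials = np.empty((n, cfg.n_channels, tau))
    for i, cls in enumerate(label_idx):
        x = _one_over_f_noise(rng, cfg.n_channels, tau, cfg.fs, cfg.one_over_f_exponent)
        x += cfg.noise_floor * rng.standard_normal((cfg.n_channels, tau))
        for eff in cfg.effects:
            if eff.class_idx != cls:
                continue
            shared = _narrowband_source(rng, tau, cfg.fs, eff.f_lo, eff.f_hi)
            for lab in eff.electrodes:
                own = _narrowband_source(rng, tau, cfg.fs, eff.f_lo, eff.f_hi)
                mix = eff.coupling * shared + (1.0 - eff.coupling) * own
                x[chan_index[lab]] += eff.amplitude * mix
        trials[i] = x

    labels = np.zeros((n, cfg.n_classes))
    labels[np.arange(n), label_idx] = 1.0
    ts = TrialSet(
        trials,
        labels,
        cfg.fs,
        list(m.labels),
        {"dataset": "synthetic", "seed": cfg.seed, "duration_s": cfg.duration},
    )
    truth = {
        "effects": [
            {
                "class_idx": e.class_idx,
                "band": (e.f_lo, e.f_hi),
                "electrodes": list(e.electrodes),
                "channel_indices": [chan_index[lab] for lab in e.electrodes],
                "amplitude": e.amplitude,
                "coupling": e.coupling,
            }
            for e in cfg.effects
        ],
        "label_indices": label_idx,
    }
    return ts, truth


def make_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write the canonical desk-scale fixtures used by tests and docs.

    Produces the 8-channel montage TSV, a 40-trial binary TrialSet and a
    5-class variant.  Regeneration under the same seed is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = default_montage8()
    paths = {
        "montage": out / "montage8.tsv",
        "binary": out / "trials_binary.h5",
        "five_class": out / "trials_5class.h5",
    }
    save_montage(m, paths["montage"])
    ts2, _ = simulate_trials(SynthConfig.binary_lateralized(n_per_class=20, seed=seed), m)
    save_trials(ts2, paths["binary"])
    ts5, _ = simulate_trials(SynthConfig.five_class(n_per_class=8, seed=seed), m)
    save_trials(ts5, paths["five_class"])
    return paths
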