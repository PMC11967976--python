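"""Synthetic two-class EEG-like cohorts with controlled entropy effects.

The generator emulates the structure of a two-class pediatric EEG study
(an ADHD group and a healthy-control group, multi-channel recordings at a
fixed sampling rate) without attempting physiological realism: channels
are amplitude-distribution processes, and the class difference is injected
into a chosen subset of "informative" channels as a manipulation of the
sample-value distribution. That is deliberate — the channel-selection
statistic under test is computed from the amplitude histogram, so the
injected effect is detectable by exactly that statistic and not by
accident of spectral structure.

The base process of every channel is a stationary Gaussian AR(1) with
lag-one coefficient ``ar_coeff`` (default 0.9) scaled to marginal
standard deviation ``base_noise_sd`` — scalp EEG sampled at 128 Hz is
strongly autocorrelated, and a temporally smooth base is also what makes
the injected effects visible to local-pattern descriptors: for i.i.d.
samples the rank pattern of any window is distribution-free, so no
purely marginal manipulation of white noise could ever register in an
order-based feature.

Effect kinds (applied to informative channels of the ADHD class):

``variance-scale``
    Signal amplitude multiplied by ``1 + effect_size``.
``uniform-vs-gaussian``
    Samples replaced by variance-matched i.i.d. uniform draws with
    probability ``effect_size / (1 + effect_size)``.
``bimodal-mixture``
    An equiprobable i.i.d. ±delta offset added per sample, with
    ``delta = effect_size * base_noise_sd / 2``.

All three are identity at ``effect_size = 0``. Each subject additionally
gets an independent noise realization and a random per-subject gain in
[0.9, 1.1], so subject-level validation splits are non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endeeg.eeg_io import STANDARD_1020_19, Recording
from endeeg.errors import ValidationError

EFFECT_KINDS = ("variance-scale", "uniform-vs-gaussian", "bimodal-mixture")


@dataclass
class SyntheticSpec:
    """Conditions for one simulated cohort.

    Defaults describe a desk-scale study: 20 subjects per class on the
    19-electrode 10-20 montage, 64 s at 128 Hz per subject (four
    non-overlapping 2048-sample windows per channel), three informative
    channels carrying a variance-scale effect of 4.
    """

    n_per_class: int = 20
    n_channels: int = 19
    fs: float = 128.0
    duration: float = 64.0
    informative_channels: frozenset[int] = field(default_factory=lambda: frozenset({0, 1, 2}))
    effect_kind: str = "variance-scale"
    effect_size: float = 4.0
    base_noise_sd: float = 1.0
    ar_coeff: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_channels = frozenset(int(i) for i in self.informative_channels)
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError("fs and duration must be positive")
        if self.effect_kind not in EFFECT_KINDS:
            raise ValidationError(f"effect_kind must be one of {EFFECT_KINDS}")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.base_noise_sd <= 0:
            raise ValidationError("base_noise_sd must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise ValidationError("ar_coeff must be in [0, 1)")
        bad = [i for i in self.informative_channels if not 0 <= i < self.n_channels]
        if bad:
            raise ValidationError(f"informative_channels out of range: {bad}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def channel_names(self) -> list[str]:
        if self.n_channels <= len(STANDARD_1020_19):
            return STANDARD_1020_19[: self.n_channels]
        return STANDARD_1020_19 + [f"X{i}" for i in range(len(STANDARD_1020_19), self.n_channels)]


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary Gaussian AR(1) with marginal standard deviation ``sd``."""
    from scipy.signal import lfilter

    innovations = rng.normal(0.0, 1.0, size=n) * (sd * np.sqrt(1.0 - phi**2))
    innovations[0] = rng.normal(0.0, sd)  # start in the stationary distribution
    return lfilter([1.0], [1.0, -phi], innovations)


def _channel_noise(rng: np.random.Generator, n: int, sd: float, spec: SyntheticSpec,
                   informative: bool, is_adhd: bool) -> np.ndarray:
    x = _ar1(rng, n, sd, spec.ar_coeff)
    if not (informative and is_adhd) or spec.effect_size == 0:
        return x
    if spec.effect_kind == "variance-scale":
        return x * (1.0 + spec.effect_size)
    if spec.effect_kind == "uniform-vs-gaussian":
        w = spec.effect_size / (1.0 + spec.effect_size)
        half_width = np.sqrt(3.0) * sd  # variance-matched uniform
        uni = rng.uniform(-half_width, half_width, size=n)
        mask = rng.random(n) < w
        return np.where(mask, uni, x)
    # bimodal-mixture
    delta = spec.effect_size * spec.base_noise_sd / 2.0
    signs = rng.choice([-1.0, 1.0], size=n)
    return x + signs * delta


def generate_cohort(spec: SyntheticSpec) -> list[Recording]:
    """Simulate ``2 * n_per_class`` labeled recordings.

    Subjects are interleaved (adhd, control, adhd, ...) so that a
    chronological split of the cohort list contains both classes on both
    sides. Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.channel_names
    recordings: list[Recording] = []
    for i in range(spec.n_per_class):
        for label in ("adhd", "control"):
            gain = rng.uniform(0.9, 1.1)
            data = np.empty((spec.n_channels, spec.n_samples))
            for ch in range(spec.n_channels):
                data[ch] = _channel_noise(
                    rng,
                    spec.n_samples,
                    spec.base_noise_sd,
                    spec,
                    informative=ch in spec.informative_channels,
                    is_adhd=label == "adhd",
                )
            data *= gain
            recordings.append(
                Recording(
                    subject_id=f"{label}_{i:03d}",
                    label=label,
                    fs=spec.fs,
                    channel_names=list(names),
                    data=data,
                )
            )
    return recordings


def make_segment(kind: str, length: int, params: dict | None = None, seed: int = 0) -> np.ndarray:
    """Deterministic single-channel test signals.

    kinds: ``constant`` (params: value), ``two-level`` (params: a, b;
    strict alternation, so an even length has exactly length/2 of each),
    ``tone`` (params: f, fs, amplitude, phase), ``gaussian``
    (params: mean, sd).
    """
    params = dict(params or {})
    if length < 1:
        raise ValidationError("length must be >= 1")
    if kind == "constant":
        return np.full(length, float(params.get("value", 1.0)))
    if kind == "two-level":
        a, b = float(params.get("a", 0.0)), float(params.get("b", 1.0))
        out = np.empty(length)
        out[0::2] = a
        out[1::2] = b
        return out
    if kind == "tone":
        f = float(params.get("f", 10.0))
        fs = float(params.get("fs", 128.0))
        amp = float(params.get("amplitude", 1.0))
        phase = float(params.get("phase", 0.0))
        t = np.arange(length) / fs
        return amp * np.sin(2 * np.pi * f * t + phase)
    if kind == "gaussian":
        rng = np.random.default_rng(seed)
        return rng.normal(float(params.get("mean", 0.0)), float(params.get("sd", 1.0)), size=length)
    raise ValidationError(f"unknown segment kind {kind!r}")


def write_cohort(recordings: list[Recording], out_dir) -> "pd.DataFrame":
    """Write a cohort as matrix-text files plus a manifest CSV.

    Returns the manifest (subject_id, label, path) with paths relative to
    ``out_dir``; the manifest itself is written to ``out_dir/manifest.csv``.
    """
    import os

    import pandas as pd

    from endeeg.eeg_io import write_recording

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        write_recording(rec, os.path.join(out_dir, fname))
        rows.append({"subject_id": rec.subject_id, "label": rec.label, "path": fname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
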