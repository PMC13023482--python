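"""Synthetic two-class multimodal datasets.

Generates labelled (audio, visual) feature-series pairs that emulate the
statistical shape of speech-derived mel-band log energies and facial
blendshape tracks, with a controllable arousal-like class contrast:

* class 1 ("high arousal") adds a per-band log-energy offset to the audio
  bands (by default concentrated in the upper half of the spectrum), and
* multiplies the amplitude of mouth-region blendshape envelopes.

Both modalities are sampled on the common 10 ms grid, so every downstream
stage (encoding, mapping, reservoir, classification, explainability) can be
exercised without any external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BLENDSHAPE_NAMES,
    BLENDSHAPES_JAW,
    BLENDSHAPES_MOUTH_LOWER,
    BLENDSHAPES_MOUTH_UPPER,
    DT,
    FeatureSeries,
)

#: blendshapes whose amplitude carries the class-1 contrast (mouth dynamics)
MOUTH_SHAPES = set(BLENDSHAPES_MOUTH_UPPER + BLENDSHAPES_MOUTH_LOWER + BLENDSHAPES_JAW)


def default_class_shift_audio(n_bands: int = 40, magnitude: float = 1.0) -> np.ndarray:
    """Default class-1 log-energy offset: +magnitude on the upper half bands.

    High-arousal speech carries relatively more high-frequency energy; the
    default shift adds ``magnitude`` (two noise standard deviations under
    the default noise level) to every band in the upper half of the mel
    axis and nothing below.
    """
    shift = np.zeros(n_bands)
    shift[n_bands // 2:] = magnitude
    return shift


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-class generator.

    Defaults give the study-scale feature geometry: 2 x 40 mel bands,
    2 x 52 blendshapes, 3.5 s at 10 ms, with a class contrast large enough
    for a mean-energy threshold to separate the classes.
    """

    n_samples_per_class: int = 20
    n_audio_bands: int = 40
    n_blendshapes: int = 52
    duration_steps: int = 350
    class_shift_audio: np.ndarray | None = None  # defaults to upper-band ramp
    class_shift_visual: float = 1.5
    ar_coefficient: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class <= 0:
            raise ValueError("n_samples_per_class must be positive")
        if self.n_audio_bands <= 0 or self.n_blendshapes <= 0:
            raise ValueError("feature counts must be positive")
        if self.duration_steps <= 0:
            raise ValueError("duration_steps must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.class_shift_audio is None:
            self.class_shift_audio = default_class_shift_audio(
                self.n_audio_bands, magnitude=2.0 * self.noise_sd
            )
        self.class_shift_audio = np.asarray(self.class_shift_audio, dtype=float)
        if self.class_shift_audio.shape != (self.n_audio_bands,):
            raise ValueError("class_shift_audio must have one entry per band")


def _baseline_profile(n_bands: int) -> np.ndarray:
    """Smooth 1/f-like log-energy decay over mel bands (speech-shaped)."""
    b = np.arange(n_bands)
    return 2.0 - 3.0 * np.log1p(b) / np.log1p(n_bands - 1)


def _ar1(rng: np.random.Generator, shape, rho: float, sd: float) -> np.ndarray:
    """AR(1) noise with stationary standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    x = np.empty(shape)
    x[..., 0] = rng.normal(0.0, sd, shape[:-1])
    eps = rng.normal(0.0, innov_sd, shape)
    for t in range(1, shape[-1]):
        x[..., t] = rho * x[..., t - 1] + eps[..., t]
    return x


def _smooth_envelope(rng: np.random.Generator, n_steps: int) -> np.ndarray:
    """Slow utterance-like modulation in [0, 1]: sum of random smooth bumps."""
    t = np.arange(n_steps)
    env = np.zeros(n_steps)
    for _ in range(rng.integers(2, 6)):
        centre = rng.uniform(0, n_steps)
        width = rng.uniform(n_steps / 12, n_steps / 4)
        env += rng.uniform(0.3, 1.0) * np.exp(-0.5 * ((t - centre) / width) ** 2)
    peak = env.max()
    return env / peak if peak > 0 else env


def _audio_sample(rng: np.random.Generator, spec: SyntheticSpec, label: int) -> FeatureSeries:
    n, T = spec.n_audio_bands, spec.duration_steps
    base = _baseline_profile(n) + label * spec.class_shift_audio
    env = _smooth_envelope(rng, T)
    gains = rng.uniform(0.5, 1.5, n)
    common = base[:, None] + gains[:, None] * env[None, :] + _ar1(
        rng, (n, T), spec.ar_coefficient, spec.noise_sd
    )
    # left/right = common signal + small independent channel noise
    lr_noise_sd = 0.05 * max(spec.noise_sd, 0.1)
    left = common + rng.normal(0.0, lr_noise_sd, (n, T))
    right = common + rng.normal(0.0, lr_noise_sd, (n, T))
    labels = [f"mel_{b}_L" for b in range(n)] + [f"mel_{b}_R" for b in range(n)]
    tags = ["L"] * n + ["R"] * n
    return FeatureSeries(np.vstack([left, right]), labels, "audio", tags, DT)


def _visual_sample(rng: np.random.Generator, spec: SyntheticSpec, label: int) -> FeatureSeries:
    names = list(BLENDSHAPE_NAMES[: spec.n_blendshapes])
    T = spec.duration_steps
    vals = np.zeros((spec.n_blendshapes, T))
    for i, name in enumerate(names):
        env = np.zeros(T)
        t = np.arange(T)
        for _ in range(rng.integers(2, 6)):
            centre = rng.uniform(0, T)
            width = rng.uniform(T / 20, T / 6)
            env += rng.uniform(0.1, 0.6) * np.exp(-0.5 * ((t - centre) / width) ** 2)
        if label == 1 and name in MOUTH_SHAPES:
            env *= spec.class_shift_visual
        env += _ar1(rng, (T,), spec.ar_coefficient, 0.1 * spec.noise_sd)
        vals[i] = np.clip(env, 0.0, 1.0)
    # bilateral duplication: identical L and R copies
    full = np.vstack([vals, vals])
    labels = [f"{n}_L" for n in names] + [f"{n}_R" for n in names]
    tags = ["L"] * len(names) + ["R"] * len(names)
    return FeatureSeries(full, labels, "visual", tags, DT)


def generate_dataset(
    spec: SyntheticSpec,
) -> list[tuple[FeatureSeries, FeatureSeries, int]]:
    """Generate a balanced labelled dataset of (audio, visual, label) triples.

    Samples are interleaved class 0, 1, 0, 1, ... and the whole dataset is a
    deterministic function of ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_samples_per_class):
        for label in (0, 1):
            audio = _audio_sample(rng, spec, label)
            visual = _visual_sample(rng, spec, label)
            out.append((audio, visual, label))
    return out


def write_dataset(dataset, out_dir) -> Path:
    """Write one CSV per sample per modality plus a manifest CSV.

    The per-sample CSVs have one row per 10 ms frame and one named column per
    feature — the same layout the real-data readers consume.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (audio, visual, label) in enumerate(dataset):
        a_path = out_dir / f"sample{i:04d}_audio.csv"
        v_path = out_dir / f"sample{i:04d}_visual.csv"
        audio.to_csv(a_path)
        visual.to_csv(v_path)
        rows.append(
            {"sample_id": i, "label": label, "audio": a_path.name, "visual": v_path.name}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path):
    """Read a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    n_half = None
    out = []
    for _, row in df.iterrows():
        audio = FeatureSeries.from_csv(base / row["audio"], modality="audio")
        if n_half is None:
            n_half = audio.n_features // 2
        audio.channel_tags = ["L"] * n_half + ["R"] * (audio.n_features - n_half)
        visual = FeatureSeries.from_csv(base / row["visual"], modality="visual")
        v_half = visual.n_features // 2
        visual.channel_tags = ["L"] * v_half + ["R"] * (visual.n_features - v_half)
        out.append((audio, visual, int(row["label"])))
    return out
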