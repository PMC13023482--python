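"""Core data containers shared across the pipeline.

The whole pipeline moves two kinds of matrices around:

* :class:`FeatureSeries` — a real-valued ``[features x timesteps]`` matrix of
  feature activations sampled every 10 ms (mel-band log energies, facial
  blendshape coefficients, or both stacked).
* :class:`SpikeRaster` — an integer spike matrix on the same time grid.
  Input rasters are ternary (-1/0/+1, the signed events of Step-Forward
  encoding); reservoir rasters are binary (0/1 firing indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: default frame period in seconds — the modalities are synchronised at 10 ms
DT = 0.01

# ---------------------------------------------------------------------------
# Canonical facial blendshape schema
# ---------------------------------------------------------------------------
# The standard 52-coefficient ARKit blendshape set, reordered into a fixed
# canonical face-region order (brow, eye, cheek, nose, jaw, mouth, tongue).
# Each coefficient is a [0, 1] activation of one facial movement component.
BLENDSHAPES_BROW = (
    "browDownLeft", "browDownRight", "browInnerUp",
    "browOuterUpLeft", "browOuterUpRight",
)
BLENDSHAPES_EYE = (
    "eyeBlinkLeft", "eyeBlinkRight",
    "eyeLookDownLeft", "eyeLookDownRight",
    "eyeLookInLeft", "eyeLookInRight",
    "eyeLookOutLeft", "eyeLookOutRight",
    "eyeLookUpLeft", "eyeLookUpRight",
    "eyeSquintLeft", "eyeSquintRight",
    "eyeWideLeft", "eyeWideRight",
)
BLENDSHAPES_CHEEK = ("cheekPuff", "cheekSquintLeft", "cheekSquintRight")
BLENDSHAPES_NOSE = ("noseSneerLeft", "noseSneerRight")
BLENDSHAPES_JAW = ("jawForward", "jawLeft", "jawOpen", "jawRight")
BLENDSHAPES_MOUTH_UPPER = (
    "mouthDimpleLeft", "mouthDimpleRight",
    "mouthFunnel", "mouthLeft", "mouthPucker", "mouthRight",
    "mouthRollUpper", "mouthShrugUpper",
    "mouthSmileLeft", "mouthSmileRight",
    "mouthUpperUpLeft", "mouthUpperUpRight",
)
BLENDSHAPES_MOUTH_LOWER = (
    "mouthClose",
    "mouthFrownLeft", "mouthFrownRight",
    "mouthLowerDownLeft", "mouthLowerDownRight",
    "mouthPressLeft", "mouthPressRight",
    "mouthRollLower", "mouthShrugLower",
    "mouthStretchLeft", "mouthStretchRight",
)
BLENDSHAPES_TONGUE = ("tongueOut",)

#: canonical order: brow, eye, cheek, nose, jaw, mouth, tongueOut (52 names)
BLENDSHAPE_NAMES = (
    BLENDSHAPES_BROW + BLENDSHAPES_EYE + BLENDSHAPES_CHEEK + BLENDSHAPES_NOSE
    + BLENDSHAPES_JAW + BLENDSHAPES_MOUTH_UPPER + BLENDSHAPES_MOUTH_LOWER
    + BLENDSHAPES_TONGUE
)
assert len(BLENDSHAPE_NAMES) == 52

#: face-region group of every blendshape (used by the explainability module)
BLENDSHAPE_FACE_GROUP = {}
for _n in BLENDSHAPES_BROW:
    BLENDSHAPE_FACE_GROUP[_n] = "brow"
for _n in BLENDSHAPES_EYE:
    BLENDSHAPE_FACE_GROUP[_n] = "eye"
for _n in BLENDSHAPES_CHEEK + BLENDSHAPES_NOSE:
    BLENDSHAPE_FACE_GROUP[_n] = "cheek/nose"
for _n in BLENDSHAPES_JAW:
    BLENDSHAPE_FACE_GROUP[_n] = "jaw"
for _n in BLENDSHAPES_MOUTH_UPPER:
    BLENDSHAPE_FACE_GROUP[_n] = "upper-mouth"
for _n in BLENDSHAPES_MOUTH_LOWER + BLENDSHAPES_TONGUE:
    BLENDSHAPE_FACE_GROUP[_n] = "lower-mouth"

#: dorsoventral height class per face region; lower rank = higher on the face,
#: mapped more dorsally (higher Z) in the superior temporal sulcus
FACE_HEIGHT_ORDER = ("brow", "eye", "nose", "cheek", "mouth", "jaw/tongue")


def blendshape_height_class(name: str) -> int:
    """Rank of a blendshape's facial height class (0 = most dorsal target)."""
    if name in BLENDSHAPES_BROW:
        return 0
    if name in BLENDSHAPES_EYE:
        return 1
    if name in BLENDSHAPES_NOSE:
        return 2
    if name in BLENDSHAPES_CHEEK:
        return 3
    if name in BLENDSHAPES_MOUTH_UPPER + BLENDSHAPES_MOUTH_LOWER:
        return 4
    if name in BLENDSHAPES_JAW + BLENDSHAPES_TONGUE:
        return 5
    raise KeyError(f"unknown blendshape: {name!r}")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureSeries:
    """Real feature-activation matrix ``values[feature, timestep]``.

    Parameters
    ----------
    values
        Matrix of shape ``(n_features, n_timesteps)``.
    feature_labels
        One name per row (e.g. ``"mel_12_L"`` or ``"jawOpen_R"``).
    modality
        ``"audio"``, ``"visual"`` or ``"multimodal"``.
    channel_tags
        ``"L"``/``"R"`` hemifield tag per row.
    dt
        Frame period in seconds (10 ms throughout).
    """

    values: np.ndarray
    feature_labels: list[str]
    modality: str
    channel_tags: list[str] | None = None
    dt: float = DT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D [features x timesteps] matrix")
        if len(self.feature_labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.feature_labels)} labels for {self.values.shape[0]} rows"
            )
        if self.channel_tags is not None and len(self.channel_tags) != self.values.shape[0]:
            raise ValueError("channel_tags length must match feature rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureSeries":
        return replace(
            self,
            values=self.values.copy(),
            feature_labels=list(self.feature_labels),
            channel_tags=None if self.channel_tags is None else list(self.channel_tags),
        )

    # -- CSV interchange: one row per 10 ms frame, one column per feature ---
    def to_csv(self, path) -> None:
        pd.DataFrame(self.values.T, columns=self.feature_labels).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, modality: str, channel_tags=None, dt: float = DT) -> "FeatureSeries":
        df = pd.read_csv(path)
        return cls(
            values=df.to_numpy(dtype=float).T,
            feature_labels=list(df.columns),
            modality=modality,
            channel_tags=channel_tags,
            dt=dt,
        )


@dataclass
class SpikeRaster:
    """Integer spike matrix ``spikes[channel, timestep]``.

    ``kind == "ternary"`` rasters hold signed input events in {-1, 0, +1};
    ``kind == "binary"`` rasters hold reservoir firing indicators in {0, 1}.
    At most one event per channel per timestep by construction.
    """

    spikes: np.ndarray
    kind: str  # "ternary" | "binary"
    channel_labels: list[str] | None = None
    dt: float = DT

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be 2-D [channels x timesteps]")
        allowed = {-1, 0, 1} if self.kind == "ternary" else {0, 1}
        present = set(np.unique(self.spikes).tolist())
        if not present <= allowed:
            raise ValueError(f"{self.kind} raster holds values outside {sorted(allowed)}")
        self.spikes = self.spikes.astype(np.int8)

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.spikes.shape[1]

    def events(self) -> np.ndarray:
        """Unsigned event indicator |spikes| (counts ternary events as 1)."""
        return np.abs(self.spikes).astype(np.int64)

    def to_csv(self, path) -> None:
        labels = self.channel_labels or [f"ch{i}" for i in range(self.n_channels)]
        pd.DataFrame(self.spikes.T, columns=labels).to_csv(path, index=False)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            spikes=self.spikes,
            kind=np.array(self.kind),
            dt=np.array(self.dt),
            channel_labels=np.array(self.channel_labels or [], dtype=object),
        )

    @classmethod
    def load_npz(cls, path) -> "SpikeRaster":
        with np.load(path, allow_pickle=True) as z:
            labels = list(z["channel_labels"]) or None
            return cls(
                spikes=z["spikes"],
                kind=str(z["kind"]),
                channel_labels=labels,
                dt=float(z["dt"]),
            )
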