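"""Step-Forward spike encoding and decoding.

Each feature channel keeps a running baseline B. At every frame, if the
signal exceeds B + theta a positive spike is emitted and B steps up by
theta; if it falls below B - theta a negative spike is emitted and B steps
down; otherwise no spike. Decoding is the cumulative sum of theta-weighted
spikes from the stored initial baseline, so for signals whose per-step
change never exceeds theta the reconstruction tracks the original within
theta at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureSeries, SpikeRaster


@dataclass
class SFConfig:
    """Step-Forward encoder configuration.

    theta_rule ``"fixed"`` uses ``theta`` as given (scalar or per-feature
    vector); ``"k_times_sd"`` sets theta per feature to ``k`` times that
    feature's standard deviation computed over a reference (training) set.
    """

    theta: float | np.ndarray | None = None
    theta_rule: str = "k_times_sd"
    k: float = 0.5
    baseline_init: str = "first-sample"  # or "zero"

    def __post_init__(self) -> None:
        if self.theta_rule not in ("fixed", "k_times_sd"):
            raise ValueError("theta_rule must be 'fixed' or 'k_times_sd'")
        if self.baseline_init not in ("first-sample", "zero"):
            raise ValueError("baseline_init must be 'first-sample' or 'zero'")
        if self.theta_rule == "fixed" and self.theta is None:
            raise ValueError("fixed theta_rule requires theta")


def thetas_from_sd(reference_values: np.ndarray, k: float = 0.5,
                   floor: float = 1e-6) -> np.ndarray:
    """Per-feature theta = k * feature standard deviation (floored)."""
    sd = np.asarray(reference_values).std(axis=-1)
    return np.maximum(k * sd, floor)


def _resolve_theta(series: FeatureSeries, cfg: SFConfig) -> np.ndarray:
    if cfg.theta_rule == "fixed":
        theta = np.broadcast_to(np.asarray(cfg.theta, dtype=float),
                                (series.n_features,)).copy()
    else:
        theta = (np.broadcast_to(np.asarray(cfg.theta, dtype=float),
                                 (series.n_features,)).copy()
                 if cfg.theta is not None
                 else thetas_from_sd(series.values, cfg.k))
    if np.any(theta <= 0):
        raise ValueError("theta must be strictly positive for every feature")
    return theta


def sf_encode(series: FeatureSeries, cfg: SFConfig | None = None
              ) -> tuple[SpikeRaster, np.ndarray, np.ndarray]:
    """Encode a feature series into a ternary raster.

    Returns ``(raster, baselines, thetas)`` where ``baselines`` are the
    initial per-feature baselines needed by :func:`sf_decode`. One signed
    spike at most per channel per step, even when the deviation exceeds
    2 theta (canonical Step-Forward behaviour).
    """
    cfg = cfg or SFConfig()
    x = series.values
    if not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    theta = _resolve_theta(series, cfg)
    n, T = x.shape
    base0 = x[:, 0].copy() if cfg.baseline_init == "first-sample" else np.zeros(n)
    B = base0.copy()
    spikes = np.zeros((n, T), dtype=np.int8)
    for t in range(T):
        up = x[:, t] > B + theta
        down = x[:, t] < B - theta
        spikes[up, t] = 1
        spikes[down, t] = -1
        B = B + theta * spikes[:, t]
    raster = SpikeRaster(spikes, "ternary", list(series.feature_labels), series.dt)
    return raster, base0, theta


def sf_decode(raster: SpikeRaster, baselines: np.ndarray,
              thetas: float | np.ndarray, modality: str = "audio") -> FeatureSeries:
    """Reconstruct a series as baseline + cumulative sum of theta * spikes."""
    theta = np.broadcast_to(np.asarray(thetas, dtype=float), (raster.n_channels,))
    baselines = np.asarray(baselines, dtype=float)
    if baselines.shape != (raster.n_channels,):
        raise ValueError(
            f"baselines shape {baselines.shape} does not match "
            f"{raster.n_channels} raster channels"
        )
    steps = theta[:, None] * raster.spikes.astype(float)
    values = baselines[:, None] + np.cumsum(steps, axis=1)
    labels = raster.channel_labels or [f"ch{i}" for i in range(raster.n_channels)]
    return FeatureSeries(values, list(labels), modality, None, raster.dt)


def reconstruction_nmse(original: FeatureSeries | np.ndarray,
                        reconstructed: FeatureSeries | np.ndarray) -> float:
    """Mean over features of MSE / variance(original); 0/0 taken as 0.

    Quantifies encode-then-decode fidelity on the scale of each feature's
    own variability.
    """
    x = original.values if isinstance(original, FeatureSeries) else np.asarray(original, float)
    y = (reconstructed.values if isinstance(reconstructed, FeatureSeries)
         else np.asarray(reconstructed, float))
    if x.shape != y.shape:
        raise ValueError("shape mismatch between original and reconstruction")
    mse = np.mean((x - y) ** 2, axis=-1)
    var = np.var(x, axis=-1)
    ratio = np.where(mse == 0, 0.0, mse / np.where(var > 0, var, np.inf))
    # constant original with a non-identical reconstruction: infinite penalty
    ratio = np.where((var == 0) & (mse > 0), np.inf, ratio)
    return float(np.mean(ratio))
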