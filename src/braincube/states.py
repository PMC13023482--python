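"""Per-sample state vectors extracted from spike rasters.

Three extraction rules:

* ``spike_count`` — total events per neuron over the sample (ternary input
  events count by magnitude).
* ``split_count`` — separate positive and negative event counts per input
  channel, doubling the dimensionality.
* ``desnn`` — the rank-order/drift scalar
  ``w_i = alpha * m**t_first + d_up * n_total - d_down * (T - n_total)``
  combining first-spike latency with total activity; a silent neuron
  contributes ``-d_down * T``.

Scopes restrict which neurons enter the vector: input channels (I), all
reservoir neurons (R), both (I+R), or the A1/STS region subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeRaster
from .template import CubeModel, InputMapping

SCOPES = ("I", "R", "I_plus_R", "A1", "STS")


@dataclass
class DeSNNParams:
    """Rank-order and drift constants of the DeSNN state-vector rule."""

    alpha: float = 5.0
    mod: float = 0.8
    drift_up: float = 0.8
    drift_down: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.mod < 1.0:
            raise ValueError("mod must lie in (0, 1)")


@dataclass
class StateVector:
    """One real value per in-scope neuron (doubled for split counts)."""

    values: np.ndarray
    neuron_ids: list[str]
    method: str  # spike_count | split_count | desnn
    scope: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.neuron_ids) != len(self.values):
            raise ValueError("one id per value required")


def spike_count(raster: SpikeRaster, scope_idx: np.ndarray | None = None,
                scope: str = "R") -> StateVector:
    """Total event count per channel: s_i = sum_t |x_it|."""
    idx = (np.arange(raster.n_channels) if scope_idx is None
           else np.asarray(scope_idx, dtype=int))
    if len(idx) == 0:
        raise ValueError("empty scope")
    counts = raster.events()[idx].sum(axis=1)
    ids = ([raster.channel_labels[i] for i in idx] if raster.channel_labels
           else [f"n{i}" for i in idx])
    return StateVector(counts.astype(float), ids, "spike_count", scope)


def split_count(raster: SpikeRaster) -> StateVector:
    """Positive counts for all channels, then negative counts.

    On a binary raster the negative half is all zeros (allowed; the split
    is only informative for ternary input rasters).
    """
    s = raster.spikes
    pos = (s > 0).sum(axis=1).astype(float)
    neg = (s < 0).sum(axis=1).astype(float)
    labels = raster.channel_labels or [f"ch{i}" for i in range(raster.n_channels)]
    ids = [f"{l}+" for l in labels] + [f"{l}-" for l in labels]
    return StateVector(np.concatenate([pos, neg]), ids, "split_count", "I")


def desnn_vector(raster: SpikeRaster, params: DeSNNParams | None = None,
                 scope_idx: np.ndarray | None = None, scope: str = "R") -> StateVector:
    """DeSNN scalar per neuron from first-spike time and total count."""
    params = params or DeSNNParams()
    if raster.n_timesteps < 1:
        raise ValueError("raster must have at least one timestep")
    idx = (np.arange(raster.n_channels) if scope_idx is None
           else np.asarray(scope_idx, dtype=int))
    ev = raster.events()[idx]
    T = raster.n_timesteps
    n_total = ev.sum(axis=1).astype(float)
    any_spike = n_total > 0
    t_first = np.where(any_spike, np.argmax(ev > 0, axis=1), 0).astype(float)
    rank_term = np.where(any_spike, params.alpha * params.mod ** t_first, 0.0)
    omega = rank_term + params.drift_up * n_total - params.drift_down * (T - n_total)
    ids = ([raster.channel_labels[i] for i in idx] if raster.channel_labels
           else [f"n{i}" for i in idx])
    return StateVector(omega, ids, "desnn", scope)


def scope_mask(cube: CubeModel, scope: str,
               mapping: InputMapping | None = None) -> np.ndarray:
    """Neuron (or input-channel) indices belonging to a scope.

    ``I`` returns input-channel indices (positions in the input raster);
    the others return reservoir neuron indices.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; choose from {SCOPES}")
    if scope == "I":
        if mapping is None:
            raise ValueError("scope 'I' requires the input mapping")
        return np.arange(mapping.n_features)
    if scope == "R":
        return np.arange(cube.n_neurons)
    if scope == "A1":
        return cube.template.region_indices("A1_L", "A1_R")
    if scope == "STS":
        return cube.template.region_indices("STS_L", "STS_R")
    # I_plus_R handled by extract_state via concatenation
    return np.arange(cube.n_neurons)


def extract_state(input_raster: SpikeRaster, reservoir_raster: SpikeRaster,
                  cube: CubeModel, mapping: InputMapping, method: str = "spike_count",
                  scope: str = "I_plus_R",
                  desnn_params: DeSNNParams | None = None) -> StateVector:
    """Extract one state vector from a sample's input + reservoir rasters.

    ``split_count`` applies to the input channels (optionally concatenated
    with reservoir counts under I_plus_R); the other methods apply to
    whichever raster the scope selects.
    """
    if method not in ("spike_count", "split_count", "desnn"):
        raise ValueError(f"unknown method {method!r}")

    def on_input():
        if method == "split_count":
            return split_count(input_raster)
        if method == "desnn":
            return desnn_vector(input_raster, desnn_params, scope="I")
        return spike_count(input_raster, scope="I")

    def on_reservoir(idx, scope_name):
        if method == "desnn":
            return desnn_vector(reservoir_raster, desnn_params, idx, scope_name)
        return spike_count(reservoir_raster, idx, scope_name)

    if scope == "I":
        return on_input()
    if scope in ("R", "A1", "STS"):
        idx = scope_mask(cube, scope, mapping)
        return on_reservoir(idx, scope)
    if scope == "I_plus_R":
        a = on_input()
        b = on_reservoir(np.arange(cube.n_neurons), "R")
        return StateVector(
            np.concatenate([a.values, b.values]),
            list(a.neuron_ids) + [f"res_{i}" for i in range(cube.n_neurons)],
            method, "I_plus_R",
        )
    raise ValueError(f"unknown scope {scope!r}")


def states_to_frame(states: list[StateVector], labels=None) -> pd.DataFrame:
    """Tabulate state vectors (rows = samples); interchange CSV format."""
    mat = np.vstack([s.values for s in states])
    df = pd.DataFrame(mat, columns=states[0].neuron_ids)
    if labels is not None:
        df["label"] = list(labels)
    return df
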