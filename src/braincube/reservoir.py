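"""Leaky integrate-and-fire reservoir dynamics with STDP learning.

Each timestep: mapped input spikes inject ``input_gain * spike`` (signed —
negative input events inject negative current) into their assigned neurons;
membrane potentials leak, integrate synaptic current from the previous
step's reservoir spikes (one-step synaptic delay), and neurons at or above
threshold fire, reset, and enter a refractory period.

In train mode, every firing event triggers nearest-neighbour
spike-timing-dependent plasticity on its afferent and efferent connections:
a pre-synaptic spike preceding the post-synaptic one potentiates the link by
``A_plus * exp((t_pre - t_post)/tau_plus)`` (LTP), a pre after post
depresses it by ``A_minus * exp((t_post - t_pre)/tau_minus)`` (LTD);
coincident spikes take the potentiation limit ``+A_plus``. Updates change
magnitudes only: the sparsity pattern is frozen and weights are clipped to
the sign class of the pre-synaptic neuron, within [-w_max, w_max]. Recall
mode never touches weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import SpikeRaster
from .template import CubeModel, InputMapping


@dataclass
class LIFConfig:
    """Leaky integrate-and-fire constants (per 10 ms step)."""

    threshold: float = 0.5
    leak_decay: float = 0.9
    refractory_steps: int = 1
    input_gain: float = 0.6
    reset_potential: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.leak_decay <= 1.0:
            raise ValueError("leak_decay must lie in (0, 1]")
        if self.threshold <= self.reset_potential:
            raise ValueError("threshold must exceed reset_potential")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")


@dataclass
class STDPParams:
    """Exponential STDP window parameters (times in steps)."""

    A_plus: float = 0.01
    A_minus: float = 0.01
    tau_plus: float = 2.0
    tau_minus: float = 2.0
    w_max: float = 1.0
    pairing: str = "nearest-neighbour"

    def __post_init__(self) -> None:
        for name in ("A_plus", "A_minus", "tau_plus", "tau_minus", "w_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReservoirActivity:
    """Binary reservoir raster plus (train mode) the final weights."""

    raster: SpikeRaster
    final_weights: sp.csr_matrix | None = None


def stdp_delta(t_pre: float, t_post: float, params: STDPParams) -> float:
    """Weight change for one pre/post spike pair.

    Potentiation ``A_plus * exp((t_pre - t_post)/tau_plus)`` when the pre
    spike leads, depression ``-A_minus * exp((t_post - t_pre)/tau_minus)``
    when it lags; the coincident case takes the potentiation limit +A_plus.
    """
    if not (np.isfinite(t_pre) and np.isfinite(t_post)):
        raise ValueError("spike times must be finite")
    if t_pre < t_post:
        return params.A_plus * float(np.exp((t_pre - t_post) / params.tau_plus))
    if t_pre > t_post:
        return -params.A_minus * float(np.exp((t_post - t_pre) / params.tau_minus))
    return params.A_plus


def _multi_range(indptr: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(indptr[r], indptr[r+1])`` for every row in rows."""
    starts = indptr[rows]
    counts = indptr[rows + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts[:-1])])
    return (np.arange(total, dtype=np.int64)
            - np.repeat(offsets, counts) + np.repeat(starts, counts))


class _EdgeIndex:
    """Fixed-sparsity adjacency views used for fast per-event STDP.

    ``incoming`` is CSR over post-neurons (row j = afferents of j) and owns
    the mutable weight data; ``out_*`` index that same data array by
    pre-neuron for efferent updates.
    """

    def __init__(self, weights: sp.csr_matrix):
        n = weights.shape[0]
        self.incoming = weights.T.tocsr().astype(float)
        self.incoming.sort_indices()
        pre = self.incoming.indices  # pre neuron of each stored edge
        order = np.argsort(pre, kind="stable")
        self.out_dataidx = order
        counts = np.bincount(pre, minlength=n)
        self.out_indptr = np.concatenate([[0], np.cumsum(counts)])
        # post neuron of each stored edge, in incoming-data order
        post = np.repeat(np.arange(n), np.diff(self.incoming.indptr))
        self.out_post = post[order]

    def afferent(self, j: int):
        lo, hi = self.incoming.indptr[j], self.incoming.indptr[j + 1]
        return slice(lo, hi), self.incoming.indices[lo:hi]

    def efferent(self, i: int):
        lo, hi = self.out_indptr[i], self.out_indptr[i + 1]
        return self.out_dataidx[lo:hi], self.out_post[lo:hi]

    def to_weights(self) -> sp.csr_matrix:
        return self.incoming.T.tocsr()


def simulate(cube: CubeModel, input_raster: SpikeRaster, mapping: InputMapping,
             mode: str = "recall", lif: LIFConfig | None = None,
             stdp: STDPParams | None = None, seed: int = 0,
             initial_potentials: np.ndarray | None = None) -> ReservoirActivity:
    """Run the cube over one input raster; returns the reservoir raster.

    ``mode="train"`` applies STDP after each firing event and returns the
    updated weights (also written back into ``cube.weights``);
    ``mode="recall"`` is a frozen-weight forward pass.
    """
    if mode not in ("train", "recall"):
        raise ValueError("mode must be 'train' or 'recall'")
    lif = lif or LIFConfig()
    stdp = stdp or STDPParams()
    n = cube.n_neurons
    T = input_raster.n_timesteps
    if mapping.n_features != input_raster.n_channels:
        raise ValueError(
            f"mapping covers {mapping.n_features} features but raster has "
            f"{input_raster.n_channels} channels"
        )
    edges = _EdgeIndex(cube.weights)
    data = edges.incoming.data
    sign = cube.neuron_sign
    lo_clip = np.where(sign[edges.incoming.indices] > 0, 0.0, -stdp.w_max)
    hi_clip = np.where(sign[edges.incoming.indices] > 0, stdp.w_max, 0.0)

    v = (np.full(n, lif.reset_potential, dtype=float)
         if initial_potentials is None else initial_potentials.astype(float).copy())
    refractory = np.zeros(n, dtype=np.int64)
    last_spike = np.full(n, -(10**9), dtype=np.int64)  # sentinel: never fired
    spikes_prev = np.zeros(n, dtype=float)
    out = np.zeros((n, T), dtype=np.int8)
    in_spikes = input_raster.spikes.astype(float)
    assign = mapping.assignments

    for t in range(T):
        current = edges.incoming.dot(spikes_prev)
        np.add.at(current, assign, lif.input_gain * in_spikes[:, t])
        v = lif.leak_decay * v + current
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise FloatingPointError(
                f"non-finite membrane potential at step {t} (neuron {bad})"
            )
        blocked = refractory > 0
        v[blocked] = lif.reset_potential
        fired = (v >= lif.threshold) & ~blocked
        fired_idx = np.flatnonzero(fired)
        out[fired_idx, t] = 1
        v[fired_idx] = lif.reset_potential
        refractory[blocked] -= 1
        refractory[fired_idx] = lif.refractory_steps

        if mode == "train" and len(fired_idx):
            # LTP: afferent edges of every fired neuron whose pre neuron
            # spiked at or before t (co-firing pre takes the +A_plus limit)
            pos = _multi_range(edges.incoming.indptr, fired_idx)
            pre = edges.incoming.indices[pos]
            tp = np.where(fired[pre], t, last_spike[pre])
            active = tp > -(10**8)
            if np.any(active):
                delta = stdp.A_plus * np.exp((tp[active] - t) / stdp.tau_plus)
                ap = pos[active]
                data[ap] = np.clip(data[ap] + delta, lo_clip[ap], hi_clip[ap])
            # LTD: efferent edges of every fired neuron whose post neuron
            # last spiked strictly before t
            pos = _multi_range(edges.out_indptr, fired_idx)
            didx = edges.out_dataidx[pos]
            post = edges.out_post[pos]
            tq = last_spike[post]
            active = (tq > -(10**8)) & (tq < t) & ~fired[post]
            if np.any(active):
                delta = -stdp.A_minus * np.exp((tq[active] - t) / stdp.tau_minus)
                ap = didx[active]
                data[ap] = np.clip(data[ap] + delta, lo_clip[ap], hi_clip[ap])
        last_spike[fired_idx] = t
        spikes_prev = out[:, t].astype(float)

    raster = SpikeRaster(out, "binary", dt=input_raster.dt)
    final = None
    if mode == "train":
        final = edges.to_weights()
        cube.weights = final
    return ReservoirActivity(raster=raster, final_weights=final)


def train_cube(cube: CubeModel, input_rasters, mapping: InputMapping,
               lif: LIFConfig | None = None, stdp: STDPParams | None = None,
               passes: int = 1, seed: int = 0) -> CubeModel:
    """Incremental unsupervised training: one STDP run per sample in order.

    Weights carry forward from sample to sample (and pass to pass), so the
    final cube depends on sample order — an inherent property of incremental
    learning.
    """
    rasters = list(input_rasters)
    if not rasters:
        raise ValueError("empty training dataset")
    for _ in range(passes):
        for r in rasters:
            simulate(cube, r, mapping, mode="train", lif=lif, stdp=stdp, seed=seed)
    return cube
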