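"""Lag-1 spike-time feature interactions and Feature Interaction Networks.

``association_matrix`` counts, per ordered channel pair (i, j), how often a
spike event on channel i is followed one 10 ms step later by an event on
channel j, aggregated over all samples of a class. Aggregating the
feature-level counts over named groups — six anatomical face regions plus
ten contiguous mel frequency groups, with left and right copies of a
feature sharing a group — yields a Feature Interaction Network whose edge
weights conserve the underlying count mass exactly. Comparing per-class
normalised networks surfaces the temporal couplings that differ between
the low- and high-arousal conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import BLENDSHAPE_FACE_GROUP
from .features import mel_band_edges
from .core import SpikeRaster

FACE_GROUPS = ("brow", "eye", "cheek/nose", "jaw", "upper-mouth", "lower-mouth")
N_MEL_GROUPS = 10


@dataclass
class AssociationMatrix:
    """Ordered lag-1 event co-occurrence counts between channels."""

    counts: np.ndarray  # [features x features], nonnegative ints, zero diagonal
    feature_labels: list[str]
    class_label: int | str | None = None
    n_samples: int = 0
    lag: int = 1


@dataclass
class FINGraph:
    """Group-level interaction graph (nodes = feature groups)."""

    nodes: list[str]
    weights: np.ndarray  # [groups x groups]
    node_modality: dict
    class_label: int | str | None = None

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name in self.nodes:
            g.add_node(name, modality=self.node_modality.get(name, ""))
        for a, src in enumerate(self.nodes):
            for b, dst in enumerate(self.nodes):
                if self.weights[a, b] > 0:
                    g.add_edge(src, dst, weight=float(self.weights[a, b]))
        return g

    def save_json(self, path) -> None:
        import json

        data = nx.node_link_data(self.to_networkx(), edges="links")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    def save_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def association_matrix(rasters, lag: int = 1,
                       class_label=None) -> AssociationMatrix:
    """Count lag-1 "spike followed by spike" events over a set of rasters.

    ``counts[i, j]`` sums over samples and timesteps the indicator that
    channel i has an event at t and channel j at t + lag. The diagonal is
    excluded by convention.
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("no rasters given")
    labels = rasters[0].channel_labels or [f"ch{i}" for i in range(rasters[0].n_channels)]
    n = rasters[0].n_channels
    counts = np.zeros((n, n), dtype=np.int64)
    for r in rasters:
        if r.n_channels != n:
            raise ValueError("all rasters must share the channel order")
        if lag >= r.n_timesteps:
            raise ValueError(f"lag {lag} >= raster length {r.n_timesteps}")
        ev = r.events()
        counts += ev[:, :-lag] @ ev[:, lag:].T
    np.fill_diagonal(counts, 0)
    return AssociationMatrix(counts, list(labels), class_label, len(rasters), lag)


def mel_group_labels(n_bands: int = 40, n_groups: int = N_MEL_GROUPS,
                     f_low: float = 50.0, f_high: float = 8000.0) -> list[str]:
    """Names of contiguous mel-band groups, labelled by their Hz spans."""
    edges = mel_band_edges(n_bands, f_low, f_high)
    bounds = np.linspace(0, n_bands, n_groups + 1).astype(int)
    names = []
    for g in range(n_groups):
        lo = edges[bounds[g]]
        hi = edges[bounds[g + 1] + 1]
        names.append(f"mel {lo:.0f}-{hi:.0f} Hz")
    return names


def default_grouping(feature_labels: list[str], n_bands: int = 40) -> dict:
    """Map each multimodal input feature to its FIN group.

    Audio rows named ``mel_<band>_<L|R>`` (or ``band_<band>_<L|R>``) fall
    into ten contiguous mel frequency groups; visual rows named
    ``<blendshape>_<L|R>`` fall into the six face regions. Left and right
    copies share a group.
    """
    mel_names = mel_group_labels(n_bands)
    bounds = np.linspace(0, n_bands, N_MEL_GROUPS + 1).astype(int)
    band_to_group = np.searchsorted(bounds[1:], np.arange(n_bands), side="right")
    grouping = {}
    for label in feature_labels:
        stem = label[:-2] if label.endswith(("_L", "_R")) else label
        if stem in BLENDSHAPE_FACE_GROUP:
            grouping[label] = BLENDSHAPE_FACE_GROUP[stem]
            continue
        parts = stem.split("_")
        if len(parts) == 2 and parts[0] in ("mel", "band") and parts[1].isdigit():
            band = int(parts[1])
            if band < n_bands:
                grouping[label] = mel_names[band_to_group[band]]
                continue
        raise KeyError(f"feature {label!r} not covered by the default grouping")
    return grouping


def aggregate_fin(assoc: AssociationMatrix, grouping: dict | None = None,
                  n_bands: int = 40) -> FINGraph:
    """Sum feature-level counts into group-level edge weights.

    Every feature must belong to a group; the aggregation conserves the
    total count mass exactly.
    """
    if grouping is None:
        grouping = default_grouping(assoc.feature_labels, n_bands)
    missing = [f for f in assoc.feature_labels if f not in grouping]
    if missing:
        raise KeyError(f"features not covered by grouping: {missing[:5]}")
    nodes = list(dict.fromkeys(grouping[f] for f in assoc.feature_labels))
    node_idx = {g: i for i, g in enumerate(nodes)}
    member = np.array([node_idx[grouping[f]] for f in assoc.feature_labels])
    G = len(nodes)
    onehot = np.zeros((G, len(member)))
    onehot[member, np.arange(len(member))] = 1.0
    weights = onehot @ assoc.counts @ onehot.T
    modality = {
        g: ("audio" if g.startswith("mel ") else "visual") for g in nodes
    }
    return FINGraph(nodes, weights, modality, assoc.class_label)


def compare_classes(fin_a: FINGraph, fin_b: FINGraph) -> pd.DataFrame:
    """Per-edge normalised weights and differences, sorted by |difference|.

    Each class's weights are normalised by its total count so classes with
    different overall spike activity are comparable. One row per ordered
    node pair (diagonal excluded).
    """
    if fin_a.nodes != fin_b.nodes:
        raise ValueError("FIN node sets differ")
    wa = fin_a.weights / max(fin_a.total_weight(), 1e-30)
    wb = fin_b.weights / max(fin_b.total_weight(), 1e-30)
    rows = []
    for i, src in enumerate(fin_a.nodes):
        for j, dst in enumerate(fin_a.nodes):
            if i == j:
                continue
            rows.append({
                "source": src,
                "target": dst,
                f"weight_{fin_a.class_label}": wa[i, j],
                f"weight_{fin_b.class_label}": wb[i, j],
                "difference": wa[i, j] - wb[i, j],
            })
    df = pd.DataFrame(rows)
    return df.reindex(df["difference"].abs().sort_values(ascending=False).index).reset_index(drop=True)
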