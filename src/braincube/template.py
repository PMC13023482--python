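"""Brain-template neuron cloud, small-world connectivity, input mappings.

The reservoir's 3108 neurons live at millimetre MNI-like coordinates
(X lateral, Y posterior-anterior, Z inferior-superior) in two mirrored
hemispheric half-ellipsoids. Two region pairs are labelled by bounding
boxes: the primary auditory cortex A1 (a Heschl-like slab per hemisphere)
receives the tonotopically mapped audio bands, and the superior temporal
sulcus STS receives the topographically mapped facial blendshapes.

Recurrent connectivity is distance-dependent (small-world): a directed
connection i -> j is drawn with probability p0 * exp(-d(i,j)^2 / sigma^2),
with p0 calibrated by bisection so the realised density of nonzero directed
connections lands in the 0.3-0.5% band. A fixed fraction of neurons is
inhibitory; all their outgoing weights are negative, excitatory ones
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .core import BLENDSHAPE_NAMES, blendshape_height_class

REGIONS = ("A1_L", "A1_R", "STS_L", "STS_R", "OTHER")

# Region bounding boxes in mm, right hemisphere; left is mirrored in X.
# STS box follows the stated posterior-temporal coordinates; the A1 box is an
# elongated slab on the superior temporal plane whose long axis supports the
# principal-component tonotopic gradient.
A1_BOX_R = ((35.0, 55.0), (-38.0, -8.0), (0.0, 14.0))
STS_BOX_R = ((28.0, 60.0), (-62.0, -42.0), (-11.0, 16.0))

# Hemispheric half-ellipsoid: centre and semi-axes chosen so both region
# boxes sit inside a brain-sized volume.
_ELL_CENTRE = np.array([0.0, -16.0, 4.0])
_ELL_AXES = np.array([72.0, 92.0, 62.0])

DENSITY_BAND = (0.003, 0.005)


def _mirror_box(box):
    (x0, x1), y, z = box
    return ((-x1, -x0), y, z)


REGION_BOXES = {
    "A1_R": A1_BOX_R,
    "A1_L": _mirror_box(A1_BOX_R),
    "STS_R": STS_BOX_R,
    "STS_L": _mirror_box(STS_BOX_R),
}


def _in_box(coords: np.ndarray, box) -> np.ndarray:
    m = np.ones(len(coords), dtype=bool)
    for axis, (lo, hi) in enumerate(box):
        m &= (coords[:, axis] >= lo) & (coords[:, axis] <= hi)
    return m


@dataclass
class BrainTemplate:
    """Neuron coordinates (mm) with region labels."""

    coordinates: np.ndarray  # [n x 3]
    region_labels: np.ndarray  # [n] of str
    source: str = "procedural"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be [n x 3]")
        if len(self.region_labels) != len(self.coordinates):
            raise ValueError("one region label per neuron required")

    @property
    def n_neurons(self) -> int:
        return len(self.coordinates)

    def region_indices(self, *regions: str) -> np.ndarray:
        mask = np.isin(self.region_labels, regions)
        return np.flatnonzero(mask)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.coordinates, columns=["x", "y", "z"])
        df["region"] = self.region_labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BrainTemplate":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(), df["region"].to_numpy(), source="file")


def _sample_in_box(rng: np.random.Generator, box, n: int) -> np.ndarray:
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    return rng.uniform(lo, hi, (n, 3))


def _sample_half_ellipsoid(rng: np.random.Generator, n: int, side: int) -> np.ndarray:
    """Uniform points in one hemispheric half of the brain ellipsoid."""
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, (2 * (n - got) + 16, 3))
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= 1.0]
        pts = cand * _ELL_AXES + _ELL_CENTRE
        pts = pts[np.sign(pts[:, 0]) == side]
        # keep a small interhemispheric gap
        pts = pts[np.abs(pts[:, 0]) >= 2.0]
        take = min(len(pts), n - got)
        out[got : got + take] = pts[:take]
        got += take
    return out


def build_template(n_neurons: int = 3108, seed: int = 0,
                   source: str = "procedural", path=None) -> BrainTemplate:
    """Build the region-labelled neuron cloud.

    Procedural mode samples quasi-uniform points in two mirrored
    half-ellipsoids, with a per-region quota sampled directly inside each
    A1/STS bounding box so the input mappings are always feasible
    (the per-region neuron counts of the reference template are not
    published; quotas scale with n with floors of 40 per A1 hemisphere and
    52 per STS hemisphere). File mode reads an x,y,z,region CSV.
    """
    if source == "file":
        return BrainTemplate.from_csv(path)
    rng = np.random.default_rng(seed)
    a1_quota = max(40, int(round(0.02 * n_neurons)))
    sts_quota = max(52, int(round(0.026 * n_neurons)))
    quotas = {"A1_L": a1_quota, "A1_R": a1_quota, "STS_L": sts_quota, "STS_R": sts_quota}
    total_quota = sum(quotas.values())
    if n_neurons < total_quota + 8:
        short = "A1_L" if n_neurons < 2 * a1_quota else "STS_L"
        raise ValueError(
            f"n_neurons={n_neurons} too small to populate region {short} "
            f"(need at least {total_quota + 8})"
        )
    blocks, labels = [], []
    for region in ("A1_L", "A1_R", "STS_L", "STS_R"):
        pts = _sample_in_box(rng, REGION_BOXES[region], quotas[region])
        blocks.append(pts)
        labels.extend([region] * quotas[region])
    n_fill = n_neurons - total_quota
    n_left = n_fill // 2
    fill = np.vstack([
        _sample_half_ellipsoid(rng, n_left, -1),
        _sample_half_ellipsoid(rng, n_fill - n_left, +1),
    ])
    fill_labels = np.array(["OTHER"] * n_fill, dtype=object)
    for region, box in REGION_BOXES.items():
        fill_labels[_in_box(fill, box)] = region
    coords = np.vstack(blocks + [fill])
    region_labels = np.array(labels + list(fill_labels), dtype=object)
    template = BrainTemplate(coords, region_labels, source="procedural")
    for region in REGION_BOXES:
        if len(template.region_indices(region)) == 0:
            raise ValueError(f"region {region} ended up empty")
    return template


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityConfig:
    """Small-world initialisation parameters.

    ``target_density`` is the desired fraction of nonzero directed
    connections out of n^2; ``distance_scale`` (sigma, mm) sets the spatial
    reach of the exponential connection-probability kernel.
    """

    target_density: float = 0.004
    distance_scale: float = 15.0
    inhibitory_fraction: float = 0.2
    initial_weight_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not DENSITY_BAND[0] <= self.target_density <= DENSITY_BAND[1]:
            raise ValueError(
                f"target_density must lie in {DENSITY_BAND}, got {self.target_density}"
            )
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be positive")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must lie in [0, 1]")


@dataclass
class CubeModel:
    """Template + sparse signed recurrent weights.

    ``weights[i, j]`` is the directed connection from neuron i to neuron j.
    Outgoing weights of inhibitory neurons are <= 0, of excitatory >= 0.
    """

    template: BrainTemplate
    weights: sp.csr_matrix
    neuron_sign: np.ndarray  # +1 excitatory / -1 inhibitory per neuron

    @property
    def n_neurons(self) -> int:
        return self.template.n_neurons

    def density(self) -> float:
        n = self.n_neurons
        return self.weights.nnz / float(n * n)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.template.to_csv(directory / "template.csv")
        coo = self.weights.tocoo()
        pd.DataFrame({"i": coo.row, "j": coo.col, "weight": coo.data}).to_csv(
            directory / "weights.csv", index=False
        )
        pd.DataFrame({"sign": self.neuron_sign}).to_csv(
            directory / "neuron_sign.csv", index=False
        )

    @classmethod
    def load(cls, directory) -> "CubeModel":
        directory = Path(directory)
        template = BrainTemplate.from_csv(directory / "template.csv")
        w = pd.read_csv(directory / "weights.csv")
        n = template.n_neurons
        weights = sp.csr_matrix(
            (w["weight"].to_numpy(), (w["i"].to_numpy(), w["j"].to_numpy())),
            shape=(n, n),
        )
        sign = pd.read_csv(directory / "neuron_sign.csv")["sign"].to_numpy()
        return cls(template, weights, sign)


def _distance_kernel(coords: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (
        np.sum(coords**2, axis=1)[:, None]
        + np.sum(coords**2, axis=1)[None, :]
        - 2.0 * coords @ coords.T
    )
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / sigma**2)
    np.fill_diagonal(K, 0.0)  # no self-connections
    return K


def init_connectivity(template: BrainTemplate,
                      cfg: ConnectivityConfig | None = None) -> CubeModel:
    """Draw sparse signed small-world connectivity at the target density.

    The base rate p0 is found by bisection so the expected density of
    ``min(1, p0 * exp(-d^2/sigma^2))`` equals ``target_density``; an error is
    raised when even a saturated kernel cannot reach the target (sigma too
    small for the requested density).
    """
    cfg = cfg or ConnectivityConfig()
    rng = np.random.default_rng(cfg.seed)
    n = template.n_neurons
    K = _distance_kernel(template.coordinates, cfg.distance_scale)
    total = float(n) * n

    def expected_density(p0: float) -> float:
        return float(np.minimum(p0 * K, 1.0).sum() / total)

    mean_k = float(K.sum() / total)
    if mean_k > 0 and cfg.target_density / mean_k <= 1.0:
        # K <= 1, so p0 <= 1 never clips: the expected density is exactly
        # linear in p0 and the bisection collapses to one division
        p_hi = cfg.target_density / mean_k
    else:
        p_hi = 1.0
        while expected_density(p_hi) < cfg.target_density:
            p_hi *= 4.0
            if p_hi > 1e8:
                raise ValueError(
                    f"target density {cfg.target_density} unattainable for "
                    f"sigma={cfg.distance_scale} mm"
                )
        p_lo = 0.0
        for _ in range(60):
            p_mid = 0.5 * (p_lo + p_hi)
            if expected_density(p_mid) < cfg.target_density:
                p_lo = p_mid
            else:
                p_hi = p_mid
    prob = np.minimum(p_hi * K, 1.0)
    mask = rng.random((n, n)) < prob
    np.fill_diagonal(mask, False)
    sign = np.where(rng.random(n) < cfg.inhibitory_fraction, -1, 1)
    rows, cols = np.nonzero(mask)
    mags = rng.uniform(0.2, 1.0, len(rows)) * cfg.initial_weight_scale
    data = mags * sign[rows]
    weights = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return CubeModel(template, weights, sign)


# ---------------------------------------------------------------------------
# Input mappings
# ---------------------------------------------------------------------------

@dataclass
class InputMapping:
    """Injective feature -> neuron assignment.

    ``assignments[f]`` is the reservoir neuron receiving input feature f
    (features ordered left-channel block first, then right). ``tonotopic_u``
    holds the normalised principal-axis position of each mapped neuron for
    audio maps.
    """

    assignments: np.ndarray  # [n_features] neuron indices
    feature_labels: list[str]
    regions: list[str]
    tonotopic_u: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if len(np.unique(self.assignments)) != len(self.assignments):
            raise ValueError("mapping must be injective")

    @property
    def n_features(self) -> int:
        return len(self.assignments)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "feature_label": self.feature_labels,
            "neuron_index": self.assignments,
            "region": self.regions,
        })
        if self.tonotopic_u is not None:
            df["u"] = self.tonotopic_u
        df.to_csv(path, index=False)


def concat_mappings(*mappings: InputMapping) -> InputMapping:
    u_parts = [
        m.tonotopic_u if m.tonotopic_u is not None else np.full(m.n_features, np.nan)
        for m in mappings
    ]
    u = np.concatenate(u_parts)
    return InputMapping(
        assignments=np.concatenate([m.assignments for m in mappings]),
        feature_labels=sum((list(m.feature_labels) for m in mappings), []),
        regions=sum((list(m.regions) for m in mappings), []),
        tonotopic_u=None if np.all(np.isnan(u)) else u,
    )


def _tonotopic_hemisphere(template: BrainTemplate, region: str, n_bands: int,
                          labels: list[str]) -> InputMapping:
    idx = template.region_indices(region)
    if len(idx) < n_bands:
        raise ValueError(f"{region} has {len(idx)} neurons, fewer than {n_bands} bands")
    coords = template.coordinates[idx]
    if coords.var(axis=0).sum() <= 1e-18:
        raise ValueError(f"degenerate {region} geometry: zero-variance principal axis")
    pca = PCA(n_components=1)
    proj = pca.fit_transform(coords)[:, 0]
    if np.ptp(proj) <= 1e-9:
        raise ValueError(f"degenerate {region} geometry: zero-variance principal axis")
    u = (proj - proj.min()) / np.ptp(proj)
    # fold the axis so low frequencies sit at the centre, high at both ends
    tau = np.abs(2.0 * u - 1.0)
    targets = np.linspace(0.0, 1.0, n_bands)
    chosen = np.full(n_bands, -1)
    available = np.ones(len(idx), dtype=bool)
    for b, target in enumerate(targets):
        cost = np.abs(tau - target)
        cost[~available] = np.inf
        pick = int(np.argmin(cost))  # argmin takes the lowest index on ties
        chosen[b] = pick
        available[pick] = False
    return InputMapping(
        assignments=idx[chosen],
        feature_labels=list(labels),
        regions=[region] * n_bands,
        tonotopic_u=u[chosen],
    )


def tonotopic_map(template: BrainTemplate, n_bands: int = 40,
                  band_labels: list[str] | None = None) -> InputMapping:
    """Map audio bands into A1 along its folded principal (tonotopic) axis.

    Per hemisphere, A1 coordinates are projected onto their first principal
    component, normalised to u in [0,1], and folded to tau = |2u - 1| so the
    lowest band targets the centre of A1 and the highest the ends (the
    mirror-symmetric cortical frequency gradient). Band i of the left
    channel maps to the i-th selected left-A1 neuron; right-channel bands
    follow after all left bands.
    """
    if band_labels is None:
        band_labels = [f"band_{b}" for b in range(n_bands)]
    left = _tonotopic_hemisphere(
        template, "A1_L", n_bands, [f"{l}_L" for l in band_labels]
    )
    right = _tonotopic_hemisphere(
        template, "A1_R", n_bands, [f"{l}_R" for l in band_labels]
    )
    return concat_mappings(left, right)


def _topographic_hemisphere(template: BrainTemplate, region: str,
                            names: list[str], suffix: str) -> InputMapping:
    idx = template.region_indices(region)
    if len(idx) < len(names):
        raise ValueError(
            f"{region} has {len(idx)} neurons, fewer than {len(names)} blendshapes"
        )
    # blendshapes ordered by facial height class (stable within class),
    # neurons by descending Z: dorsal neurons take upper-face features
    order = sorted(range(len(names)), key=lambda i: (blendshape_height_class(names[i]), i))
    z = template.coordinates[idx, 2]
    by_z = idx[np.lexsort((idx, -z))]
    assignments = np.empty(len(names), dtype=int)
    for rank, feat in enumerate(order):
        assignments[feat] = by_z[rank]
    return InputMapping(
        assignments=assignments,
        feature_labels=[f"{n}{suffix}" for n in names],
        regions=[region] * len(names),
    )


def topographic_map(template: BrainTemplate,
                    blendshape_names: list[str] | None = None) -> InputMapping:
    """Map blendshapes into STS dorsoventrally (brow dorsal, jaw ventral).

    The same height ordering is applied in both hemispheres; left copies of
    all features come before right copies, matching the bilateral 104-row
    visual series.
    """
    names = list(blendshape_names or BLENDSHAPE_NAMES)
    left = _topographic_hemisphere(template, "STS_L", names, "_L")
    right = _topographic_hemisphere(template, "STS_R", names, "_R")
    return concat_mappings(left, right)
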