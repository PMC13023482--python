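"""End-to-end orchestration: encode, map, train, extract, classify, explain.

A :class:`RunConfig` fully determines a run (all stage randomness derives
from one root seed), and a trained model bundle — template, weights, input
mapping, encoder thetas, classifier and normalisation statistics — can be
saved to and reloaded from a directory, reproducing predictions exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify
from .classify import (
    DEFAULT_THRESHOLDS,
    LearnedPrototypeConfig,
    Normaliser,
    PrototypeSet,
    balance_by_duplication,
    fit_centroid,
    fit_learned_prototype,
    predict_proba,
    selective_metrics,
    selective_predict,
)
from .core import FeatureSeries, SpikeRaster
from .encoding import SFConfig, sf_encode, thetas_from_sd
from .explain import aggregate_fin, association_matrix, compare_classes
from .features import synchronise
from .reservoir import LIFConfig, STDPParams, simulate, train_cube
from .states import DeSNNParams, extract_state
from .template import (
    BrainTemplate,
    ConnectivityConfig,
    CubeModel,
    InputMapping,
    build_template,
    concat_mappings,
    init_connectivity,
    tonotopic_map,
    topographic_map,
)


@dataclass
class RunConfig:
    """Serialisable configuration of one experiment."""

    modality: str = "multimodal"  # audio | visual | multimodal
    n_neurons: int = 3108
    n_audio_bands: int = 40
    sf_k: float = 0.5
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    lif: LIFConfig = field(default_factory=LIFConfig)
    stdp: STDPParams = field(default_factory=STDPParams)
    state_method: str = "split_count"
    state_scope: str = "I_plus_R"
    classifier: str = "learned_prototype"
    prototype: LearnedPrototypeConfig = field(default_factory=LearnedPrototypeConfig)
    threshold: float | None = None
    passes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("audio", "visual", "multimodal"):
            raise ValueError("modality must be audio, visual or multimodal")
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS[
                "visual" if self.modality == "visual" else self.modality
            ]

    def to_json(self, path=None) -> str:
        d = asdict(self)
        s = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["connectivity"] = ConnectivityConfig(**d["connectivity"])
        d["lif"] = LIFConfig(**d["lif"])
        d["stdp"] = STDPParams(**d["stdp"])
        d["prototype"] = LearnedPrototypeConfig(**d["prototype"])
        return cls(**d)

    def stage_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        names = ("template", "connectivity", "classifier")
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def select_series(audio: FeatureSeries, visual: FeatureSeries, modality: str) -> FeatureSeries:
    if modality == "audio":
        return audio
    if modality == "visual":
        return visual
    return synchronise(audio, visual)


@dataclass
class TrainedModel:
    """Everything needed to reproduce predictions on new samples."""

    config: RunConfig
    cube: CubeModel
    mapping: InputMapping
    thetas: np.ndarray
    feature_labels: list[str]
    normaliser: Normaliser
    protoset: PrototypeSet

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.config.to_json(directory / "config.json")
        self.cube.save(directory / "cube")
        self.mapping.to_csv(directory / "mapping.csv")
        np.savez_compressed(
            directory / "model_arrays.npz",
            thetas=self.thetas,
            norm_mean=self.normaliser.mean,
            norm_sd=self.normaliser.sd,
            prototypes=self.protoset.prototypes,
            classes=self.protoset.classes,
            tau=np.array(self.protoset.tau),
            feature_labels=np.array(self.feature_labels, dtype=object),
        )
        digest = hashlib.sha256()
        for name in ("config.json", "mapping.csv"):
            digest.update((directory / name).read_bytes())
        (directory / "manifest.json").write_text(
            json.dumps({"hash": digest.hexdigest()}, indent=1)
        )

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        config = RunConfig.from_json(directory / "config.json")
        cube = CubeModel.load(directory / "cube")
        mdf = pd.read_csv(directory / "mapping.csv")
        mapping = InputMapping(
            assignments=mdf["neuron_index"].to_numpy(),
            feature_labels=list(mdf["feature_label"]),
            regions=list(mdf["region"]),
            tonotopic_u=mdf["u"].to_numpy() if "u" in mdf else None,
        )
        with np.load(directory / "model_arrays.npz", allow_pickle=True) as z:
            thetas = z["thetas"]
            normaliser = Normaliser(z["norm_mean"], z["norm_sd"])
            protoset = PrototypeSet(z["prototypes"], z["classes"], float(z["tau"]))
            labels = list(z["feature_labels"])
        return cls(config, cube, mapping, thetas, labels, normaliser, protoset)

    # ------------------------------------------------------------------
    def encode(self, series: FeatureSeries) -> SpikeRaster:
        cfg = SFConfig(theta=self.thetas, theta_rule="fixed")
        raster, _, _ = sf_encode(series, cfg)
        return raster

    def state_for(self, series: FeatureSeries) -> np.ndarray:
        raster = self.encode(series)
        activity = simulate(self.cube, raster, self.mapping, mode="recall",
                            lif=self.config.lif, stdp=self.config.stdp)
        sv = extract_state(raster, activity.raster, self.cube, self.mapping,
                           self.config.state_method, self.config.state_scope)
        return sv.values

    def predict_proba(self, states: np.ndarray) -> np.ndarray:
        return predict_proba(self.protoset, self.normaliser.transform(states))


def build_mapping(template: BrainTemplate, config: RunConfig,
                  audio_band_labels=None) -> InputMapping:
    parts = []
    if config.modality in ("audio", "multimodal"):
        parts.append(tonotopic_map(template, config.n_audio_bands, audio_band_labels))
    if config.modality in ("visual", "multimodal"):
        parts.append(topographic_map(template))
    return parts[0] if len(parts) == 1 else concat_mappings(*parts)


def run_train(config: RunConfig, train_samples, out_dir=None) -> "TrainedModel":
    """Train cube + classifier on (audio, visual, label) samples.

    Stages: per-feature Step-Forward thetas from the pooled training
    values; template + small-world cube; tonotopic/topographic mapping;
    incremental STDP over the training rasters; state extraction; z-score +
    class balancing; classifier fit.
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValueError("empty training dataset")
    seeds = config.stage_seeds()
    series = [select_series(a, v, config.modality) for a, v, _ in train_samples]
    labels = np.array([lab for _, _, lab in train_samples])
    pooled = np.concatenate([s.values for s in series], axis=1)
    thetas = thetas_from_sd(pooled, config.sf_k)
    rasters = [sf_encode(s, SFConfig(theta=thetas, theta_rule="fixed"))[0] for s in series]

    template = build_template(config.n_neurons, seed=seeds["template"])
    conn = ConnectivityConfig(**{**asdict(config.connectivity), "seed": seeds["connectivity"]})
    cube = init_connectivity(template, conn)
    band_labels = [f"mel_{b}" for b in range(config.n_audio_bands)]
    mapping = build_mapping(template, config, band_labels)

    train_cube(cube, rasters, mapping, lif=config.lif, stdp=config.stdp,
               passes=config.passes)

    states = np.vstack([
        extract_state(r, simulate(cube, r, mapping, mode="recall", lif=config.lif,
                                  stdp=config.stdp).raster,
                      cube, mapping, config.state_method, config.state_scope).values
        for r in rasters
    ])
    model = fit_classifier(config, states, labels, seeds["classifier"])
    trained = TrainedModel(
        config=config, cube=cube, mapping=mapping, thetas=thetas,
        feature_labels=list(series[0].feature_labels),
        normaliser=model["normaliser"], protoset=model["protoset"],
    )
    if out_dir is not None:
        trained.save(out_dir)
    return trained


def fit_classifier(config: RunConfig, states: np.ndarray, labels: np.ndarray,
                   seed: int = 0) -> dict:
    """Normalise, balance and fit the configured classifier on state vectors."""
    normaliser = Normaliser.fit(states)
    Xn = normaliser.transform(states)
    Xb, yb = balance_by_duplication(Xn, labels, seed=seed)
    if config.classifier == "centroid":
        protoset = fit_centroid(Xb, yb, config.prototype.tau)
    elif config.classifier == "learned_prototype":
        proto_cfg = LearnedPrototypeConfig(**{**asdict(config.prototype), "seed": seed})
        protoset = fit_learned_prototype(Xb, yb, proto_cfg)
    else:
        raise ValueError(
            f"classifier {config.classifier!r} is not bundle-serialisable here; "
            "use 'centroid' or 'learned_prototype' (wwknn/svm available via "
            "the classify module)"
        )
    return {"normaliser": normaliser, "protoset": protoset}


def run_eval(model: TrainedModel, test_samples, thresholds=None) -> dict:
    """One prediction pass; selective reports for each threshold.

    Returns per-sample probabilities/forced predictions plus one
    :class:`~braincube.classify.SelectiveReport` per threshold, all from
    the same pass (no retraining).
    """
    test_samples = list(test_samples)
    if thresholds is None:
        thresholds = [model.config.threshold]
    states = np.vstack([
        model.state_for(select_series(a, v, model.config.modality))
        for a, v, _ in test_samples
    ])
    if states.shape[1] != len(model.normaliser.mean):
        raise ValueError("state-vector dimensionality does not match the model")
    truth = np.array([lab for _, _, lab in test_samples])
    probs = model.predict_proba(states)
    forced = model.protoset.classes[np.argmax(probs, axis=1)]
    reports = {}
    for thr in thresholds:
        sel = selective_predict(probs, thr, model.protoset.classes)
        reports[thr] = selective_metrics(truth, sel, forced, threshold=thr)
    return {
        "probs": probs,
        "forced": forced,
        "truth": truth,
        "reports": reports,
        "accuracy": float(np.mean(forced == truth)),
    }


def run_explain(model: TrainedModel, samples, out_dir=None) -> dict:
    """Per-class Feature Interaction Networks and their difference table."""
    samples = list(samples)
    classes = sorted({lab for _, _, lab in samples})
    fins = {}
    for c in classes:
        rasters = [
            model.encode(select_series(a, v, model.config.modality))
            for a, v, lab in samples if lab == c
        ]
        if not rasters:
            raise ValueError(f"no samples for class {c!r}")
        assoc = association_matrix(rasters, class_label=c)
        fins[c] = aggregate_fin(assoc, n_bands=model.config.n_audio_bands)
    diff = compare_classes(fins[classes[0]], fins[classes[1]]) if len(classes) == 2 else None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for c, fin in fins.items():
            fin.save_json(out_dir / f"fin_class{c}.json")
            fin.save_graphml(out_dir / f"fin_class{c}.graphml")
        if diff is not None:
            diff.to_csv(out_dir / "fin_difference.csv", index=False)
    return {"fins": fins, "difference": diff}
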