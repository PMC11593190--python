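"""Scenario orchestration: feature extraction, fusion, split, train, report.

A *scenario* is one (feature set, classifier) pair; the standard grid
crosses the three cumulative feature sets (deep; deep+textural;
deep+textural+contextual) with the four classifier families, giving 12
scenarios.  Feature blocks are extracted once per (extractor config, tile)
and cached, so the whole grid costs three extraction passes.

End-to-end fine-tuning of a pretrained CNN (the 13th scenario of the full
protocol) is available only through a user-supplied pretrained adapter and
is not part of the automated grid.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sklearn

from . import classify, evaluate
from .deep_backbone import BackboneSpec, extract_deep_features, resolve_backbone
from .fusion_matrix import FeatureBlock, assemble_matrix, fuse, split_dataset
from .imageio_preproc import (CLASS_CODES, ImageTile, PIPELINE_SIDE,
                              resize_tile, to_grayscale)
from .lbp_texture import LBPConfig, lbp_feature_vector
from .vit_context import ViTConfig, ViTParams, vit_encode

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "deep": ("deep",),
    "deep+textural": ("deep", "textural"),
    "deep+textural+contextual": ("deep", "textural", "contextual"),
}

CLASSIFIERS: tuple[str, ...] = classify.ALGORITHMS


@dataclass
class PipelineConfig:
    """One bundle of every stage's configuration."""

    lbp: LBPConfig = field(default_factory=LBPConfig)
    vit: ViTConfig = field(default_factory=ViTConfig)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    split_ratio: float = 0.8
    split_seed: int = 0
    stratified: bool = True
    classifier_seed: int = 0
    classifier_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw: dict = {}
        if "lbp" in d:
            kw["lbp"] = LBPConfig(**d["lbp"])
        if "vit" in d:
            v = dict(d["vit"])
            if "weights" in v:
                v["weight_source"] = v.pop("weights")
            kw["vit"] = ViTConfig(**v)
        if "backbone" in d:
            b = dict(d["backbone"])
            if "out_shape" in b:
                b["out_shape"] = tuple(b["out_shape"])
            kw["backbone"] = BackboneSpec(**b)
        split = d.get("split", {})
        if "ratio" in split:
            kw["split_ratio"] = float(split["ratio"])
        if "seed" in split:
            kw["split_seed"] = int(split["seed"])
        if "stratified" in split:
            kw["stratified"] = bool(split["stratified"])
        clf = d.get("classifier", {})
        if "seed" in clf:
            kw["classifier_seed"] = int(clf["seed"])
        if "params" in clf:
            kw["classifier_params"] = dict(clf["params"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def extractor_hash(self, kind: str) -> str:
        """Stable hash of the configuration that determines one extractor."""
        if kind == "deep":
            payload = {"kind": self.backbone.kind,
                       "out_shape": list(self.backbone.out_shape),
                       "seed": self.backbone.seed}
        elif kind == "textural":
            payload = dataclasses.asdict(self.lbp)
        elif kind == "contextual":
            c = self.vit
            payload = {"patch_size": c.patch_size, "embed_dim": c.embed_dim,
                       "n_heads": c.n_heads, "n_layers": c.n_layers,
                       "mlp_dim": c.mlp_dim, "positional": c.positional,
                       "weight_source": (c.weight_source
                                         if isinstance(c.weight_source, int)
                                         else "external")}
        else:
            raise ValueError(f"unknown extractor kind {kind!r}")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def config_hash(self) -> str:
        blob = json.dumps({k: self.extractor_hash(k)
                           for k in ("deep", "textural", "contextual")},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScenarioSpec:
    """One grid cell: feature set, classifier and the seeds that drive it."""

    feature_set: str
    classifier: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"feature_set must be one of {tuple(FEATURE_SETS)}, "
                f"got {self.feature_set!r}"
            )
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"classifier must be one of {CLASSIFIERS}, got {self.classifier!r}"
            )

    @property
    def method_name(self) -> str:
        return f"{self.feature_set} / {self.classifier}"


class FeatureCache:
    """In-memory block cache keyed by (block kind, config hash, tile id)."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str, str], np.ndarray] = {}
        self.hits = 0
        self.misses = 0

    def get(self, kind: str, cfg_hash: str, source_id: str):
        key = (kind, cfg_hash, source_id)
        if key in self._store:
            self.hits += 1
            return self._store[key]
        self.misses += 1
        return None

    def put(self, kind: str, cfg_hash: str, source_id: str,
            values: np.ndarray) -> None:
        self._store[(kind, cfg_hash, source_id)] = values


def _dataset_fingerprint(tiles: list[ImageTile]) -> str:
    h = hashlib.sha256()
    for t in tiles:
        h.update(t.source_id.encode())
        h.update(str(t.label).encode())
        h.update(str(t.pixels.shape).encode())
    return h.hexdigest()[:16]


def extract_blocks(tiles: list[ImageTile], feature_set: str,
                   config: PipelineConfig,
                   cache: FeatureCache | None = None
                   ) -> list[list[FeatureBlock]]:
    """Per-tile feature blocks for one feature set, cache-aware.

    Every tile passes through the real preprocessing path: resize to
    224x224 for all branches, grayscale for the textural branch.
    """
    kinds = FEATURE_SETS[feature_set]
    hashes = {k: config.extractor_hash(k) for k in kinds}
    backbone_fn = None
    out: list[list[FeatureBlock]] = []
    for tile in tiles:
        pre = None
        blocks: list[FeatureBlock] = []
        for kind in kinds:
            cached = cache.get(kind, hashes[kind], tile.source_id) \
                if cache is not None and tile.source_id else None
            if cached is not None:
                blocks.append(FeatureBlock(name=kind, values=cached))
                continue
            if pre is None:
                pre = resize_tile(tile, PIPELINE_SIDE)
            if kind == "deep":
                if backbone_fn is None:
                    backbone_fn = resolve_backbone(config.backbone,
                                                   in_side=PIPELINE_SIDE)
                block = extract_deep_features(
                    pre, backbone_fn, expected_dim=config.backbone.out_shape[2])
            elif kind == "textural":
                block = lbp_feature_vector(to_grayscale(pre), config.lbp)
            else:
                block = vit_encode(pre, config.vit)
            if cache is not None and tile.source_id:
                cache.put(kind, hashes[kind], tile.source_id, block.values)
            blocks.append(block)
        out.append(blocks)
    return out


@dataclass
class RunManifest:
    """Everything needed to audit (and re-run) one scenario."""

    scenario: dict
    dataset_fingerprint: str
    n_samples: int
    feature_dims: dict
    fused_dim: int
    split: dict
    metrics: list
    confusion: list
    overall_accuracy: float
    versions: dict
    timings: dict = field(default_factory=dict)

    def canonical_json(self) -> str:
        """Deterministic JSON of everything except wall-clock timings."""
        d = dataclasses.asdict(self)
        d.pop("timings", None)
        return json.dumps(d, sort_keys=True)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _versions(classifier: str) -> dict:
    v = {"numpy": np.__version__, "scikit-learn": sklearn.__version__}
    if classifier == "boosted_trees_A":
        import lightgbm
        v["lightgbm"] = lightgbm.__version__
    if classifier == "boosted_trees_B":
        import xgboost
        v["xgboost"] = xgboost.__version__
    return v


def run_scenario(spec: ScenarioSpec, tiles: list[ImageTile],
                 config: PipelineConfig,
                 cache: FeatureCache | None = None) -> RunManifest:
    """Execute one scenario end to end and return its manifest."""
    if any(t.label is None for t in tiles):
        raise ValueError("every tile needs a label to run a scenario")
    labels = np.array([CLASS_CODES[t.label] for t in tiles])
    if np.unique(labels).size < 2:
        raise ValueError("scenario needs at least 2 classes in the dataset")

    t0 = time.perf_counter()
    per_tile = extract_blocks(tiles, spec.feature_set, config, cache)
    t_extract = time.perf_counter() - t0

    fused = [fuse(blocks) for blocks in per_tile]
    matrix = assemble_matrix(fused, labels)
    feature_dims = {name: length for name, _, length in fused[0].offsets}

    train_idx, test_idx = split_dataset(
        labels, ratio=config.split_ratio, seed=config.split_seed,
        stratified=config.stratified)

    cspec = classify.ClassifierSpec(
        algorithm=spec.classifier,
        hyperparameters=dict(config.classifier_params.get(spec.classifier, {})),
        seed=spec.seed if spec.seed else config.classifier_seed)
    t0 = time.perf_counter()
    model = classify.train_classifier(matrix.subset(train_idx), cspec)
    y_pred = classify.predict(model, matrix.subset(test_idx))
    t_fit = time.perf_counter() - t0

    cm = evaluate.confusion(labels[test_idx], y_pred)
    report = evaluate.metrics_report(cm)

    return RunManifest(
        scenario={"feature_set": spec.feature_set,
                  "classifier": spec.classifier,
                  "classifier_seed": cspec.seed,
                  "split_seed": config.split_seed,
                  "split_ratio": config.split_ratio,
                  "stratified": config.stratified,
                  "config_hash": config.config_hash(),
                  "standardized": cspec.effective_standardize,
                  "hyperparameters": cspec.hyperparameters},
        dataset_fingerprint=_dataset_fingerprint(tiles),
        n_samples=len(tiles),
        feature_dims=feature_dims,
        fused_dim=matrix.dim,
        split={"n_train": int(train_idx.size), "n_test": int(test_idx.size)},
        metrics=report.to_dict(orient="records"),
        confusion=cm.counts.tolist(),
        overall_accuracy=evaluate.overall_accuracy(cm),
        versions=_versions(spec.classifier),
        timings={"extract_s": t_extract, "fit_predict_s": t_fit},
    )


def run_grid(tiles: list[ImageTile], config: PipelineConfig,
             seed: int = 0):
    """Run all 12 (feature set x classifier) scenarios.

    Returns ``(report, manifests)``: a consolidated Table-style report
    DataFrame and the per-scenario manifests.  Feature blocks are computed
    once per extractor and reused across classifiers via the cache.
    """
    cache = FeatureCache()
    manifests: dict[str, RunManifest] = {}
    results: dict[str, evaluate.ConfusionMatrix] = {}
    for feature_set in FEATURE_SETS:
        for clf in CLASSIFIERS:
            spec = ScenarioSpec(feature_set=feature_set, classifier=clf,
                                seed=seed)
            man = run_scenario(spec, tiles, config, cache)
            manifests[spec.method_name] = man
            results[spec.method_name] = evaluate.ConfusionMatrix(
                counts=np.array(man.confusion),
                labels=evaluate.DISPLAY_CODES)
    report = evaluate.scenario_report(results)
    return report, manifests
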