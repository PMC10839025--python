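"""End-to-end experiment orchestration.

The central objects follow the model/results idiom of statistical
modelling packages:

* :class:`GasfBowExperiment` is the model: signals plus a
  :class:`PipelineConfig`.  Its :meth:`~GasfBowExperiment.fit` runs
  epoching -> GASF encoding -> keypoint extraction -> vocabulary
  (training split only) -> BoW encoding -> chi-square selection
  (training split only) -> classifier training -> held-out evaluation.
* :class:`ExperimentResults` carries the fitted artifacts (vocabularies,
  selections, models) and the evaluation reports, renders a summary
  table, draws ROC curves, and runs the Gaussian-noise robustness sweep
  against the frozen artifacts.

``run_all`` / ``run_noise_sweep`` wrap these objects with on-disk
artifacts and a run manifest for command-line use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bow import (
    Chi2Result,
    FeatureTable,
    Vocabulary,
    build_vocabulary,
    chi2_score,
    encode_table,
    select_top_k,
)
from .evaluation import (
    ClassifierSpec,
    EvaluationReport,
    FittedModel,
    evaluate,
    split_indices,
    train,
)
from .exceptions import ConfigError, SweepError
from .gasf import EpochingConfig, GASFImage, signal_to_images
from .keypoints import ExtractorConfig, extract_batch
from .signals import (
    NO_NOISE,
    NoiseSpec,
    Signal,
    SyntheticConfig,
    add_noise,
    generate_dataset,
    read_manifest,
    write_manifest,
)

__all__ = [
    "PipelineConfig",
    "GasfBowExperiment",
    "ExperimentResults",
    "RunManifest",
    "run_all",
    "run_noise_sweep",
]


def _spec_to_dict(spec: ClassifierSpec) -> dict:
    return {"kind": spec.kind, "hyperparams": dict(spec.hyperparams), "seed": spec.seed}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the experiment, with the published defaults.

    The global ``seed`` fans out to the stages (dataset, split,
    vocabulary, classifiers, noise) with fixed small offsets so a single
    integer reproduces the whole run.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    manifest: str | None = None
    epoch_len: int = 256
    overlap: int = 0
    rescale_mode: str = "symmetric"
    methods: tuple[str, ...] = ("sift", "orb")
    extractor_overrides: dict = field(default_factory=dict)
    bow_k: int = 100
    normalization: str = "frequency"
    max_train_descriptors: int | None = 100_000
    k_select: int = 10
    test_frac: float = 0.1
    stratified: bool = True
    group_by_signal: bool = False
    classifier_kinds: tuple[str, ...] = ("svm_rbf", "rf", "knn")
    classifier_hyperparams: dict = field(default_factory=dict)
    positive_class: str = "focal"
    noise_snr_grid: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    noise_n_per_class: int = 40
    noise_unit: str = "signals"
    noise_classifier: str = "rf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_unit not in ("signals", "epochs"):
            raise ConfigError("noise_unit must be 'signals' or 'epochs'")
        for m in self.methods:
            if m not in ("sift", "orb"):
                raise ConfigError(f"unknown feature method {m!r}")

    # -- derived stage seeds -------------------------------------------------
    @property
    def split_seed(self) -> int:
        return (self.seed + 1) % (2**31)

    @property
    def vocab_seed(self) -> int:
        return (self.seed + 2) % (2**31)

    @property
    def classifier_seed(self) -> int:
        return (self.seed + 3) % (2**31)

    @property
    def noise_seed(self) -> int:
        return (self.seed + 4) % (2**31)

    def epoching(self) -> EpochingConfig:
        return EpochingConfig(epoch_len=self.epoch_len, overlap=self.overlap)

    def extractor(self, method: str) -> ExtractorConfig:
        return ExtractorConfig(method=method, **self.extractor_overrides.get(method, {}))

    def classifier_specs(self) -> list[ClassifierSpec]:
        return [
            ClassifierSpec(
                kind=k,
                hyperparams=self.classifier_hyperparams.get(k, {}),
                seed=self.classifier_seed,
            )
            for k in self.classifier_kinds
        ]

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["class_params"] = {
            name: dataclasses.asdict(p) for name, p in self.synthetic.class_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .signals import ClassParams

        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "class_params" in syn:
            syn["class_params"] = {
                name: ClassParams(
                    band=tuple(p["band"]),
                    osc_amp=p.get("osc_amp", 1.0),
                    transient_rate=p.get("transient_rate", 0.0),
                    transient_amp=tuple(p.get("transient_amp", (3.0, 5.0))),
                )
                for name, p in syn["class_params"].items()
            }
        for key in ("methods", "classifier_kinds", "noise_snr_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(synthetic=SyntheticConfig(**syn), **d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class _ImageSet:
    """GASF images of a dataset plus per-image label / source bookkeeping."""

    images: list[GASFImage]
    labels: np.ndarray
    groups: np.ndarray  # source signal id per image

    def __len__(self) -> int:
        return len(self.images)


def _encode_dataset(signals: Sequence[Signal], config: PipelineConfig) -> _ImageSet:
    images: list[GASFImage] = []
    labels: list[str] = []
    groups: list[str] = []
    epoching = config.epoching()
    for sig in signals:
        imgs = signal_to_images(sig, epoching, config.rescale_mode)
        images.extend(imgs)
        labels.extend([sig.label or ""] * len(imgs))
        groups.extend([sig.id] * len(imgs))
    return _ImageSet(images=images, labels=np.asarray(labels), groups=np.asarray(groups))


class GasfBowExperiment:
    """The experiment model: a set of labelled signals plus a configuration.

    Parameters
    ----------
    signals
        Labelled single-channel EEG signals.
    config
        Pipeline configuration; defaults reproduce the published setting
        (50+50 signals of 20 s at 512 Hz, 256-sample epochs, k=100 words,
        top-10 chi-square features, 90/10 stratified split).
    """

    def __init__(self, signals: Sequence[Signal], config: PipelineConfig | None = None):
        self.signals = list(signals)
        self.config = config or PipelineConfig()
        if not self.signals:
            raise ConfigError("experiment requires at least one signal")

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "GasfBowExperiment":
        """Build the model from its config: synthetic generation or a manifest."""
        if config.manifest:
            signals = read_manifest(config.manifest)
        else:
            syn = replace(config.synthetic, seed=config.seed)
            signals = generate_dataset(syn)
        return cls(signals, config)

    def fit(self, verbose: bool = False) -> "ExperimentResults":
        """Run the full pipeline and return the fitted results."""
        cfg = self.config
        t0 = time.perf_counter()
        timings: dict[str, float] = {}

        image_set = _encode_dataset(self.signals, cfg)
        timings["gasf"] = time.perf_counter() - t0

        train_idx, test_idx = split_indices(
            image_set.labels,
            test_frac=cfg.test_frac,
            stratified=cfg.stratified,
            groups=image_set.groups if cfg.group_by_signal else None,
            seed=cfg.split_seed,
        )

        vocabularies: dict[str, Vocabulary] = {}
        selections: dict[str, np.ndarray] = {}
        chi2_results: dict[str, Chi2Result] = {}
        tables: dict[str, FeatureTable] = {}
        models: dict[tuple[str, str], FittedModel] = {}
        reports: dict[tuple[str, str], EvaluationReport] = {}

        for method in cfg.methods:
            t = time.perf_counter()
            dsets = extract_batch(image_set.images, cfg.extractor(method))
            timings[f"extract_{method}"] = time.perf_counter() - t
            if verbose:
                n_desc = sum(len(d) for d in dsets)
                print(f"[{method}] {len(dsets)} images, {n_desc} descriptors")

            t = time.perf_counter()
            vocab = build_vocabulary(
                [dsets[i] for i in train_idx],
                k=cfg.bow_k,
                seed=cfg.vocab_seed,
                max_train_descriptors=cfg.max_train_descriptors,
            )
            table = encode_table(
                dsets, vocab, image_set.labels, cfg.normalization, groups=image_set.groups
            )
            timings[f"bow_{method}"] = time.perf_counter() - t

            train_table = table.subset(train_idx)
            test_table = table.subset(test_idx)
            chi2_res = chi2_score(train_table)
            sel_train = select_top_k(chi2_res, train_table, cfg.k_select)
            keep = sel_train.selected_idx
            sel_test = replace(test_table, rows=test_table.rows[:, keep], selected_idx=keep)

            vocabularies[method] = vocab
            chi2_results[method] = chi2_res
            selections[method] = keep
            tables[method] = table

            for spec in cfg.classifier_specs():
                t = time.perf_counter()
                model = train(spec, sel_train)
                reports[(method, spec.kind)] = evaluate(
                    model, sel_test, positive_class=cfg.positive_class
                )
                models[(method, spec.kind)] = model
                timings[f"train_{method}_{spec.kind}"] = time.perf_counter() - t

        return ExperimentResults(
            model=self,
            config=cfg,
            reports=reports,
            models=models,
            vocabularies=vocabularies,
            selections=selections,
            chi2_results=chi2_results,
            tables=tables,
            train_idx=train_idx,
            test_idx=test_idx,
            image_labels=image_set.labels,
            image_groups=image_set.groups,
            timings=timings,
        )


@dataclass
class ExperimentResults:
    """Fitted artifacts and held-out evaluation of one experiment."""

    model: GasfBowExperiment
    config: PipelineConfig
    reports: dict[tuple[str, str], EvaluationReport]
    models: dict[tuple[str, str], FittedModel]
    vocabularies: dict[str, Vocabulary]
    selections: dict[str, np.ndarray]
    chi2_results: dict[str, Chi2Result]
    tables: dict[str, FeatureTable]
    train_idx: np.ndarray
    test_idx: np.ndarray
    image_labels: np.ndarray
    image_groups: np.ndarray
    timings: dict[str, float]

    # -- presentation --------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Metric table: one row per feature method x classifier."""
        rows = []
        for (method, kind), rep in sorted(self.reports.items()):
            rows.append(
                {
                    "features": method,
                    "classifier": kind,
                    **{k: round(v, 4) for k, v in rep.metrics.items()},
                }
            )
        return pd.DataFrame(rows)

    def plot_roc(self, method: str = "sift", ax=None):
        """ROC curves of all classifiers for one feature method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (m, kind), rep in sorted(self.reports.items()):
            if m != method:
                continue
            pts = np.asarray(rep.roc_points)
            ax.plot(pts[:, 0], pts[:, 1], label=f"{kind} (AUC={rep.metrics['auc']:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"ROC ({method.upper()} features)")
        ax.legend(loc="lower right")
        return ax

    def report_dict(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "n_train_images": int(self.train_idx.size),
            "n_test_images": int(self.test_idx.size),
            "reports": {
                f"{method}/{kind}": rep.to_dict()
                for (method, kind), rep in sorted(self.reports.items())
            },
            "selected_features": {m: idx.tolist() for m, idx in self.selections.items()},
            "vocab_hashes": {m: v.training_hash for m, v in self.vocabularies.items()},
        }

    # -- noise robustness ----------------------------------------------------
    def _frozen_hashes(self) -> dict:
        return {
            m: hashlib.sha256(v.centroids.tobytes()).hexdigest()
            for m, v in self.vocabularies.items()
        }

    def noise_sweep(
        self,
        snr_grid: Sequence[float] | None = None,
        n_per_class: int | None = None,
        unit: str | None = None,
        classifier: str | None = None,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Robustness of the frozen pipeline to additive Gaussian noise.

        For each SNR, ``n_per_class`` evaluation signals (or test epochs)
        per class are corrupted in the raw-signal domain, re-encoded
        through the frozen vocabulary and feature selection, and scored by
        the frozen classifier.  Nothing is refitted.  Returns a long-form
        table with per-method, per-class accuracy and F1 per SNR; the
        per-class rows treat that class as the positive label.
        """
        cfg = self.config
        snr_grid = tuple(cfg.noise_snr_grid if snr_grid is None else snr_grid)
        n_per_class = cfg.noise_n_per_class if n_per_class is None else n_per_class
        unit = cfg.noise_unit if unit is None else unit
        classifier = cfg.noise_classifier if classifier is None else classifier
        seed = cfg.noise_seed if seed is None else seed
        if unit not in ("signals", "epochs"):
            raise SweepError(f"unknown noise unit {unit!r}")
        for method in cfg.methods:
            if (method, classifier) not in self.models:
                raise SweepError(
                    f"no frozen {classifier!r} model for method {method!r}; run fit() first"
                )
        hashes_before = self._frozen_hashes()
        rng = np.random.default_rng(seed)

        signals = {s.id: s for s in self.model.signals}
        classes = sorted(set(self.image_labels))
        # choose the evaluation pool once, reused at every SNR
        if unit == "signals":
            # pool = signals with held-out epochs (the whole signal under a
            # grouped split; under an image-level split most signals qualify
            # and epochs of the same signal may also have been trained on)
            test_groups = self.image_groups[self.test_idx]
            test_labels = self.image_labels[self.test_idx]
            chosen: list[str] = []
            for c in classes:
                ids = sorted(set(test_groups[test_labels == c]))
                take = min(n_per_class, len(ids))
                chosen.extend(rng.choice(ids, size=take, replace=False))
            keep_epochs = None
        else:
            test_labels = self.image_labels[self.test_idx]
            picks = []
            for c in classes:
                pool = self.test_idx[test_labels == c]
                take = min(n_per_class, pool.size)
                picks.append(rng.choice(pool, size=take, replace=False))
            keep_epochs = np.sort(np.concatenate(picks))
            chosen = sorted(set(self.image_groups[keep_epochs]))
            epoch_keys = _epoch_keys(self.image_groups, keep_epochs)

        epoching = cfg.epoching()
        records = []
        for snr in snr_grid:
            noisy_signals = [
                add_noise(
                    signals[sid],
                    NoiseSpec(snr_db=snr, seed=int(rng.integers(0, 2**31))),
                )
                for sid in chosen
            ]
            image_set = _encode_dataset(noisy_signals, cfg)
            if keep_epochs is not None:
                # keep only the chosen (signal, epoch) rows of the noisy set
                sel = [
                    j
                    for j, img in enumerate(image_set.images)
                    if (img.source_id, img.epoch_index) in epoch_keys
                ]
                image_set = _ImageSet(
                    images=[image_set.images[j] for j in sel],
                    labels=image_set.labels[sel],
                    groups=image_set.groups[sel],
                )
            for method in cfg.methods:
                dsets = extract_batch(image_set.images, cfg.extractor(method))
                table = encode_table(
                    dsets, self.vocabularies[method], image_set.labels, cfg.normalization
                )
                keep = self.selections[method]
                reduced = replace(table, rows=table.rows[:, keep], selected_idx=keep)
                fitted = self.models[(method, classifier)]
                for positive in classes:
                    rep = evaluate(fitted, reduced, positive_class=positive)
                    records.append(
                        {
                            "method": method,
                            "class": positive,
                            "snr_db": snr,
                            "accuracy": rep.metrics["accuracy"],
                            "f1": rep.metrics["f1"],
                            "n_images": rep.n,
                        }
                    )
        if self._frozen_hashes() != hashes_before:
            raise SweepError("frozen-vocabulary contract violated during sweep")
        return pd.DataFrame(records)


def _epoch_keys(groups: np.ndarray, keep_epochs: np.ndarray) -> set[tuple[str, int]]:
    """(signal id, epoch index within signal) keys for chosen global rows."""
    keys = set()
    for i in keep_epochs:
        gid = groups[i]
        first = int(np.flatnonzero(groups == gid)[0])
        keys.add((str(gid), int(i - first)))
    return keys


@dataclass(frozen=True)
class RunManifest:
    """Record of one completed run: artifacts, timings, seeds, version."""

    config_hash: str
    outdir: str
    artifacts: dict
    timings: dict
    seed: int
    version: str = __version__

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def run_all(
    config: PipelineConfig, outdir: str | Path, verbose: bool = False
) -> tuple[RunManifest, ExperimentResults | None]:
    """Execute the full experiment and persist its artifacts.

    If a manifest with the same config hash already exists in ``outdir``
    and every listed artifact is present, the run is skipped and the
    cached manifest returned (with ``None`` results).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "run_manifest.json"
    chash = config.config_hash()
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash and all(
            (outdir / p).exists() for p in prev.get("artifacts", {}).values()
        ):
            return RunManifest(**{k: prev[k] for k in ("config_hash", "outdir", "artifacts", "timings", "seed", "version")}), None

    t0 = time.perf_counter()
    experiment = GasfBowExperiment.from_config(config)
    results = experiment.fit(verbose=verbose)
    artifacts: dict[str, str] = {}

    config.to_yaml(outdir / "config.yaml")
    artifacts["config"] = "config.yaml"
    write_manifest(experiment.signals, outdir / "signals", seed=config.seed)
    artifacts["signals_manifest"] = "signals/manifest.csv"

    for method, vocab in results.vocabularies.items():
        vocab.save(outdir)
        artifacts[f"vocab_{method}"] = f"vocab_{method}.csv"
        results.tables[method].to_csv(outdir / f"features_{method}.csv")
        artifacts[f"features_{method}"] = f"features_{method}.csv"

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(results.report_dict(), indent=2, sort_keys=True))
    artifacts["report"] = "report.json"
    results.summary().to_csv(outdir / "summary.csv", index=False)
    artifacts["summary"] = "summary.csv"

    import joblib

    for (method, kind), fitted in results.models.items():
        name = f"model_{method}_{kind}.joblib"
        joblib.dump(fitted, outdir / name)
        (outdir / f"model_{method}_{kind}.json").write_text(
            json.dumps(
                {
                    "spec": _spec_to_dict(fitted.spec),
                    "vocab_hash": results.vocabularies[method].training_hash,
                    "selected_features": results.selections[method].tolist(),
                },
                indent=2,
            )
        )
        artifacts[f"model_{method}_{kind}"] = name

    timings = dict(results.timings)
    timings["total"] = time.perf_counter() - t0
    manifest = RunManifest(
        config_hash=chash,
        outdir=str(outdir),
        artifacts=artifacts,
        timings=timings,
        seed=config.seed,
    )
    manifest.to_json(manifest_path)
    return manifest, results


def run_noise_sweep(
    results: ExperimentResults, outdir: str | Path | None = None, **kwargs
) -> pd.DataFrame:
    """Run the noise sweep off fitted results; optionally persist CSV/JSON."""
    sweep = results.noise_sweep(**kwargs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sweep.to_csv(outdir / "noise_sweep.csv", index=False)
        wide = sweep.pivot_table(
            index=["method", "class"], columns="snr_db", values=["accuracy", "f1"]
        )
        wide.to_csv(outdir / "noise_sweep_wide.csv")
    return sweep
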