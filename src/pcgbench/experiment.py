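"""Experiment orchestration: all augmentation arms under one shared fold plan.

The runner builds (or loads) the dataset, conditions it, renders the baseline
Mel-spectrogram images once, creates a single stratified fold plan, and then
evaluates every arm against it: augmentation is applied to training folds
only, in one-to-one correspondence (N -> 2N); audio-level arms re-render
spectrograms from the augmented audio, spectrogram-level arms mask the cached
dB matrices, and image-level arms transform the cached images. Test folds are
never augmented. Every random draw is traceable to the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pcgbench import augment as aug
from pcgbench import evaluate as ev
from pcgbench.cnn import ModelSpec, TrainedModel, train
from pcgbench.preprocess import PreprocessConfig, normalize_amplitude, preprocess_recordings
from pcgbench.spectral import SpectrogramParams, mel_spectrogram, render_image
from pcgbench.synthetic import AudioRecording, PcgConfig, generate_recordings, load_manifest
from pcgbench.preprocess import preprocess_pipeline

logger = logging.getLogger(__name__)

#: arm id -> augmentation method (None = unaugmented baseline)
ARM_METHODS = {
    "0": None,
    "1": "pitch_time",
    "2": "noise",
    "3.1": "hflip",
    "3.2": "vflip",
    "4.1": "sv",
    "4.2": "pca",
    "4.3": "color_filter",
    "5": "mask",
    "6": "hflip_pca",
    "7": "hflip_sv",
}
DEFAULT_ARMS = tuple(ARM_METHODS)


@dataclass
class ExperimentConfig:
    """Everything a run needs; serializable to/from a plain dict (YAML/JSON)."""

    n_normal: int = 318
    n_abnormal: int = 82  # ~3.9:1 imbalance at 400 recordings
    wav_manifest: str | None = None  # optional: CSV manifest of real WAV files
    pcg: PcgConfig = field(default_factory=PcgConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectrogramParams = field(default_factory=SpectrogramParams)
    model: ModelSpec = field(default_factory=ModelSpec)
    k: int = 5
    arms: tuple = DEFAULT_ARMS
    seed: int = 0
    out_dir: str | None = None
    make_plots: bool = False

    def validate(self) -> None:
        self.pcg.validate()
        self.preprocess.validate()
        self.spectral.validate()
        unknown = [a for a in self.arms if a not in ARM_METHODS]
        if unknown:
            raise ValueError(f"unknown arms {unknown}")
        if self.k < 2:
            raise ValueError("k must be at least 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arms"] = list(self.arms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (
            ("pcg", PcgConfig),
            ("preprocess", PreprocessConfig),
            ("spectral", SpectrogramParams),
            ("model", ModelSpec),
        ):
            if key in d and isinstance(d[key], dict):
                kw = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = sub(**kw)
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        return cls(**d)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    fold_plan: ev.FoldPlan
    arms: dict  # arm id -> ev.ArmResult
    comparisons: dict  # arm id -> per-metric paired CI dicts
    class_counts: dict

    def report(self) -> dict:
        """Machine-readable twin of the summary tables."""
        out = {
            "config": self.config.to_dict(),
            "fold_plan_hash": self.fold_plan.plan_hash(),
            "k": self.fold_plan.k,
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
            "arms": {},
        }
        for arm_id, res in self.arms.items():
            out["arms"][arm_id] = {
                "method": ARM_METHODS[arm_id],
                "per_fold": res.per_fold,
                "summary": res.summary(),
                "fold_plan_hash": res.fold_plan_hash,
                "model_hash": res.model_hash,
                "comparison_to_baseline": self.comparisons.get(arm_id),
            }
        return out


def _fold_seed(master: int, arm_id: str, fold: int, salt: int = 0) -> int:
    tag = int.from_bytes(arm_id.encode()[:4].ljust(4, b"\0"), "little")
    return int(
        np.random.SeedSequence((int(master), tag, int(fold), salt)).generate_state(1)[0]
        % (2**31 - 1)
    )


def _load_dataset(cfg: ExperimentConfig) -> list[AudioRecording]:
    if cfg.wav_manifest:
        manifest = load_manifest(cfg.wav_manifest)
        recs, _ = preprocess_pipeline(manifest, cfg.preprocess)
        return recs
    raw = generate_recordings(cfg.n_normal, cfg.n_abnormal, cfg.pcg, cfg.seed)
    return preprocess_recordings(raw, cfg.preprocess)


def _training_images(
    arm_id: str,
    method: str | None,
    train_recs: list[AudioRecording],
    mels: dict,
    images: dict,
    cfg: ExperimentConfig,
    fold_idx: int,
):
    """Assemble the fold's training images, applying the arm's augmentation."""
    train_ids = [r.record_id for r in train_recs]
    base = lambda rid: images[rid].pixels  # noqa: E731
    if method is None:
        x = np.stack([base(r.record_id) for r in train_recs])
        y = np.array([r.label for r in train_recs])
        return x, y
    level = aug.method_level(method)
    if level == "audio":
        items = [aug.TrainingItem(r.record_id, r.label, r) for r in train_recs]
    elif level == "mel":
        items = [aug.TrainingItem(r.record_id, r.label, mels[r.record_id]) for r in train_recs]
    else:
        items = [aug.TrainingItem(r.record_id, r.label, images[r.record_id]) for r in train_recs]
    doubled = aug.augment_training_set(items, method, _fold_seed(cfg.seed, arm_id, fold_idx, 1))
    if len(doubled) != 2 * len(items):
        raise RuntimeError("augmentation did not double the training set")
    allowed = set(train_ids)
    for item in doubled:
        if item.source_id is not None and item.source_id not in allowed:
            raise RuntimeError("leakage: augmented item sourced outside the training fold")
    pixels, labels = [], []
    for item in doubled:
        if item.source_id is None:
            pixels.append(base(item.record_id))
        elif level == "audio":
            rec = normalize_amplitude(item.payload)
            img = render_image(
                mel_spectrogram(rec, cfg.spectral), cfg.spectral.colormap, rec.record_id
            )
            pixels.append(img.pixels)
        elif level == "mel":
            pixels.append(
                render_image(item.payload, cfg.spectral.colormap, item.record_id).pixels
            )
        else:
            pixels.append(item.payload.pixels)
        labels.append(item.label)
    return np.stack(pixels), np.array(labels)


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every configured arm under one shared stratified fold plan."""
    cfg.validate()
    recs = _load_dataset(cfg)
    if not recs:
        raise ValueError("no recordings survive preprocessing")
    by_id = {r.record_id: r for r in recs}
    labels = {r.record_id: r.label for r in recs}
    counts = {0: sum(1 for r in recs if r.label == 0), 1: sum(1 for r in recs if r.label == 1)}
    logger.info("dataset: %d recordings (normal=%d abnormal=%d)", len(recs), counts[0], counts[1])

    mels = {r.record_id: mel_spectrogram(r, cfg.spectral) for r in recs}
    images = {
        rid: render_image(mel, cfg.spectral.colormap, rid) for rid, mel in mels.items()
    }

    plan = ev.stratified_folds(
        [r.record_id for r in recs], [r.label for r in recs], cfg.k, cfg.seed
    )
    plan_hash = plan.plan_hash()
    model_hash = cfg.model.architecture_hash()

    arm_results: dict[str, ev.ArmResult] = {}
    for arm_id in cfg.arms:
        method = ARM_METHODS[arm_id]
        res = ev.ArmResult(arm=arm_id, fold_plan_hash=plan_hash, model_hash=model_hash)
        for fold_idx, (train_ids, test_ids) in enumerate(plan.folds):
            train_recs = [by_id[rid] for rid in train_ids]
            x_train, y_train = _training_images(
                arm_id, method, train_recs, mels, images, cfg, fold_idx
            )
            model: TrainedModel = train(
                cfg.model, x_train, y_train, seed=_fold_seed(cfg.seed, arm_id, fold_idx)
            )
            x_test = np.stack([images[rid].pixels for rid in test_ids])
            y_test = np.array([labels[rid] for rid in test_ids])
            scores = model.predict_scores(x_test)
            fold = ev.fold_metrics(scores, y_test)
            fold["n_train"] = int(len(y_train))
            fold["n_test"] = int(len(y_test))
            res.per_fold.append(fold)
            res.fold_scores.append((scores, y_test))
            logger.info(
                "arm %s fold %d: roc_auc=%.3f pr_auc=%.3f (n_train=%d)",
                arm_id, fold_idx, res.per_fold[-1]["roc_auc"], res.per_fold[-1]["pr_auc"],
                len(y_train),
            )
        arm_results[arm_id] = res

    comparisons = {}
    if "0" in arm_results:
        for arm_id, res in arm_results.items():
            if arm_id != "0":
                comparisons[arm_id] = ev.compare_to_baseline(res, arm_results["0"])

    result = ExperimentResult(cfg, plan, arm_results, comparisons, counts)
    if cfg.out_dir:
        write_report(result, cfg.out_dir)
    return result


def write_report(result: ExperimentResult, out_dir: str | Path) -> dict:
    """Write the JSON report and the two CSV summary tables (plus curves)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = result.report()
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)

    rows1, rows2 = [], []
    for arm_id, arm in report["arms"].items():
        s = arm["summary"]
        cmp_ = arm["comparison_to_baseline"] or {}

        def ci_str(metric):
            m = s[metric]
            return f"{m['mean']:.3f} [{m['ci'][0]:.3f}, {m['ci'][1]:.3f}]"

        def diff_str(metric):
            if metric not in cmp_:
                return ""
            d = cmp_[metric]
            return f"{d['mean_difference']:.3f} [{d['ci'][0]:.3f}, {d['ci'][1]:.3f}]"

        rows1.append(
            {
                "model": arm_id,
                "method": arm["method"] or "baseline",
                "accuracy": ci_str("accuracy"),
                "sensitivity": ci_str("sensitivity"),
                "specificity_at_90sens": ci_str("specificity_at_90sens"),
                "roc_auc": ci_str("roc_auc"),
                "roc_auc_diff_from_baseline": diff_str("roc_auc"),
            }
        )
        rows2.append(
            {
                "model": arm_id,
                "method": arm["method"] or "baseline",
                "f1": ci_str("f1"),
                "f1_diff_from_baseline": diff_str("f1"),
                "pr_auc": ci_str("pr_auc"),
                "pr_auc_diff_from_baseline": diff_str("pr_auc"),
            }
        )
    pd.DataFrame(rows1).to_csv(out_dir / "table1_roc.csv", index=False)
    pd.DataFrame(rows2).to_csv(out_dir / "table2_pr.csv", index=False)

    if result.config.make_plots:
        _write_curves(result, out_dir)
    return report


def _write_curves(result: ExperimentResult, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for arm_id, res in result.arms.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        aucs = res.metric_values("roc_auc")
        prs = res.metric_values("pr_auc")
        for fold_idx, (scores, y) in enumerate(res.fold_scores):
            curves = ev.roc_pr_curves(scores, y)
            axes[0].plot(*curves["roc"], alpha=0.7, label=f"fold {fold_idx}")
            axes[1].plot(*curves["pr"], alpha=0.7, label=f"fold {fold_idx}")
        axes[0].plot([0, 1], [0, 1], "r--", label="no discrimination")
        axes[0].set(title=f"Model {arm_id} ROC (mean AUC {np.mean(aucs):.3f})",
                    xlabel="1 - specificity", ylabel="sensitivity")
        axes[1].set(title=f"Model {arm_id} PR (mean AUC {np.mean(prs):.3f})",
                    xlabel="recall", ylabel="precision")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"curves_model_{arm_id.replace('.', '_')}.png", dpi=100)
        plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
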