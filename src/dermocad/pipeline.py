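"""Two-arm experiment orchestration.

Arm ``raw`` trains and evaluates the classifier on resized raw images; arm
``preprocessed`` first runs every image through hair removal, contrast
enhancement, lesion segmentation and ROI cropping, then trains and
evaluates the identical classifier with identical seeds and
hyperparameters.  Comparing the two arms isolates the contribution of the
preprocessing stages.

Desk-scale defaults (64x64 classifier input, compact segmentation widths,
few epochs) are chosen so a full two-arm run takes tens of seconds on one
CPU; see docs/methods.md.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as cls
from . import contrast, hair_removal, segmentation, synthetic
from .dataset_ops import random_oversample, stratified_split
from .metrics import MetricReport, confusion_from_labels, roc_auc
from .synthetic import MEL

logger = logging.getLogger("dermocad.pipeline")


@dataclass
class ExperimentData:
    """A synthetic hairy/degraded study dataset.

    ``images`` hold the observed (degraded, hair-occluded) frames;
    ``masks`` the ground-truth lesion masks (available to train the
    segmentation stage); ``clean`` the pristine renders, kept only for
    external analysis, never shown to either arm.
    """

    images: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    index: pd.DataFrame
    clean: dict[str, np.ndarray] = field(default_factory=dict)


def make_experiment_dataset(n_mel: int = 30, n_ben: int = 30, seed: int = 0,
                            image_size: tuple[int, int] = (64, 64),
                            n_hairs: int = 12) -> ExperimentData:
    """Generate the hairy, contrast-degraded two-class study dataset."""
    clean, index, masks = synthetic.generate_dataset(
        n_mel, n_ben, dup_fraction=0.0, seed=seed, image_size=image_size)
    rng = np.random.default_rng(seed + 1)
    observed: dict[str, np.ndarray] = {}
    for path, img in clean.items():
        gamma = rng.uniform(*synthetic.DEGRADE_GAMMA)
        gain = rng.uniform(*synthetic.DEGRADE_GAIN)
        degraded = synthetic.degrade_contrast(img, gamma, gain)
        hspec = synthetic.HairOverlaySpec(
            n_hairs=n_hairs, seed=int(rng.integers(0, 2 ** 31 - 1)))
        observed[path], _ = synthetic.add_hairs(degraded, hspec)
    index = stratified_split(index, seed=seed)
    return ExperimentData(images=observed, masks=masks, index=index, clean=clean)


@dataclass(frozen=True)
class ExperimentConfig:
    arm: str = "raw"
    seed: int = 0
    classifier_input: tuple[int, int, int] = (64, 64, 3)
    ndcnn_epochs: int = 10
    ndcnn_batch_size: int = 16
    mcan_epochs: int = 8
    mcan_patch: int = 32
    acnn_epochs: int = 6
    acnn_channels: tuple[int, ...] = (8, 16, 16, 24, 24)
    roi_margin: int = 2
    out_dir: str | None = None

    def __post_init__(self):
        if self.arm not in ("raw", "preprocessed"):
            raise ValueError("arm must be 'raw' or 'preprocessed'")


@dataclass
class ArmResult:
    arm: str
    report: MetricReport
    predictions: pd.DataFrame
    stage_calls: dict[str, int]
    train_history: list[float]


def _split_paths(index: pd.DataFrame, split: str) -> list[str]:
    return index.loc[index["split"] == split, "path"].tolist()


def _preprocess_all(cfg: ExperimentConfig, data: ExperimentData,
                    stage_calls: dict[str, int]) -> dict[str, np.ndarray]:
    """Dehair -> enhance -> segment -> crop for every image in the index."""
    paths = data.index["path"].tolist()
    train_paths = _split_paths(data.index, "train")

    dehaired: dict[str, np.ndarray] = {}
    for p in paths:
        dehaired[p], _ = hair_removal.remove_hairlines(data.images[p])
        stage_calls["hair_removal"] += 1

    # contrast model: self-supervised on further-degraded training patches
    mcan = contrast.build_mcan(
        contrast.MCANSpec(patch_size=cfg.mcan_patch), seed=cfg.seed)

    def sampler(im: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return synthetic.degrade_contrast(
            im, rng.uniform(*synthetic.DEGRADE_GAMMA),
            rng.uniform(*synthetic.DEGRADE_GAIN))

    def center_patch(im: np.ndarray, size: int) -> np.ndarray:
        h, w = im.shape[:2]
        r0, c0 = max(0, (h - size) // 2), max(0, (w - size) // 2)
        return im[r0:r0 + size, c0:c0 + size]

    train_patches = [center_patch(dehaired[p], cfg.mcan_patch) for p in train_paths]
    contrast.train_mcan(mcan, train_patches, sampler, epochs=cfg.mcan_epochs,
                        seed=cfg.seed)
    enhanced = {}
    for p in paths:
        enhanced[p] = contrast.enhance(mcan, dehaired[p])
        stage_calls["enhance"] += 1

    # segmentation stage trained on the training split's ground-truth masks
    h, w = next(iter(data.images.values())).shape[:2]
    acnn_spec = segmentation.ACNNSpec(input_shape=(h, w, 3),
                                      channels=cfg.acnn_channels)
    acnn = segmentation.build_acnn(acnn_spec, seed=cfg.seed)
    seg_cfg = segmentation.ACNNTrainConfig(epochs=cfg.acnn_epochs, batch_size=4)
    segmentation.train_acnn(acnn,
                            [enhanced[p] for p in train_paths],
                            [data.masks[p].astype(np.uint8) for p in train_paths],
                            seg_cfg, seed=cfg.seed)

    out: dict[str, np.ndarray] = {}
    for p in paths:
        mask = segmentation.segment(acnn, enhanced[p])
        stage_calls["segment"] += 1
        if not mask.any():
            logger.warning("empty segmentation mask for %s; using full frame", p)
            out[p] = enhanced[p]
        else:
            out[p] = segmentation.crop_roi(enhanced[p], mask, margin=cfg.roi_margin)
        stage_calls["crop_roi"] += 1
    return out


def run_arm(cfg: ExperimentConfig, data: ExperimentData) -> ArmResult:
    """Train and evaluate one arm; returns the metric report and artifacts."""
    splits = set(data.index.get("split", pd.Series(dtype=str)).unique())
    if not {"train", "test"} <= splits:
        raise ValueError("index must carry train/val/test split assignments")
    stage_calls = {"hair_removal": 0, "enhance": 0, "segment": 0, "crop_roi": 0}

    if cfg.arm == "preprocessed":
        working = _preprocess_all(cfg, data, stage_calls)
    else:
        working = data.images

    train_idx = data.index[data.index["split"] == "train"].reset_index(drop=True)
    train_idx = random_oversample(train_idx, seed=cfg.seed)
    train_imgs = [working[p] for p in train_idx["path"]]
    train_labels = train_idx["label"].tolist()

    spec = cls.NDCNNSpec(input_shape=cfg.classifier_input)
    model = cls.build_ndcnn(spec, seed=cfg.seed)
    train_cfg = cls.NDCNNTrainConfig(epochs=cfg.ndcnn_epochs,
                                     batch_size=cfg.ndcnn_batch_size)
    history = cls.train_ndcnn(model, train_imgs, train_labels, train_cfg,
                              seed=cfg.seed)

    test_paths = _split_paths(data.index, "test")
    truth = data.index.set_index("path").loc[test_paths, "label"].tolist()
    p_mel, pred_labels = cls.predict_batch(model, [working[p] for p in test_paths])
    counts = confusion_from_labels(truth, pred_labels, positive=MEL)
    auc = None
    if len(set(truth)) == 2:
        auc = roc_auc(p_mel, truth, positive=MEL)
    report = MetricReport.from_confusion(counts, auc=auc)
    predictions = pd.DataFrame({
        "path": test_paths, "p_mel": p_mel,
        "p_ben": 1.0 - np.asarray(p_mel), "label": pred_labels, "truth": truth})
    result = ArmResult(cfg.arm, report, predictions, stage_calls, history)
    if cfg.out_dir:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: ExperimentConfig, result: ArmResult) -> None:
    out = Path(cfg.out_dir) / cfg.arm
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(result.report.as_dict(), indent=2))
    result.predictions.to_csv(out / "predictions.csv", index=False)
    logger.info("arm %s: metrics written to %s", cfg.arm, out)


def compare_arms(report_raw: MetricReport, report_pre: MetricReport) -> pd.DataFrame:
    """Side-by-side metric deltas (preprocessed minus raw)."""
    if report_raw.counts.total != report_pre.counts.total:
        raise ValueError("reports come from different test sets")
    rows = []
    for m in ("acc", "pre", "rec", "spe", "f1"):
        a, b = getattr(report_raw, m), getattr(report_pre, m)
        rows.append({"metric": m, "raw": a, "preprocessed": b,
                     "delta": round(b - a, 2)})
    return pd.DataFrame(rows, columns=["metric", "raw", "preprocessed", "delta"])


def run_two_arm_experiment(seed: int = 0, n_mel: int = 30, n_ben: int = 30,
                           out_dir: str | None = None
                           ) -> tuple[ArmResult, ArmResult, pd.DataFrame]:
    """Full comparison on one seeded dataset: raw arm vs preprocessed arm."""
    data = make_experiment_dataset(n_mel=n_mel, n_ben=n_ben, seed=seed)
    raw = run_arm(ExperimentConfig(arm="raw", seed=seed, out_dir=out_dir), data)
    pre = run_arm(ExperimentConfig(arm="preprocessed", seed=seed, out_dir=out_dir), data)
    return raw, pre, compare_arms(raw.report, pre.report)
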