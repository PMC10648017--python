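"""End-to-end orchestration: label → tile → split → train → evaluate.

One master seed drives every stochastic stage through documented derived
seeds (master + fixed per-stage offsets), so any stage can be rerun
independently and an identical config + seed reproduces the whole report.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import dataset_builder, gmm_labeler, imagery_io, synthetic_scene, unet_family
from .gmm_labeler import BinaryMask, MergeRule
from .imagery_io import MultiBandImage
from .synthetic_scene import SceneSpec
from .unet_family import TrainConfig, UNetSpec

# fixed per-stage seed offsets (kept < 2**31 after derivation)
_STAGE_OFFSETS = {"scenes": 101, "gmm": 211, "split": 307, "train": 401}


def stage_seed(master: int, stage: str) -> int:
    return (int(master) + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on synthetic scenes."""

    n_images: int = 10
    scene_size: int = 160
    k_min: int = 2
    k_max: int = 8
    criterion: str = "BIC"
    merge_components: Optional[Sequence[int]] = None  # None → automatic rule
    # 3×3 = the compact "9-pixel" square kernel; proportionate for the
    # default desk-scale scene sizes (full-size 4,000 px rasters use 9×9)
    median_size: int = 3
    closing_size: int = 3
    top_n: int = 4
    tile: int = 32
    n_test: int = 0
    val_fraction: float = 0.10
    scenario: int = 6
    epochs: int = 2
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_fit_pixels: int = 200_000
    gmm_max_iter: int = 100
    output_dir: Optional[str] = None
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    scan_rows: List[Tuple[int, float, int, float, float]]
    selected_k: int
    merge_rule: List[int]
    ranking: List[Tuple[str, float]]
    selected_ids: List[str]
    n_tiles: int
    split_counts: Dict[str, int]
    label_agreement: float
    ledger_totals: Dict[str, int]
    eval_result: Optional[Dict[str, float]] = None
    history: Optional[List[Dict[str, float]]] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


def make_scenes(config: RunConfig) -> List[Tuple[str, MultiBandImage,
                                                 synthetic_scene.GroundTruth]]:
    """Generate the run's seeded synthetic scenes."""
    base = stage_seed(config.seed, "scenes")
    scenes = []
    for i in range(config.n_images):
        spec = synthetic_scene.default_spec(config.scene_size, seed=base + i)
        image, truth = synthetic_scene.generate_scene(spec)
        scenes.append((f"scene{i:03d}", image, truth))
    return scenes


def label_images(
    scenes: Sequence[Tuple[str, MultiBandImage, synthetic_scene.GroundTruth]],
    config: RunConfig,
) -> Tuple[gmm_labeler.CriterionScan, int, MergeRule,
           List[Tuple[str, MultiBandImage, BinaryMask]], float]:
    """Scan → select K → predict → merge → filter over all images.

    The mixture is fitted once, on the first image (the training image
    convention); its centers predict clusters for every image.  Returns the
    scan, selected K, merge rule, labeled images, and mean pixel agreement
    with ground truth.
    """
    gmm_seed = stage_seed(config.seed, "gmm")
    first_image = scenes[0][1]
    scan = gmm_labeler.scan_k(
        first_image, k_min=config.k_min, k_max=config.k_max, seed=gmm_seed,
        max_fit_pixels=config.max_fit_pixels, max_iter=config.gmm_max_iter,
    )
    k = gmm_labeler.select_k_elbow(scan, criterion=config.criterion)
    model = scan.model_for(k)
    labeled: List[Tuple[str, MultiBandImage, BinaryMask]] = []
    agreements = []
    rule: Optional[MergeRule] = None
    for name, image, truth in scenes:
        cmap = gmm_labeler.predict_clusters(model, image)
        if config.merge_components is not None:
            rule = MergeRule(set(config.merge_components), rationale="manual")
        elif rule is None:
            rule = gmm_labeler.auto_merge_rule(model, cmap)
        mask = gmm_labeler.apply_merge(cmap, rule)
        mask = gmm_labeler.postprocess_mask(mask, config.median_size,
                                            config.closing_size)
        labeled.append((name, image, mask))
        agreements.append(float(np.mean(mask.mask == truth.mask)))
    return scan, k, rule, labeled, float(np.mean(agreements))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the whole workflow and return the consolidated report."""
    scenes = make_scenes(config)
    scan, k, rule, labeled, agreement = label_images(scenes, config)
    ranking = gmm_labeler.rank_and_select(labeled, top_n=config.top_n)
    chosen = [(name, img, mask) for name, img, mask in labeled
              if name in set(ranking.selected)]
    samples = dataset_builder.build_dataset(chosen, tile=config.tile)
    n_test = config.n_test if config.n_test < len(samples) else 0
    split = dataset_builder.split_dataset(
        samples, n_test=n_test, val_fraction=config.val_fraction,
        seed=stage_seed(config.seed, "split"))
    spec = unet_family.make_spec(scenario=config.scenario)
    ledger = unet_family.count_parameters(spec)
    train_seed = stage_seed(config.seed, "train")
    model = unet_family.build_model(spec, seed=train_seed)
    tconfig = TrainConfig(learning_rate=config.learning_rate,
                          batch_size=config.batch_size,
                          epochs=config.epochs, seed=train_seed)
    history = unet_family.train(model, split, tconfig)
    eval_samples = split.test if split.test else split.train
    result = unet_family.evaluate(model, eval_samples)
    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        scan_rows=scan.rows,
        selected_k=k,
        merge_rule=sorted(rule.forest_components),
        ranking=ranking.entries,
        selected_ids=ranking.selected,
        n_tiles=len(samples),
        split_counts={"train": len(split.train),
                      "validation": len(split.validation),
                      "test": len(split.test)},
        label_agreement=agreement,
        ledger_totals={"kernels": unet_family.count_kernels(spec),
                       "parameters": ledger.total_parameters},
        eval_result=asdict(result),
        history=history.epochs,
    )
    if config.output_dir:
        _persist(config, report, ranking, split, model)
    return report


def _persist(config: RunConfig, report: RunReport,
             ranking: gmm_labeler.DbRanking,
             split: dataset_builder.DatasetSplit,
             model: unet_family.UNet) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        fh.write(report.to_json())
    with open(os.path.join(out, "ranking.csv"), "w") as fh:
        fh.write(ranking.to_csv())
    with open(os.path.join(out, "manifest.csv"), "w") as fh:
        fh.write(split.manifest_csv())
    model.save(os.path.join(out, "model.npz"))


def lr_sweep(config: RunConfig,
             rates: Sequence[float] = (1e-2, 1e-3, 1e-4, 1e-5)
             ) -> Dict[float, unet_family.TrainingHistory]:
    """Train one model per learning rate on shared data and seed.

    Divergence at a rate is recorded as an empty history; the sweep
    continues with the remaining rates.
    """
    scenes = make_scenes(config)
    _, _, _, labeled, _ = label_images(scenes, config)
    samples = dataset_builder.build_dataset(labeled, tile=config.tile)
    split = dataset_builder.split_dataset(
        samples, n_test=0, val_fraction=config.val_fraction,
        seed=stage_seed(config.seed, "split"))
    spec = unet_family.make_spec(scenario=config.scenario)
    train_seed = stage_seed(config.seed, "train")
    histories: Dict[float, unet_family.TrainingHistory] = {}
    for rate in rates:
        model = unet_family.build_model(spec, seed=train_seed)
        tconfig = TrainConfig(learning_rate=rate, batch_size=config.batch_size,
                              epochs=config.epochs, seed=train_seed)
        try:
            histories[rate] = unet_family.train(model, split, tconfig)
        except unet_family.DivergenceError:
            histories[rate] = unet_family.TrainingHistory()
    return histories


def sweep_table(histories: Dict[float, unet_family.TrainingHistory]) -> str:
    lines = ["learning_rate,final_train_accuracy,final_val_accuracy"]
    for rate in histories:
        h = histories[rate].epochs
        if h:
            last = h[-1]
            va = last.get("val_accuracy")
            lines.append(f"{rate:g},{last['train_accuracy']:.6f},"
                         f"{'' if va is None else f'{va:.6f}'}")
        else:
            lines.append(f"{rate:g},diverged,diverged")
    return "\n".join(lines) + "\n"


def scenario_report(config: RunConfig,
                    scenarios: Sequence[int] = (1, 2, 3, 4, 5, 6),
                    train_models: bool = True) -> List[Dict[str, object]]:
    """Per-scenario table: ledger totals and (optionally) trained accuracy.

    Kernel and parameter columns come from the analytic ledgers, never from
    measurement; accuracy/F1 columns come from training each scenario on
    the run's shared labeled dataset.
    """
    rows: List[Dict[str, object]] = []
    shared = None
    if train_models and scenarios:
        scenes = make_scenes(config)
        _, _, _, labeled, _ = label_images(scenes, config)
        samples = dataset_builder.build_dataset(labeled, tile=config.tile)
        n_test = config.n_test if config.n_test < len(samples) else 0
        shared = dataset_builder.split_dataset(
            samples, n_test=n_test, val_fraction=config.val_fraction,
            seed=stage_seed(config.seed, "split"))
    for s in scenarios:
        spec = unet_family.make_spec(scenario=s)
        row: Dict[str, object] = {
            "scenario": s,
            "total_kernels": unet_family.count_kernels(spec),
            "trainable_parameters": unet_family.count_parameters(spec).total_parameters,
        }
        if shared is not None:
            train_seed = stage_seed(config.seed, "train")
            model = unet_family.build_model(spec, seed=train_seed)
            tconfig = TrainConfig(learning_rate=config.learning_rate,
                                  batch_size=config.batch_size,
                                  epochs=config.epochs, seed=train_seed)
            unet_family.train(model, shared, tconfig)
            result = unet_family.evaluate(
                model, shared.test if shared.test else shared.train)
            row["test_accuracy"] = result.pixel_accuracy
            row["f1_score"] = result.f1_score
        rows.append(row)
    return rows


def scenario_table_csv(rows: Sequence[Dict[str, object]]) -> str:
    if not rows:
        return "scenario,total_kernels,trainable_parameters\n"
    cols = list(rows[0].keys())
    lines = [",".join(cols)]
    for row in rows:
        lines.append(",".join(str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"
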