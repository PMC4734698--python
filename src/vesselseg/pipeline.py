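"""End-to-end orchestration: presegmentation, candidate extraction,
classification, training on labeled scenes, and the synthetic benchmark.

The segmentation path for one image is: Gabor feature extraction ->
k-means foreground mask -> two-pass component labeling -> small-structure
filtering -> six-feature extraction -> forest classification. Training for
the benchmark mirrors the deployment condition: trees learn from
presegmentation-produced candidate structures whose labels come from
IoU-matching against the generator's ground truth, so the classifier sees
the same population of noisy candidates at train and test time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation, forest, preseg, structures, synthesis
from .config import default_config
from .gabor import GaborBankConfig, extract_pixel_features
from .io import BinaryMask, IHCImage, LabelMap
from .structures import StructureRecord, feature_vector
from .synthesis import SceneParams, SyntheticScene, TRUTH_MICROVESSEL

logger = logging.getLogger("vesselseg")


@dataclass(frozen=True)
class SegmentationResult:
    mask: BinaryMask
    labelmap: LabelMap
    records: list[StructureRecord]
    classes: list[str] | None  # None when no model was applied


def _bank_config(cfg: dict) -> GaborBankConfig:
    g = cfg["gabor"]
    return GaborBankConfig(
        f0=g["f0"], ratio=g["ratio"], n_freqs=g["n_freqs"], n_orients=g["n_orients"],
        gamma=g["gamma"], eta=g["eta"], phi=g["phi"], sigma_coeff=g["sigma_coeff"],
        truncate=g["truncate"], smooth_factor=g["smooth_factor"],
    )


def presegment(image: IHCImage, cfg: dict | None = None) -> SegmentationResult:
    """Run the candidate-isolation stage (no classification)."""
    cfg = cfg or default_config()
    feats = extract_pixel_features(image, _bank_config(cfg))
    h, w = image.pixels.shape
    if not feats.values.any():
        # textureless (e.g. constant) image: nothing to segment
        empty = LabelMap(labels=np.zeros((h, w), dtype=np.int32), n_structures=0)
        return SegmentationResult(
            mask=BinaryMask(np.zeros((h, w), dtype=bool)),
            labelmap=empty, records=[], classes=None,
        )
    kcfg = cfg["kmeans"]
    m = cfg["mask"]
    pts = feats.as_points()
    if kcfg["log_compress"]:
        # log-compress response magnitudes so strongly responding clutter
        # cannot dominate the squared-error metric over weaker vessels
        scale = pts.mean()
        pts = np.log1p(pts / (0.1 * scale)) if scale > 0 else pts
    od = preseg.stain_od(image, background_window_px=m["background_window_px"])
    gate = od > m["od_threshold"]
    init = None
    if kcfg["init"] == "stain-supervised" and gate.any() and not gate.all():
        init = preseg.supervised_init(pts, gate, standardize=kcfg["standardize"])
    km = preseg.fit_kmeans(
        pts,
        k=kcfg["k"],
        init=init,
        seed=kcfg["seed"],
        max_iter=kcfg["max_iter"],
        standardize=kcfg["standardize"],
    )
    mask = preseg.select_foreground(km, feats)
    mask = preseg.refine_mask(
        mask, image,
        od_threshold=m["od_threshold"],
        strong_od_threshold=m["strong_od_threshold"],
        background_window_px=m["background_window_px"],
        fill_holes=m["fill_holes"],
        od=od,
    )
    labelmap = structures.label_components(mask)
    labelmap = structures.filter_small(labelmap, cfg["structures"]["min_area_px"])
    records = structures.extract_structure_features(labelmap, image)
    return SegmentationResult(mask=mask, labelmap=labelmap, records=records, classes=None)


def segment_image(
    image: IHCImage, model: forest.ForestModel, cfg: dict | None = None
) -> SegmentationResult:
    """Full pipeline: presegment, then classify every candidate structure."""
    res = presegment(image, cfg)
    X = [feature_vector(r) for r in res.records]
    classes = [forest.predict(model, x) for x in X]
    return SegmentationResult(
        mask=res.mask, labelmap=res.labelmap, records=res.records, classes=classes
    )


def candidate_training_records(
    scenes: list[SyntheticScene], cfg: dict | None = None
) -> tuple[np.ndarray, list[str]]:
    """Extract (features, labels) from presegmented candidates of truth scenes.

    Each candidate is labeled 'M' when it IoU-matches a truth microvessel at
    the evaluation threshold, 'N' otherwise (distractors and background
    clutter alike).
    """
    cfg = cfg or default_config()
    thr = cfg["evaluation"]["iou_threshold"]
    X: list[np.ndarray] = []
    y: list[str] = []
    for scene in scenes:
        res = presegment(scene.image, cfg)
        if not res.records:
            continue
        matched = evaluation.greedy_iou_matching(res.labelmap, scene.truth_labelmap, thr)
        for rec in res.records:
            tid = matched.get(rec.structure_id)
            is_vessel = (
                tid is not None and scene.truth_classes[tid - 1] == TRUTH_MICROVESSEL
            )
            X.append(feature_vector(rec))
            y.append(forest.CLASS_M if is_vessel else forest.CLASS_N)
    return np.asarray(X, dtype=np.float64), y


def train_on_scenes(
    scenes: list[SyntheticScene], cfg: dict | None = None
) -> forest.ForestModel:
    cfg = cfg or default_config()
    X, y = candidate_training_records(scenes, cfg)
    f = cfg["forest"]
    return forest.train_forest(
        X, y,
        n_trees=f["n_trees"], subset_size=f["subset_size"], seed=f["seed"],
        gain_epsilon=f["gain_epsilon"], min_samples=f["min_samples"],
        max_depth=f["max_depth"], candidate_grid=f["candidate_grid"],
    )


def evaluate_scene(
    scene: SyntheticScene, model: forest.ForestModel, cfg: dict | None = None
) -> dict:
    """Segment one scene and score it against its ground truth."""
    cfg = cfg or default_config()
    res = segment_image(scene.image, model, cfg)
    counts = evaluation.match_structures(
        res.labelmap, res.classes, scene.truth_labelmap, scene.truth_classes,
        iou_threshold=cfg["evaluation"]["iou_threshold"],
    )
    return {
        "entropy_bits": scene.achieved_entropy_bits,
        "seed": scene.seed,
        "n_candidates": len(res.records),
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        "n_missed": counts.n_missed,
    }


def run_benchmark(
    cfg: dict | None = None,
    n_scenes: int | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate -> train -> segment the held-out split -> characterize.

    The scene-level split is 70/30 train/test by default, interleaved across
    the entropy ramp so both splits span the full range. Returns a dict with
    per-scene and per-bin tables plus the summary statistics.
    """
    cfg = cfg or default_config()
    bcfg = cfg["benchmark"]
    n = n_scenes if n_scenes is not None else bcfg["n_scenes"]
    master = seed if seed is not None else cfg["seed"]

    scene_params = _scene_params_from_cfg(cfg)
    scenes, manifest = synthesis.generate_dataset(
        n, tuple(bcfg["entropy_range"]), scene_params, seed=master, strict=False
    )
    # interleaved split: targets are sorted by entropy, so stride sampling
    # keeps train and test spanning the whole range
    rng = np.random.default_rng(master)
    order = rng.permutation(n)
    n_train = int(round(bcfg["train_fraction"] * n))
    train_idx = set(order[:n_train].tolist())
    train_scenes = [s for i, s in enumerate(scenes) if i in train_idx]
    test_scenes = [s for i, s in enumerate(scenes) if i not in train_idx]

    logger.info("training forest on %d scenes", len(train_scenes))
    model = train_on_scenes(train_scenes, cfg)
    logger.info(
        "forest trained: %d records, oob=%.3f",
        model.metadata.get("n_training_records", -1),
        model.metadata.get("oob_accuracy") or float("nan"),
    )

    rows = [evaluate_scene(s, model, cfg) for s in test_scenes]
    per_scene = pd.DataFrame(rows)
    bins, summary = evaluation.characterize_by_entropy(
        per_scene,
        bin_width=cfg["evaluation"]["bin_width"],
        entropy_low=cfg["evaluation"]["entropy_low"],
        entropy_high=cfg["evaluation"]["entropy_high"],
    )
    summary.update(
        {
            "n_train_scenes": len(train_scenes),
            "n_test_scenes": len(test_scenes),
            "master_seed": int(master),
            "oob_accuracy": model.metadata.get("oob_accuracy"),
        }
    )
    return {
        "per_scene": per_scene,
        "bins": bins,
        "summary": summary,
        "model": model,
        "manifest": manifest,
    }


def _scene_params_from_cfg(cfg: dict) -> SceneParams:
    s = cfg["synthesis"]
    return SceneParams(
        image_size=tuple(s["image_size"]),
        n_vessels=s["n_vessels"],
        n_distractors=s["n_distractors"],
        vessel_width_px=tuple(s["vessel_width_px"]),
        vessel_length_px=tuple(s["vessel_length_px"]),
        artery_width_px=tuple(s["artery_width_px"]),
        artery_length_px=tuple(s["artery_length_px"]),
        neuron_diameter_px=tuple(s["neuron_diameter_px"]),
        stain_intensity=tuple(s["stain_intensity"]),
        entropy_tol=s["entropy_tol"],
        max_refine_iter=s["max_refine_iter"],
        min_area_px=cfg["structures"]["min_area_px"],
    )
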