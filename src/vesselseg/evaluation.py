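"""Structure-level scoring against ground truth and the FPR/FNR-vs-entropy
characterization.

Matching rule: predicted and truth structures are paired one-to-one by
greedy descending IoU (intersection over union of their pixel sets), with
pairs below the IoU threshold never matched. Counts are then assigned at
the structure level:

* predicted microvessel matched to a truth microvessel      -> TP
* predicted microvessel matched to a non-vessel / unmatched -> FP
* predicted non-vessel matched to a truth microvessel       -> FN
* predicted non-vessel otherwise (correct rejection)        -> TN
* truth microvessel with no matching candidate at all       -> FN
  (a presegmentation miss; reported separately as ``n_missed``)

FPR = FP / (FP + TN) uses all candidate non-vessel structures reaching the
classifier as its denominator; FNR = FN / (FN + TP). Scenes are binned by
achieved image entropy and the per-bin mean of per-image rates is reported,
mirroring how FPR rises with background complexity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LabelMap
from .synthesis import TRUTH_MICROVESSEL


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_missed: int = 0  # truth microvessels with no candidate at all (subset of fn)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.n_missed + other.n_missed,
        )


@dataclass(frozen=True)
class EntropyBinRecord:
    bin_low: float
    bin_high: float
    n_images: int
    mean_fpr: float | None
    mean_fnr: float | None


def _overlap_table(pred: np.ndarray, truth: np.ndarray, n_pred: int, n_truth: int):
    """Pairwise intersection pixel counts between positive labels."""
    either = (pred > 0) | (truth > 0)
    p = pred[either].astype(np.int64)
    t = truth[either].astype(np.int64)
    joint = np.bincount(p * (n_truth + 1) + t, minlength=(n_pred + 1) * (n_truth + 1))
    inter = joint.reshape(n_pred + 1, n_truth + 1)
    a_pred = np.bincount(pred.ravel(), minlength=n_pred + 1)
    a_truth = np.bincount(truth.ravel(), minlength=n_truth + 1)
    return inter, a_pred, a_truth


def greedy_iou_matching(
    pred_labels: LabelMap, truth_labels: LabelMap, iou_threshold: float
) -> dict[int, int]:
    """One-to-one greedy matching by descending IoU; ties break toward the
    lower predicted id, then the lower truth id. Returns {pred_id: truth_id}."""
    n_p, n_t = pred_labels.n_structures, truth_labels.n_structures
    if n_p == 0 or n_t == 0:
        return {}
    inter, a_p, a_t = _overlap_table(pred_labels.labels, truth_labels.labels, n_p, n_t)
    pairs = []
    for pid in range(1, n_p + 1):
        for tid in np.nonzero(inter[pid, 1:])[0] + 1:
            i = inter[pid, tid]
            iou = i / (a_p[pid] + a_t[tid] - i)
            if iou >= iou_threshold:
                pairs.append((-iou, pid, tid))
    pairs.sort()
    matched: dict[int, int] = {}
    used_truth: set[int] = set()
    for _, pid, tid in pairs:
        if pid in matched or tid in used_truth:
            continue
        matched[pid] = tid
        used_truth.add(tid)
    return matched


def match_structures(
    pred_labels: LabelMap,
    pred_classes,
    truth_labels: LabelMap,
    truth_classes,
    iou_threshold: float = 0.3,
) -> ConfusionCounts:
    """Structure-level confusion counts for one scene (see module docstring)."""
    if pred_labels.labels.shape != truth_labels.labels.shape:
        raise ValueError("predicted and truth labelmaps differ in shape")
    if len(pred_classes) != pred_labels.n_structures:
        raise ValueError("pred_classes length mismatch")
    if len(truth_classes) != truth_labels.n_structures:
        raise ValueError("truth_classes length mismatch")
    matched = greedy_iou_matching(pred_labels, truth_labels, iou_threshold)
    tp = fp = tn = fn = 0
    for pid in range(1, pred_labels.n_structures + 1):
        is_vessel_call = pred_classes[pid - 1] == "M"
        tid = matched.get(pid)
        truth_is_vessel = tid is not None and truth_classes[tid - 1] == TRUTH_MICROVESSEL
        if is_vessel_call:
            if truth_is_vessel:
                tp += 1
            else:
                fp += 1
        else:
            if truth_is_vessel:
                fn += 1
            else:
                tn += 1
    matched_truth = set(matched.values())
    n_missed = sum(
        1
        for tid in range(1, truth_labels.n_structures + 1)
        if truth_classes[tid - 1] == TRUTH_MICROVESSEL and tid not in matched_truth
    )
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn + n_missed, n_missed=n_missed)


def rates(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(FPR, FNR); a zero denominator reports the rate as None (missing)."""
    fpr = counts.fp / (counts.fp + counts.tn) if (counts.fp + counts.tn) > 0 else None
    fnr = counts.fn / (counts.fn + counts.tp) if (counts.fn + counts.tp) > 0 else None
    return fpr, fnr


def characterize_by_entropy(
    scene_records: pd.DataFrame,
    bin_width: float = 0.5,
    entropy_low: float = 3.0,
    entropy_high: float = 8.0,
) -> tuple[list[EntropyBinRecord], dict]:
    """Bin per-scene results by achieved entropy and summarize.

    ``scene_records`` needs columns ``entropy_bits, tp, fp, tn, fn``
    (one row per scene). Returns the per-bin records plus a summary with
    per-image-averaged and pooled rates and the Spearman correlation of bin
    midpoint vs mean FPR.
    """
    from scipy import stats

    df = scene_records.copy()
    df["fpr"] = np.where(df.fp + df.tn > 0, df.fp / np.maximum(df.fp + df.tn, 1), np.nan)
    df["fnr"] = np.where(df.fn + df.tp > 0, df.fn / np.maximum(df.fn + df.tp, 1), np.nan)

    n_bins = int(np.ceil((entropy_high - entropy_low) / bin_width))
    records: list[EntropyBinRecord] = []
    for b in range(n_bins):
        lo = entropy_low + b * bin_width
        hi = lo + bin_width
        sel = df[(df.entropy_bits >= lo) & (df.entropy_bits < hi)]
        if sel.empty:
            continue
        mean_fpr = float(sel.fpr.mean()) if sel.fpr.notna().any() else None
        mean_fnr = float(sel.fnr.mean()) if sel.fnr.notna().any() else None
        records.append(
            EntropyBinRecord(
                bin_low=lo, bin_high=hi, n_images=len(sel),
                mean_fpr=mean_fpr, mean_fnr=mean_fnr,
            )
        )

    pooled_fp, pooled_tn = int(df.fp.sum()), int(df.tn.sum())
    pooled_fn, pooled_tp = int(df.fn.sum()), int(df.tp.sum())
    usable = [r for r in records if r.mean_fpr is not None]
    rho = None
    if len(usable) >= 3 and len({r.mean_fpr for r in usable}) > 1:
        mids = [(r.bin_low + r.bin_high) / 2 for r in usable]
        rho = float(stats.spearmanr(mids, [r.mean_fpr for r in usable]).statistic)
    summary = {
        "n_scenes": int(len(df)),
        "mean_fpr_per_image": float(df.fpr.mean()) if df.fpr.notna().any() else None,
        "mean_fnr_per_image": float(df.fnr.mean()) if df.fnr.notna().any() else None,
        "pooled_fpr": pooled_fp / (pooled_fp + pooled_tn) if pooled_fp + pooled_tn else None,
        "pooled_fnr": pooled_fn / (pooled_fn + pooled_tp) if pooled_fn + pooled_tp else None,
        "spearman_entropy_fpr": rho,
    }
    return records, summary


def bins_to_frame(records: list[EntropyBinRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin_low": r.bin_low,
                "bin_high": r.bin_high,
                "n_images": r.n_images,
                "mean_fpr": r.mean_fpr,
                "mean_fnr": r.mean_fnr,
            }
            for r in records
        ]
    )


def plot_fpr_vs_entropy(
    scene_records: pd.DataFrame,
    bin_records: list[EntropyBinRecord],
    path: str | Path,
) -> None:
    """Scatter of per-image FPR over entropy with the per-bin mean curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scene_records
    fpr = np.where(df.fp + df.tn > 0, df.fp / np.maximum(df.fp + df.tn, 1), np.nan)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df.entropy_bits, 100 * fpr, ".", alpha=0.4, label="per image")
    xs = [(r.bin_low + r.bin_high) / 2 for r in bin_records if r.mean_fpr is not None]
    ys = [100 * r.mean_fpr for r in bin_records if r.mean_fpr is not None]
    ax.plot(xs, ys, "o-", color="crimson", label="bin mean")
    ax.set_xlabel("image entropy (bits)")
    ax.set_ylabel("false positive rate (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
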