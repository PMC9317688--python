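"""Segmentation evaluation: Dice overlap, label resolution, paired testing.

Unsupervised segmenters emit arbitrary class indices, so a predicted label
map is scored by the best-matching class (``best_label_dice``), the standard
convention when no class is designated as foreground.  Method comparisons on
the same images use the two-sided Wilcoxon signed-rank test on per-image
Dice values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dice",
    "best_label_dice",
    "center_prior_label",
    "wilcoxon_signed_rank",
    "EvalResult",
    "evaluate_dataset",
]


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X ∩ Y| / (|X| + |Y|) of two boolean masks.

    Two empty masks agree vacuously and score 1.0 (with a warning).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int(np.logical_and(x, y).sum()) / denom


def best_label_dice(pseudo: np.ndarray, truth: np.ndarray, num_classes: int):
    """Dice of the best-matching class of a label map against a boolean mask.

    Returns ``(dice_value, class_index)``; ties resolve to the smaller index.
    """
    pseudo = np.asarray(pseudo)
    if pseudo.shape != np.asarray(truth).shape:
        raise ValueError(f"shapes differ: {pseudo.shape} vs {np.asarray(truth).shape}")
    best_d, best_k = -1.0, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(num_classes):
            d = dice(pseudo == k, truth)
            if d > best_d:
                best_d, best_k = d, k
    return best_d, best_k


def center_prior_label(pseudo: np.ndarray, num_classes: int, window: float = 0.25) -> int:
    """Annotation-free foreground heuristic: the majority class of a central window."""
    h, w = pseudo.shape
    dh, dw = max(1, int(h * window)), max(1, int(w * window))
    patch = pseudo[(h - dh) // 2:(h + dh) // 2, (w - dw) // 2:(w + dw) // 2]
    counts = np.bincount(patch.ravel(), minlength=num_classes)
    return int(counts.argmax())


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float],
                         alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's rule).  The exact null
    distribution is used for n <= 25 without ties among the nonzero absolute
    differences; otherwise the normal approximation with tie correction.
    All-zero differences give p = 1.0 with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                         method=method, correction=False)
    return float(res.pvalue)


@dataclass
class EvalResult:
    """Per-method Dice results plus pairwise significance tests."""

    per_image_dice: dict[str, list[float]]
    mean_dice: dict[str, float]
    chosen_labels: dict[str, list[int]]
    p_values: dict[str, float] = field(default_factory=dict)
    ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids}
        for name, vals in self.per_image_dice.items():
            data[f"dice_{name}"] = vals
        return pd.DataFrame(data)


def _as_method_dict(preds) -> dict:
    if isinstance(preds, Mapping):
        return dict(preds)
    return {"pred": preds}


def evaluate_dataset(pred_masks, truths, num_classes: int, ids=None,
                     out_csv=None) -> EvalResult:
    """Score one or more methods' label maps against ground-truth masks.

    ``pred_masks`` is a list of label maps (single method) or a mapping of
    method name to such a list, id-aligned with ``truths``.  Per-image Dice
    uses the best-matching class; with >= 2 methods, all pairwise two-sided
    Wilcoxon tests on the per-image Dice values are reported.
    """
    methods = _as_method_dict(pred_masks)
    n = len(truths)
    if ids is None:
        ids = [f"{k:04d}" for k in range(n)]
    if len(ids) != n:
        raise ValueError("ids and truths must have equal length")
    for name, masks in methods.items():
        if len(masks) != n:
            missing = set(ids[:n]) ^ set(ids[:len(masks)])
            raise ValueError(
                f"method {name!r} has {len(masks)} masks for {n} truths; "
                f"unmatched ids: {sorted(missing)}")

    per, labels, means = {}, {}, {}
    for name, masks in methods.items():
        scores, ks = [], []
        for pm, tm in zip(masks, truths):
            d, k = best_label_dice(pm, tm, num_classes)
            scores.append(d)
            ks.append(k)
        per[name] = scores
        labels[name] = ks
        means[name] = float(np.mean(scores))

    p_values = {}
    names = list(methods)
    for i_a in range(len(names)):
        for i_b in range(i_a + 1, len(names)):
            na, nb = names[i_a], names[i_b]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_values[f"{na} vs {nb}"] = wilcoxon_signed_rank(per[na], per[nb])

    result = EvalResult(per_image_dice=per, mean_dice=means, chosen_labels=labels,
                        p_values=p_values, ids=list(ids))
    if out_csv is not None:
        result.to_frame().to_csv(out_csv, index=False)
    return result
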