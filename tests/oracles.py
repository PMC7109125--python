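"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (dynamic
programs, direct formulas, explicit recurrences) and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def exhaustive_multi_otsu(hist: np.ndarray, centers: np.ndarray, n_levels: int = 3):
    """Brute-force maximiser of between-class variance over *all* ordered
    cut placements (enumerated outer loop over the first cut, vectorised
    grids over the remaining ones).  Only n_levels in {1, 3} are needed by
    the suite.

    Returns (thresholds as bin-center values of the last bin of each lower
    class, achieved between-class variance).
    """
    hist = np.asarray(hist, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    w = hist / hist.sum()
    m = w * centers
    P = np.concatenate([[0.0], np.cumsum(w)])
    M = np.concatenate([[0.0], np.cumsum(m)])
    nbins = len(hist)

    def seg(i, j):
        # W * mu^2 contribution of the class covering bins [i, j)
        W = P[j] - P[i]
        Mu = M[j] - M[i]
        W = np.asarray(W, dtype=np.float64)
        out = np.where(W > 0, np.asarray(Mu) ** 2 / np.where(W > 0, W, 1.0), 0.0)
        return out

    best_score, best_cuts = -np.inf, None
    if n_levels == 1:
        for c1 in range(1, nbins):
            score = float(seg(0, c1) + seg(c1, nbins))
            if score > best_score:
                best_score, best_cuts = score, (c1,)
    elif n_levels == 3:
        for c1 in range(1, nbins - 2):
            c2g, c3g = np.meshgrid(
                np.arange(c1 + 1, nbins - 1), np.arange(c1 + 2, nbins), indexing="ij"
            )
            if c2g.size == 0:
                continue
            valid = c3g > c2g
            total = np.where(
                valid,
                seg(0, c1) + seg(c1, c2g) + seg(c2g, c3g) + seg(c3g, nbins),
                -np.inf,
            )
            k = int(np.argmax(total))
            sc = float(total.ravel()[k])
            if sc > best_score:
                i2, i3 = np.unravel_index(k, total.shape)
                best_score, best_cuts = sc, (c1, int(c2g[i2, i3]), int(c3g[i2, i3]))
    else:
        raise NotImplementedError
    variance = best_score - M[-1] ** 2
    thresholds = tuple(float(centers[c - 1]) for c in best_cuts)
    return thresholds, float(variance)


def direct_metrics(tp: int, fp: int, fn: int, tn: int, variant: str) -> dict:
    """Metric formulas written out verbatim."""
    nan = float("nan")
    total = tp + fp + fn + tn
    if variant == "printed":
        pa_c = tp / (tp + fp) if tp + fp else nan
        pa_b = tn / (tn + fn) if tn + fn else nan
        iou_c = tp / (fn + tp + tn) if fn + tp + tn else nan
        iou_b = tn / (fp + tn + tp) if fp + tn + tp else nan
    else:
        pa_c = tp / (tp + fn) if tp + fn else nan
        pa_b = tn / (tn + fp) if tn + fp else nan
        iou_c = tp / (tp + fp + fn) if tp + fp + fn else nan
        iou_b = tn / (tn + fn + fp) if tn + fn + fp else nan
    return {
        "pixel_acc_canal": pa_c,
        "pixel_acc_background": pa_b,
        "global_acc": (tp + tn) / total if total else nan,
        "class_acc": (pa_c + pa_b) / 2,
        "iou_canal": iou_c,
        "iou_background": iou_b,
        "mean_iou": (iou_c + iou_b) / 2,
    }


def unet_output_size(size: int, depth: int, valid: bool) -> int:
    """Per-layer spatial recurrence of a double-conv U-Net (kernel 3).

    Raises AssertionError when a pooled size would be odd — the same
    condition under which the real network cannot run.
    """

    def conv2(s: int) -> int:
        return s - 4 if valid else s

    sizes = []
    s = size
    for _ in range(depth):
        s = conv2(s)
        sizes.append(s)
        assert s % 2 == 0 and s > 0, f"size {s} cannot be pooled"
        s //= 2
    s = conv2(s)
    for _ in range(depth):
        s *= 2
        s = conv2(s)
    assert s > 0
    return s
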