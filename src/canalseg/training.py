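"""Class balancing, loss, dataset splitting, patch sampling and training.

The canal occupies a fraction of a percent of a scan, so the loss is a
class-weighted binary cross-entropy with weights from median frequency
balancing: ``freq(c) = pixels(c) / (images containing c * image size)`` and
``weight(c) = median(freq) / freq(c)`` (for two classes the median is the
mean of the two frequencies), which upweights the rare canal class by the
inverse of its relative frequency.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import CanalSegError
from .nn import Adam, WeightedCrossEntropy
from .volume_io import BinaryMask, Volume

__all__ = [
    "ClassWeights",
    "TrainConfig",
    "PatchSpec",
    "SplitSpec",
    "median_frequency_weights",
    "weighted_bce",
    "split_dataset",
    "sample_patches",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class ClassWeights:
    """Positive per-class weights; keys are class names (e.g. background,
    canal)."""

    weights: Mapping[str, float]
    method: Literal["median_frequency", "manual"] = "manual"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise CanalSegError("class weights must be > 0")

    def pair(self) -> tuple[float, float]:
        """(background, canal) tuple for the two-class loss."""
        return (float(self.weights["background"]), float(self.weights["canal"]))

    def normalized_to(self, reference: str, scale: float = 1000.0) -> dict[str, float]:
        """Weights rescaled so ``weights[reference] == scale``."""
        ref = self.weights[reference]
        return {k: v * scale / ref for k, v in self.weights.items()}


def median_frequency_weights(
    pixel_counts: Mapping[str, int],
    presence_counts: Mapping[str, int],
    image_pixel_count: int,
) -> ClassWeights:
    """Median frequency balancing over per-class pixel statistics."""
    if set(pixel_counts) != set(presence_counts):
        raise CanalSegError("pixel_counts and presence_counts must share keys")
    freqs = {}
    for c, n in pixel_counts.items():
        if n <= 0:
            raise CanalSegError(f"class {c!r} has no pixels")
        if presence_counts[c] <= 0:
            raise CanalSegError(f"class {c!r} has zero presence count")
        freqs[c] = n / (presence_counts[c] * image_pixel_count)
    med = float(np.median(list(freqs.values())))
    return ClassWeights(
        weights={c: med / f for c, f in freqs.items()}, method="median_frequency"
    )


def weighted_bce(
    pred_prob: np.ndarray,
    target: np.ndarray | BinaryMask,
    weights: ClassWeights | tuple[float, float],
    eps: float = 1e-7,
) -> float:
    """Mean over voxels of ``-[w_canal*t*log p + w_bg*(1-t)*log(1-p)]``.

    ``pred_prob`` is the per-voxel canal probability, clipped to
    ``[eps, 1-eps]``.
    """
    t = target.data if isinstance(target, BinaryMask) else np.asarray(target)
    p = np.asarray(pred_prob, dtype=np.float64)
    if p.shape != t.shape:
        raise CanalSegError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    w_bg, w_fg = weights.pair() if isinstance(weights, ClassWeights) else weights
    p = np.clip(p, eps, 1.0 - eps)
    t = t.astype(np.float64)
    return float(-(w_fg * t * np.log(p) + w_bg * (1.0 - t) * np.log(1.0 - p)).mean())


@dataclass(frozen=True)
class SplitSpec:
    """train:valid:test ratio split, seeded and optionally stratified."""

    ratio: tuple[int, int, int] = (6, 2, 2)
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratio) or sum(self.ratio) <= 0:
            raise CanalSegError(f"bad split ratio {self.ratio}")


def _split_sizes(n: int, ratio: tuple[int, int, int]) -> tuple[int, int, int]:
    total = sum(ratio)
    n_test = n * ratio[2] // total
    n_valid = n * ratio[1] // total
    return (n - n_valid - n_test, n_valid, n_test)


def split_dataset(
    n_items: int,
    spec: SplitSpec,
    labels: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seed-reproducible (train, valid, test) indices.

    ``test = floor(n*r_test/sum)``, ``valid = floor(n*r_valid/sum)``, train
    takes the remainder.  With ``stratified`` and per-item class labels the
    ratio is applied within each label group so every partition sees the
    same class mix.
    """
    if spec.stratified:
        if labels is None:
            raise CanalSegError("stratified split requires labels")
        labels = np.asarray(labels)
        if len(labels) != n_items:
            raise CanalSegError("labels length must equal n_items")
        need = sum(1 for r in spec.ratio if r > 0)
        parts: list[list[np.ndarray]] = [[], [], []]
        for gi, lab in enumerate(np.unique(labels)):
            idx = np.nonzero(labels == lab)[0]
            if len(idx) < need:
                raise CanalSegError(
                    f"cannot stratify: class {lab!r} has {len(idx)} items for {need} partitions"
                )
            rng = np.random.default_rng(spec.seed + gi)
            idx = rng.permutation(idx)
            n_tr, n_va, n_te = _split_sizes(len(idx), spec.ratio)
            parts[0].append(idx[:n_tr])
            parts[1].append(idx[n_tr : n_tr + n_va])
            parts[2].append(idx[n_tr + n_va :])
        return tuple(np.sort(np.concatenate(p)) for p in parts)  # type: ignore[return-value]
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_items)
    n_tr, n_va, n_te = _split_sizes(n_items, spec.ratio)
    return (
        np.sort(perm[:n_tr]),
        np.sort(perm[n_tr : n_tr + n_va]),
        np.sort(perm[n_tr + n_va :]),
    )


@dataclass(frozen=True)
class PatchSpec:
    """Random 3D patch sampling: ``count`` cubes of ``size`` voxels."""

    count: int = 64
    size: tuple[int, int, int] = (132, 132, 132)

    def __post_init__(self) -> None:
        if self.count < 1 or any(s < 1 for s in self.size):
            raise CanalSegError("invalid patch spec")


def sample_patches(
    vol: Volume,
    mask: BinaryMask,
    spec: PatchSpec,
    seed: int,
    mask_output_size: tuple[int, int, int] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Uniform random corner positions, seed-reproducible.

    With ``mask_output_size`` the mask patch is centre-cropped to the
    network's valid-padding output region.
    """
    data, m = vol.data, mask.data
    if data.shape != m.shape:
        raise CanalSegError("volume and mask shapes differ")
    if any(d < p for d, p in zip(data.shape, spec.size)):
        raise CanalSegError(f"volume {data.shape} smaller than patch {spec.size}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(spec.count):
        corner = [int(rng.integers(0, d - p + 1)) for d, p in zip(data.shape, spec.size)]
        sl = tuple(slice(c, c + p) for c, p in zip(corner, spec.size))
        vp, mp = data[sl], m[sl]
        if mask_output_size is not None:
            off = [(p - o) // 2 for p, o in zip(spec.size, mask_output_size)]
            sl2 = tuple(slice(o, o + s) for o, s in zip(off, mask_output_size))
            mp = mp[sl2]
        out.append((vp, mp))
    return out


@dataclass(frozen=True)
class TrainConfig:
    """Adam-based optimisation settings.

    ``decay`` follows the 2D variants' semantics (multiplicative per-epoch
    decay, ``lr / (1 + decay * epoch)``); ``schedule`` is the 3D variant's
    step decay ``(factor, period)`` — divide the rate by ``factor`` after
    every ``period`` epochs.  Only one of the two is typically used.
    """

    learning_rate: float = 1e-3
    decay: float = 0.0
    momentum_beta1: float = 0.9
    epochs: int = 1
    batch_size: int = 1
    seed: int = 0
    schedule: tuple[float, int] | None = None
    class_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise CanalSegError("invalid training configuration")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        lr = self.learning_rate
        if self.schedule is not None:
            factor, period = self.schedule
            lr /= factor ** (epoch // period)
        if self.decay:
            lr /= 1.0 + self.decay * epoch
        return lr


@dataclass
class TrainResult:
    model: object
    loss_history: list[float]
    valid_history: list[float]
    best_epoch: int | None


def train(
    model,
    batches: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    valid_batches: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> TrainResult:
    """Weighted-cross-entropy optimisation with per-epoch loss history.

    ``batches`` are (input ``(N,C,*S)``, target ``(N,*S_out)``) pairs; the
    batch order is reshuffled each epoch from ``cfg.seed``.  When a
    validation set is given, the parameters of the best validation epoch are
    restored at the end (best-on-validation checkpoint selection).
    ``epochs = 0`` leaves the parameters untouched.  A NaN loss aborts with
    a diagnostic.
    """
    loss_fn = WeightedCrossEntropy(cfg.class_weights)
    params = model.params()
    opt = Adam(params, lr=cfg.learning_rate, beta1=cfg.momentum_beta1)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    valid_history: list[float] = []
    best = (np.inf, None, None)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(len(batches))
        losses = []
        for bi in order:
            x, t = batches[bi]
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, g = loss_fn.loss_and_grad(logits, t)
            if not np.isfinite(loss):
                raise CanalSegError(
                    f"non-finite training loss at epoch {epoch}: {loss}; "
                    "reduce the learning rate"
                )
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if valid_batches is not None:
            vl = []
            for x, t in valid_batches:
                logits = model.forward(x, train=False)
                vl.append(loss_fn.loss_and_grad(logits, t)[0])
            v = float(np.mean(vl))
            valid_history.append(v)
            if v < best[0]:
                best = (v, epoch, [p.value.copy() for p in params])
    best_epoch = None
    if valid_batches is not None and best[2] is not None:
        best_epoch = best[1]
        for p, v in zip(params, best[2]):
            p.value[...] = v
    return TrainResult(model, history, valid_history, best_epoch)
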