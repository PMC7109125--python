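"""Encoder-decoder architecture builders.

Three families are provided, mirroring the study variants:

* ``segnet2d`` — VGG16-style 13-conv encoder with batch normalisation and
  max-pooling that stores its argmax indices; the mirrored decoder upsamples
  through those indices (no learned upsampling).
* ``unet2d`` — 4-down/4-up U-Net; the variant used here keeps the feature
  maps at input resolution with 'same' padding, so no crop before the skip
  concatenation is needed.  ``filters`` selects the original channel plan
  (64..1024) or the halved "fewer filters" plan (32..512).  Adjacent-slice
  context enters as extra input channels (one shared 2D network).
* ``unet3d`` — the 3D counterpart (3D convolutions, 3D max pooling, 3D
  up-convolutions) with three resolution steps, batch normalisation, no
  dropout, and 'valid' padding kept from its original formulation; a 132^3
  patch maps to a 44^3 output.

``build_model`` returns both a declarative per-layer description (shapes
and parameter counts, computed analytically) and the instantiated
trainable network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import CanalSegError
from . import nn

__all__ = [
    "ModelSpec",
    "LayerInfo",
    "ModelDescription",
    "build_model",
    "describe_model",
    "load_encoder_weights",
    "UNet",
    "SegNet",
]

SEGNET_PLAN: tuple[tuple[int, ...], ...] = (
    (64, 64),
    (128, 128),
    (256, 256, 256),
    (512, 512, 512),
    (512, 512, 512),
)
UNET2D_ORIGINAL: tuple[int, ...] = (64, 128, 256, 512, 1024)
UNET2D_FEWER: tuple[int, ...] = (32, 64, 128, 256, 512)
UNET3D_PLAN: tuple[int, ...] = (32, 64, 128, 256)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one architecture variant.

    ``filters``: for the U-Nets, per-level channel counts (the last entry is
    the bottleneck); for SegNet, a tuple of per-stage tuples.  ``None``
    selects the family's canonical plan.
    """

    family: Literal["segnet2d", "unet2d", "unet3d"]
    filters: tuple | None = None
    padding: Literal["same", "valid"] | None = None
    input_channels: int = 1
    batch_norm: bool | None = None
    dropout: bool | None = None
    pretrained_encoder: str | None = None
    n_classes: int = 2
    seed: int = 0

    def resolved(self) -> "ModelSpec":
        """Fill family defaults and enforce the family invariants."""
        fam = self.family
        if fam == "segnet2d":
            filters = self.filters or SEGNET_PLAN
            padding = self.padding or "same"
            bn = True if self.batch_norm is None else self.batch_norm
            dropout = False if self.dropout is None else self.dropout
            if not bn:
                raise CanalSegError("segnet2d requires batch normalisation")
            if padding != "same":
                raise CanalSegError("segnet2d uses same padding")
        elif fam == "unet2d":
            filters = self.filters or UNET2D_ORIGINAL
            padding = self.padding or "same"
            bn = False if self.batch_norm is None else self.batch_norm
            dropout = True if self.dropout is None else self.dropout
            if padding != "same":
                raise CanalSegError(
                    "this unet2d variant keeps same padding (no crop before concatenation)"
                )
        elif fam == "unet3d":
            filters = self.filters or UNET3D_PLAN
            padding = self.padding or "valid"
            bn = True if self.batch_norm is None else self.batch_norm
            dropout = False if self.dropout is None else self.dropout
            if padding != "valid":
                raise CanalSegError("unet3d maintains valid padding")
            if dropout:
                raise CanalSegError("unet3d removes dropout")
            if not bn:
                raise CanalSegError("unet3d adds batch normalisation")
        else:
            raise CanalSegError(f"unknown family {fam!r}")
        if self.input_channels < 1:
            raise CanalSegError("input_channels must be >= 1")
        return ModelSpec(
            family=fam,
            filters=tuple(filters),
            padding=padding,
            input_channels=self.input_channels,
            batch_norm=bn,
            dropout=dropout,
            pretrained_encoder=self.pretrained_encoder,
            n_classes=self.n_classes,
            seed=self.seed,
        )


@dataclass(frozen=True)
class LayerInfo:
    name: str
    kind: str
    out_channels: int
    spatial: tuple[int, ...] | None
    n_params: int


@dataclass(frozen=True)
class ModelDescription:
    family: str
    layers: tuple[LayerInfo, ...]
    total_params: int
    input_spatial: tuple[int, ...] | None
    output_spatial: tuple[int, ...] | None


# ---------------------------------------------------------------------------
# trainable networks
# ---------------------------------------------------------------------------


class _Block:
    """conv -> (BN) -> ReLU, repeated; the U-Net double-conv unit."""

    def __init__(self, in_ch, channels, dim, padding, bn, rng, kernel=3):
        self.layers = []
        c = in_ch
        for out in channels:
            self.layers.append(nn.Conv(c, out, kernel, dim, padding, rng))
            if bn:
                self.layers.append(nn.BatchNorm(out))
            self.layers.append(nn.ReLU())
            c = out
        self.out_channels = c

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def _center_crop(x: np.ndarray, spatial: Sequence[int]) -> tuple[np.ndarray, tuple]:
    offsets = []
    sl = [slice(None), slice(None)]
    for cur, tgt in zip(x.shape[2:], spatial):
        off = (cur - tgt) // 2
        offsets.append(off)
        sl.append(slice(off, off + tgt))
    return x[tuple(sl)], tuple(sl)


class UNet:
    """U-Net in 2 or 3 dimensions with explicit forward/backward passes."""

    def __init__(self, dim, in_ch, filters, padding, batch_norm, dropout, n_classes, seed):
        rng = np.random.default_rng(seed)
        self.dim, self.padding = dim, padding
        depth = len(filters) - 1
        self.enc = []
        self.pools = []
        c = in_ch
        for f in filters[:-1]:
            self.enc.append(_Block(c, (f, f), dim, padding, batch_norm, rng))
            self.pools.append(nn.MaxPool(dim))
            c = f
        self.bottleneck = _Block(c, (filters[-1], filters[-1]), dim, padding, batch_norm, rng)
        self.drop = nn.Dropout(0.5, rng) if dropout else None
        self.ups = []
        self.dec = []
        c = filters[-1]
        for f in reversed(filters[:-1]):
            self.ups.append(nn.UpConv(c, f, dim, rng))
            self.dec.append(_Block(2 * f, (f, f), dim, padding, batch_norm, rng))
            c = f
        self.final = nn.Conv(c, n_classes, 1, dim, "same", rng)
        self._depth = depth

    def forward(self, x, train=True):
        self._skips = []
        self._crops = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            self._skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        if self.drop is not None:
            x = self.drop.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(self._skips)):
            x = up.forward(x, train)
            if self.padding == "valid":
                skip_c, sl = _center_crop(skip, x.shape[2:])
            else:
                skip_c, sl = skip, None
            self._crops.append((skip.shape, sl))
            x = np.concatenate([skip_c, x], axis=1)
            x = dec.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, g):
        g = self.final.backward(g)
        skip_grads = []
        for up, dec, (skip_shape, sl) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._crops)
        ):
            g = dec.backward(g)
            half = g.shape[1] // 2
            gs, gx = g[:, :half], g[:, half:]
            if sl is not None:
                full = np.zeros(skip_shape)
                full[sl] = gs
                gs = full
            skip_grads.append(gs)
            g = up.backward(gx)
        if self.drop is not None:
            g = self.drop.backward(g)
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallowest-first; the encoder unwinds
        # deepest-first
        for block, pool, gs in zip(reversed(self.enc), reversed(self.pools), reversed(skip_grads)):
            g = pool.backward(g)
            g = block.backward(g + gs)
        self._skips = None
        return g

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.ups, self.dec):
            out += up.params() + dec.params()
        out += self.final.params()
        return out

    def param_items(self):
        items = []
        for i, block in enumerate(self.enc):
            items += _named_block(f"enc{i}", block)
        items += _named_block("bottleneck", self.bottleneck)
        for i, (up, dec) in enumerate(zip(self.ups, self.dec)):
            items += [(f"up{i}.W", up.W), (f"up{i}.b", up.b)]
            items += _named_block(f"dec{i}", dec)
        items += [("final.W", self.final.W), ("final.b", self.final.b)]
        return items


class SegNet:
    """SegNet: VGG-style encoder, decoder driven by stored pooling indices."""

    def __init__(self, in_ch, plan, batch_norm, n_classes, seed):
        rng = np.random.default_rng(seed)
        dim = 2
        self.enc_stages = []
        self.pools = []
        c = in_ch
        for stage in plan:
            self.enc_stages.append(_Block(c, stage, dim, "same", batch_norm, rng))
            self.pools.append(nn.MaxPool(dim))
            c = stage[-1]
        self.unpools = [nn.MaxUnpool(p) for p in reversed(self.pools)]
        self.dec_stages = []
        rev = list(reversed(plan))
        for i, stage in enumerate(rev):
            # mirrored stage; its last conv steps down to the next stage width
            target = rev[i + 1][-1] if i + 1 < len(rev) else stage[-1]
            channels = tuple(stage[:-1]) + (target,)
            self.dec_stages.append(_Block(c, channels, dim, "same", batch_norm, rng))
            c = channels[-1]
        self.final = nn.Conv(c, n_classes, 1, dim, "same", rng)

    def forward(self, x, train=True):
        for stage, pool in zip(self.enc_stages, self.pools):
            x = stage.forward(x, train)
            x = pool.forward(x, train)
        for unpool, stage in zip(self.unpools, self.dec_stages):
            x = unpool.forward(x, train)
            x = stage.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, g):
        g = self.final.backward(g)
        for unpool, stage in zip(reversed(self.unpools), reversed(self.dec_stages)):
            g = stage.backward(g)
            g = unpool.backward(g)
        for stage, pool in zip(reversed(self.enc_stages), reversed(self.pools)):
            g = pool.backward(g)
            g = stage.backward(g)
        return g

    def params(self):
        out = []
        for s in self.enc_stages:
            out += s.params()
        for s in self.dec_stages:
            out += s.params()
        out += self.final.params()
        return out

    def param_items(self):
        items = []
        for i, s in enumerate(self.enc_stages):
            items += _named_block(f"enc{i}", s)
        for i, s in enumerate(self.dec_stages):
            items += _named_block(f"dec{i}", s)
        items += [("final.W", self.final.W), ("final.b", self.final.b)]
        return items


def _named_block(prefix, block):
    items = []
    ci = bi = 0
    for layer in block.layers:
        if isinstance(layer, nn.Conv):
            items += [(f"{prefix}.conv{ci}.W", layer.W), (f"{prefix}.conv{ci}.b", layer.b)]
            ci += 1
        elif isinstance(layer, nn.BatchNorm):
            items += [(f"{prefix}.bn{bi}.gamma", layer.gamma), (f"{prefix}.bn{bi}.beta", layer.beta)]
            bi += 1
    return items


# ---------------------------------------------------------------------------
# analytic description
# ---------------------------------------------------------------------------


def _conv_out(spatial, k, padding, name):
    if spatial is None:
        return None
    out = tuple(nn.conv_output_size(s, k, padding) for s in spatial)
    if any(s < 1 for s in out):
        raise CanalSegError(f"layer {name}: spatial size {spatial} too small for valid {k}-conv")
    return out


def _pool_out(spatial, name):
    if spatial is None:
        return None
    if any(s % 2 for s in spatial):
        raise CanalSegError(f"layer {name}: odd spatial size {spatial} cannot be 2x-pooled")
    return tuple(s // 2 for s in spatial)


def describe_model(spec: ModelSpec, input_spatial: tuple[int, ...] | None = None) -> ModelDescription:
    """Per-layer output shapes and parameter counts, computed analytically.

    Raises a shape error naming the first failing layer when
    ``input_spatial`` is incompatible (valid padding underflow, odd size at
    a pooling stage).
    """
    spec = spec.resolved()
    dim = 3 if spec.family == "unet3d" else 2
    if input_spatial is not None and len(input_spatial) != dim:
        raise CanalSegError(f"{spec.family} expects {dim} spatial dims")
    rows: list[LayerInfo] = []
    k = 3

    def conv_row(name, cin, cout, spatial, kernel=3):
        out = _conv_out(spatial, kernel, spec.padding if kernel != 1 else "same", name)
        n = cout * cin * kernel**dim + cout
        rows.append(LayerInfo(name, "conv", cout, out, n))
        if spec.batch_norm and kernel != 1:
            rows.append(LayerInfo(name + ".bn", "batchnorm", cout, out, 2 * cout))
        return out

    if spec.family == "segnet2d":
        spatial = input_spatial
        c = spec.input_channels
        for si, stage in enumerate(spec.filters):
            for ci, f in enumerate(stage):
                spatial = conv_row(f"enc{si}.conv{ci}", c, f, spatial)
                c = f
            spatial = _pool_out(spatial, f"pool{si}")
            rows.append(LayerInfo(f"pool{si}", "maxpool", c, spatial, 0))
        rev = list(reversed(spec.filters))
        for si, stage in enumerate(rev):
            spatial = tuple(2 * s for s in spatial) if spatial else None
            rows.append(LayerInfo(f"unpool{si}", "maxunpool", c, spatial, 0))
            target = rev[si + 1][-1] if si + 1 < len(rev) else stage[-1]
            channels = tuple(stage[:-1]) + (target,)
            for ci, f in enumerate(channels):
                spatial = conv_row(f"dec{si}.conv{ci}", c, f, spatial)
                c = f
        spatial = conv_row("final", c, spec.n_classes, spatial, kernel=1)
    else:
        filters = spec.filters
        spatial = input_spatial
        c = spec.input_channels
        enc_spatial = []
        for li, f in enumerate(filters[:-1]):
            for ci in range(2):
                spatial = conv_row(f"enc{li}.conv{ci}", c, f, spatial)
                c = f
            enc_spatial.append(spatial)
            spatial = _pool_out(spatial, f"pool{li}")
            rows.append(LayerInfo(f"pool{li}", "maxpool", c, spatial, 0))
        for ci in range(2):
            spatial = conv_row(f"bottleneck.conv{ci}", c, filters[-1], spatial)
            c = filters[-1]
        if spec.dropout:
            rows.append(LayerInfo("dropout", "dropout", c, spatial, 0))
        for li, f in enumerate(reversed(filters[:-1])):
            spatial = tuple(2 * s for s in spatial) if spatial else None
            n = c * f * 2**dim + f
            rows.append(LayerInfo(f"up{li}", "upconv", f, spatial, n))
            rows.append(LayerInfo(f"concat{li}", "concat", 2 * f, spatial, 0))
            c = 2 * f
            for ci in range(2):
                spatial = conv_row(f"dec{li}.conv{ci}", c, f, spatial)
                c = f
        spatial = conv_row("final", c, spec.n_classes, spatial, kernel=1)

    return ModelDescription(
        family=spec.family,
        layers=tuple(rows),
        total_params=sum(r.n_params for r in rows),
        input_spatial=input_spatial,
        output_spatial=spatial,
    )


def build_model(spec: ModelSpec, input_spatial: tuple[int, ...] | None = None):
    """Instantiate the trainable network and its analytic description."""
    spec = spec.resolved()
    desc = describe_model(spec, input_spatial)
    if spec.family == "segnet2d":
        model = SegNet(spec.input_channels, spec.filters, spec.batch_norm, spec.n_classes, spec.seed)
    else:
        dim = 3 if spec.family == "unet3d" else 2
        model = UNet(
            dim,
            spec.input_channels,
            spec.filters,
            spec.padding,
            spec.batch_norm,
            spec.dropout,
            spec.n_classes,
            spec.seed,
        )
    if spec.pretrained_encoder:
        load_encoder_weights(model, spec.pretrained_encoder)
    return desc, model


def load_encoder_weights(model, path: str) -> list[str]:
    """Name-matched weight loading hook for externally pre-trained encoders.

    Reads an ``.npz`` of named arrays and copies every entry whose name and
    shape match one of the model's parameters.  No weights ship with the
    package and the hook is not validated against any published checkpoint.
    """
    data = np.load(path)
    loaded = []
    for name, param in model.param_items():
        if name in data and data[name].shape == param.value.shape:
            param.value[...] = data[name]
            loaded.append(name)
    return loaded
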