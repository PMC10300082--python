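"""Two-step UNet-RCAN restoration network (2D and 3D).

Stage one is a residual U-Net that recovers broad contextual information
from the noisy input: encoder stages are residual convolution blocks
(conv → LeakyReLU → conv, with a kernel-1 convolution refining the block's
skip path) followed by stride-2 max pooling; filters start at 64 and
double after each pooling.  The decoder mirrors this with transposed
convolutions, and each encoder→decoder skip connection is routed through a
residual channel attention block rather than copied verbatim, so that only
informative low-frequency channels bypass the bottleneck.  The output
layer is a 1×1 convolution.

Stage two is an RCAN without the super-resolution upscaling head (input
and output share their shape): its input is the U-Net prediction
concatenated with the original noisy image (2 channels), and its trunk is
3 residual groups of 8 channel attention blocks each, wrapped by short and
long skip connections.  A channel attention block computes a per-channel
sigmoid gate from globally pooled features (squeeze to 4 channels, expand
back) and rescales its convolutional features with it before the residual
addition.

For the 3D variant every convolution, pooling and upsampling kernel
becomes three-dimensional; arrays are laid out ``(N, C, z, y, x)``.

A statsmodels-flavoured front door is provided by
:class:`RestorationModel` (data + configuration) whose ``fit`` returns a
:class:`~sted_restore.train.RestorationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from ._engine import (Module, Conv, ConvTranspose, Tensor, concat,
                      global_avg_pool, leaky_relu, max_pool, mul, sigmoid)


@dataclass
class NetworkConfig:
    """All architecture hyperparameters of the two-step network."""

    dims: int = 2
    unet_base_filters: int = 64
    unet_depth: int = 3
    leaky_slope: float = 0.3
    rcan_filters: int = 64
    n_residual_groups: int = 3
    n_cab_per_group: int = 8
    ca_reduction_filters: int = 4
    conv_kernel: int = 3
    output_kernel: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.unet_depth < 1:
            raise ValueError("unet_depth must be >= 1")
        for name in ("unet_base_filters", "rcan_filters", "n_residual_groups",
                     "n_cab_per_group", "ca_reduction_filters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.conv_kernel % 2 == 0 or self.output_kernel % 2 == 0:
            raise ValueError("kernels must be odd for shape preservation")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class ResConvBlock(Module):
    """conv → LeakyReLU → conv, plus a kernel-1 conv on the skip path."""

    def __init__(self, in_ch, out_ch, cfg: NetworkConfig, rng):
        super().__init__()
        self.conv1 = Conv(in_ch, out_ch, cfg.conv_kernel, cfg.dims, rng)
        self.conv2 = Conv(out_ch, out_ch, cfg.conv_kernel, cfg.dims, rng)
        self.skip = Conv(in_ch, out_ch, 1, cfg.dims, rng)
        self.slope = cfg.leaky_slope

    def forward(self, x):
        h = self.conv2(leaky_relu(self.conv1(x), self.slope))
        return h + self.skip(x)


class ChannelAttentionBlock(Module):
    """Residual block gated channel-wise by globally pooled features.

    ``frozen_gate`` supports tile-consistent inference: when set, the
    per-channel gate from a reference forward pass replaces the
    tile-local global pooling (see :func:`predict`).
    """

    def __init__(self, channels, cfg: NetworkConfig, rng):
        super().__init__()
        self.conv1 = Conv(channels, channels, cfg.conv_kernel, cfg.dims, rng)
        self.conv2 = Conv(channels, channels, cfg.conv_kernel, cfg.dims, rng)
        self.squeeze = Conv(channels, cfg.ca_reduction_filters, 1, cfg.dims, rng)
        self.expand = Conv(cfg.ca_reduction_filters, channels, 1, cfg.dims, rng)
        self.slope = cfg.leaky_slope
        self.frozen_gate: np.ndarray | None = None
        self.last_gate: np.ndarray | None = None

    def attention(self, features):
        pooled = global_avg_pool(features)
        gate = sigmoid(self.expand(leaky_relu(self.squeeze(pooled), self.slope)))
        return gate

    def forward(self, x):
        feat = self.conv2(leaky_relu(self.conv1(x), self.slope))
        if self.frozen_gate is not None:
            return x + mul(Tensor(self.frozen_gate), feat)
        gate = self.attention(feat)
        self.last_gate = gate.data
        return x + mul(gate, feat)


class ResidualGroup(Module):
    """A stack of CABs, a trailing convolution, and a short skip."""

    def __init__(self, channels, cfg: NetworkConfig, rng):
        super().__init__()
        self.cabs = self.register_children(
            "cab", [ChannelAttentionBlock(channels, cfg, rng)
                    for _ in range(cfg.n_cab_per_group)])
        self.conv = Conv(channels, channels, cfg.conv_kernel, cfg.dims, rng)

    def forward(self, x):
        h = x
        for cab in self.cabs:
            h = cab(h)
        return x + self.conv(h)


class UNet(Module):
    """Residual U-Net with channel-attention skip connections."""

    def __init__(self, cfg: NetworkConfig, rng, in_ch: int = 1,
                 out_ch: int = 1):
        super().__init__()
        self.cfg = cfg
        f = cfg.unet_base_filters
        enc_channels = [f * 2 ** d for d in range(cfg.unet_depth)]
        self.encoders = self.register_children(
            "enc", [ResConvBlock(in_ch if d == 0 else enc_channels[d - 1],
                                 enc_channels[d], cfg, rng)
                    for d in range(cfg.unet_depth)])
        self.skip_cabs = self.register_children(
            "skipcab", [ChannelAttentionBlock(c, cfg, rng)
                        for c in enc_channels])
        bottom = enc_channels[-1] * 2
        self.bottleneck = ResConvBlock(enc_channels[-1], bottom, cfg, rng)
        ups, decs = [], []
        ch = bottom
        for d in reversed(range(cfg.unet_depth)):
            ups.append(ConvTranspose(ch, enc_channels[d], cfg.dims, rng))
            decs.append(ResConvBlock(2 * enc_channels[d], enc_channels[d],
                                     cfg, rng))
            ch = enc_channels[d]
        self.upsamplers = self.register_children("up", ups)
        self.decoders = self.register_children("dec", decs)
        self.head = Conv(enc_channels[0], out_ch, 1, cfg.dims, rng)

    def forward(self, x):
        x = Tensor.as_tensor(x)
        spatial = x.data.shape[2:]
        div = 2 ** self.cfg.unet_depth
        bad = [s for s in spatial if s % div]
        if bad:
            raise ValueError(
                f"spatial extents {spatial} must be divisible by 2^depth="
                f"{div}; pad the input (e.g. reflect-pad to the next "
                f"multiple) before the forward pass")
        skips = []
        h = x
        for enc, cab in zip(self.encoders, self.skip_cabs):
            h = enc(h)
            skips.append(cab(h))
            h = max_pool(h)
        h = self.bottleneck(h)
        for up, dec, skip in zip(self.upsamplers, self.decoders,
                                 reversed(skips)):
            h = dec(concat([up(h), skip], axis=1))
        return self.head(h)


class RCAN(Module):
    """Residual channel attention network without the upscaling module."""

    def __init__(self, cfg: NetworkConfig, rng, in_ch: int = 2,
                 out_ch: int = 1):
        super().__init__()
        f = cfg.rcan_filters
        self.head = Conv(in_ch, f, cfg.conv_kernel, cfg.dims, rng)
        self.groups = self.register_children(
            "rg", [ResidualGroup(f, cfg, rng)
                   for _ in range(cfg.n_residual_groups)])
        self.trunk_conv = Conv(f, f, cfg.conv_kernel, cfg.dims, rng)
        self.tail = Conv(f, out_ch, cfg.output_kernel, cfg.dims, rng)

    def forward(self, x):
        shallow = self.head(x)
        h = shallow
        for rg in self.groups:
            h = rg(h)
        h = self.trunk_conv(h) + shallow   # long skip connection
        return self.tail(h)


class UNetRCAN(Module):
    """The composite two-step network."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(self.config.seed)
        self.unet = UNet(self.config, rng)
        self.rcan = RCAN(self.config, rng, in_ch=2)

    def forward_stages(self, x):
        x = Tensor.as_tensor(x)
        coarse = self.unet(x)
        final = self.rcan(concat([coarse, x], axis=1))
        return coarse, final

    def forward(self, x):
        return self.forward_stages(x)[1]

    # -- persistence ---------------------------------------------------------
    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "weights.npz", **self.state_dict())
        self.config.to_yaml(directory / "config.yaml")
        return directory

    @classmethod
    def load(cls, directory) -> "UNetRCAN":
        directory = Path(directory)
        model = cls(NetworkConfig.from_yaml(directory / "config.yaml"))
        with np.load(directory / "weights.npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return model


def build_unet(config: NetworkConfig | None = None) -> UNet:
    config = config or NetworkConfig()
    return UNet(config, np.random.default_rng(config.seed))


def build_rcan(config: NetworkConfig | None = None, in_ch: int = 2) -> RCAN:
    config = config or NetworkConfig()
    return RCAN(config, np.random.default_rng(config.seed), in_ch=in_ch)


def build_unet_rcan(config: NetworkConfig | None = None) -> UNetRCAN:
    return UNetRCAN(config)


# ---------------------------------------------------------------------------
# tiled inference
# ---------------------------------------------------------------------------

def _blend_window(tile_shape, overlap: int, interior) -> np.ndarray:
    """Separable blending window for overlap-tiled inference.

    On tile faces interior to the image, the outer ``overlap/2`` pixels
    are discarded (their prediction lacks context the untiled pass would
    have seen) and the remaining overlap carries a linear cross-fade; on
    faces at the image border (``interior`` flag False) the weight stays 1
    to the edge, since the untiled pass sees the same truncated context
    there.
    """
    window = np.ones(tile_shape, dtype=np.float64)
    trim = overlap // 2
    ramp = overlap - trim
    for ax, size in enumerate(tile_shape):
        prof = np.ones(size)
        lo_int, hi_int = interior[ax]
        edge = np.arange(1, ramp + 1) / (ramp + 1)
        if lo_int:
            prof[:trim] = 0.0
            prof[trim:trim + ramp] = edge
        if hi_int:
            if trim:
                prof[-trim:] = 0.0
            stop = size - trim
            prof[stop - ramp:stop] = edge[::-1]
        shape = [1] * len(tile_shape)
        shape[ax] = size
        window = window * prof.reshape(shape)
    return window


def _all_cabs(model: UNetRCAN) -> list[ChannelAttentionBlock]:
    cabs = list(model.unet.skip_cabs)
    for rg in model.rcan.groups:
        cabs.extend(rg.cabs)
    return cabs


def predict(model: UNetRCAN, image: np.ndarray, tile_shape=None,
            overlap: int = 32, lock_gates: bool = True,
            gate_reference_extent: int = 512) -> np.ndarray:
    """Restore one frame (2D) or volume (3D) with overlap-tiled inference.

    The input is normalized to its maximum before the forward pass and
    rescaled afterwards, matching how training patches were normalized.
    Tiles contribute only their context-valid interior and are cross-faded
    inside the overlap region.

    Channel attention pools features globally, so a tile-local forward
    pass would gate channels differently from a whole-image pass.  With
    ``lock_gates`` (default) the gates are first captured on a reference
    forward pass — the whole image when it is small enough, else a
    central crop of up to ``gate_reference_extent`` per axis — and reused
    for every tile, which makes tiling consistent with the untiled
    result up to the (overlap-controlled) convolutional context.
    """
    cfg = model.config
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != cfg.dims:
        raise ValueError(f"expected a {cfg.dims}D image, got shape {image.shape}")
    top = image.max()
    scale = top if top > 0 else 1.0
    norm = (image / scale).astype(np.float32)
    div = 2 ** cfg.unet_depth
    if tile_shape is None:
        out = model(norm[None, None]).data[0, 0]
        return out.astype(np.float64) * scale
    tile_shape = tuple(int(t) for t in (tile_shape if np.iterable(tile_shape)
                                        else (tile_shape,) * cfg.dims))
    if any(t % div for t in tile_shape):
        raise ValueError(f"tile shape {tile_shape} must be divisible by {div}")
    if any(t > s for t, s in zip(tile_shape, image.shape)):
        raise ValueError("tile larger than image; pass tile_shape=None")
    if any(overlap >= t for t in tile_shape):
        raise ValueError("overlap must be smaller than the tile")
    if any((t - overlap) % div for t in tile_shape):
        raise ValueError(
            f"tile step (tile - overlap) must be a multiple of 2^depth={div} "
            "so that every tile stays aligned with the pooling grid")
    step = tuple(t - overlap for t in tile_shape)
    starts = []
    for s, t, st in zip(image.shape, tile_shape, step):
        pos = list(range(0, max(s - t, 0) + 1, st))
        if pos[-1] + t < s:
            pos.append(s - t)
        starts.append(pos)
    cabs = _all_cabs(model)
    if lock_gates:
        ref_slices = []
        for s, d in zip(image.shape, (div,) * cfg.dims):
            extent = min(s, gate_reference_extent) // d * d
            lo = (s - extent) // 2
            ref_slices.append(slice(lo, lo + extent))
        model(Tensor(norm[tuple(ref_slices)][None, None]))
        for cab in cabs:
            cab.frozen_gate = cab.last_gate
    acc = np.zeros(image.shape, dtype=np.float64)
    wacc = np.zeros(image.shape, dtype=np.float64)
    mesh = np.meshgrid(*[np.arange(len(p)) for p in starts], indexing="ij")
    for flat in zip(*[m.ravel() for m in mesh]):
        corner = tuple(starts[d][i] for d, i in enumerate(flat))
        sl = tuple(slice(c, c + t) for c, t in zip(corner, tile_shape))
        interior = [(c > 0, c + t < s)
                    for c, t, s in zip(corner, tile_shape, image.shape)]
        window = _blend_window(tile_shape, overlap, interior)
        pred = model(norm[sl][None, None]).data[0, 0].astype(np.float64)
        acc[sl] += pred * window
        wacc[sl] += window
    if lock_gates:
        for cab in cabs:
            cab.frozen_gate = None
    return acc / wacc * scale


def predict_stack(model: UNetRCAN, stack: np.ndarray, tile_shape=None,
                  overlap: int = 32) -> np.ndarray:
    """Frame-by-frame (2D model) or whole-volume (3D model) restoration."""
    stack = np.asarray(stack, dtype=np.float64)
    if model.config.dims == 3 or stack.ndim == model.config.dims:
        if stack.ndim == model.config.dims:
            return predict(model, stack, tile_shape, overlap)
    return np.stack([predict(model, frame, tile_shape, overlap)
                     for frame in stack])


# ---------------------------------------------------------------------------
# statsmodels-style front door
# ---------------------------------------------------------------------------

class RestorationModel:
    """Restoration problem = training patches + network configuration.

    ``fit()`` trains the two-step network and returns a
    :class:`~sted_restore.train.RestorationResults` carrying the trained
    network, the loss history and a ``summary()`` table.
    """

    def __init__(self, noisy_patches: np.ndarray, gt_patches: np.ndarray,
                 config: NetworkConfig | None = None):
        noisy_patches = np.asarray(noisy_patches, dtype=np.float64)
        gt_patches = np.asarray(gt_patches, dtype=np.float64)
        if noisy_patches.shape != gt_patches.shape:
            raise ValueError("noisy and ground-truth patch arrays must match")
        self.noisy = noisy_patches
        self.gt = gt_patches
        self.config = config or NetworkConfig(dims=noisy_patches.ndim - 1)

    @classmethod
    def from_patch_set(cls, patch_set, config: NetworkConfig | None = None
                       ) -> "RestorationModel":
        return cls(patch_set.noisy, patch_set.gt, config)

    def fit(self, train_config=None, loss_config=None, verbose: bool = False):
        from .train import fit_network  # deferred: train imports this module
        return fit_network(self, train_config, loss_config, verbose=verbose)
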