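"""Losses and the training loop.

The training objective combines a Charbonnier penalty with an edge
penalty on Laplacian-filtered images,

    L_char(y, ŷ) = mean( sqrt((y − ŷ)² + ε²) ),         ε = 1e-3
    L_edge(y, ŷ) = mean( sqrt((Δy − Δŷ)² + ε²) ),
    L(y, ŷ)      = L_char + α · L_edge,                  α = 0.05.

The per-pixel mean form (the multi-stage restoration convention) is the
default; the global-norm form sqrt(‖y−ŷ‖² + ε²) is available via
``reduction='global'``.  Both satisfy L(y, y) = ε(1 + α).  The Laplacian
is a 4-neighbour (2D) / 6-neighbour (3D) stencil with replicate borders,
so a constant offset between the images leaves the edge loss at ε.

Optimization uses Adam with default moments, batch size 1 and a single
cosine-annealing cycle from the initial learning rate down to ``min_lr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import Tensor, Adam, add, laplacian, mean, mul, sqrt, square, tsum
from .model import RestorationModel, UNetRCAN, predict, predict_stack

EPSILON = 1e-3
ALPHA = 0.05


@dataclass
class LossConfig:
    epsilon: float = EPSILON
    alpha: float = ALPHA
    reduction: str = "mean"          # 'mean' (per pixel) or 'global' (norm)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.reduction not in ("mean", "global"):
            raise ValueError("reduction must be 'mean' or 'global'")


@dataclass
class TrainConfig:
    initial_lr: float = 1e-4
    min_lr: float = 1e-6
    batch_size: int = 1
    epochs: int = 200                # full-scale 2D default; 100 for 3D
    seed: int = 0
    val_fraction: float = 0.1
    shuffle: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0 or self.min_lr < 0:
            raise ValueError("learning rates must be positive")


def _charbonnier_core(diff, epsilon: float, reduction: str) -> Tensor:
    if reduction == "mean":
        return mean(sqrt(add(square(diff), epsilon ** 2)))
    return sqrt(add(tsum(square(diff)), epsilon ** 2))


def charbonnier_loss(y, y_hat, epsilon: float = EPSILON,
                     reduction: str = "mean") -> Tensor:
    """Smooth L1-like fidelity term; exactly ε when y == ŷ."""
    y, y_hat = Tensor.as_tensor(y), Tensor.as_tensor(y_hat)
    if y.data.shape != y_hat.data.shape:
        raise ValueError(f"shape mismatch: {y.data.shape} vs {y_hat.data.shape}")
    return _charbonnier_core(y - y_hat, epsilon, reduction)


def edge_loss(y, y_hat, epsilon: float = EPSILON, spatial_dims: int | None = None,
              reduction: str = "mean") -> Tensor:
    """Charbonnier distance between Laplacian-filtered images."""
    y, y_hat = Tensor.as_tensor(y), Tensor.as_tensor(y_hat)
    if y.data.shape != y_hat.data.shape:
        raise ValueError(f"shape mismatch: {y.data.shape} vs {y_hat.data.shape}")
    nd = y.data.ndim
    if spatial_dims is None:
        spatial_dims = nd if nd <= 3 else nd - 2
    lead = nd - spatial_dims
    if lead == 0:
        reshape = (1, 1) + y.data.shape
        y = Tensor(y.data.reshape(reshape), parents=(y,),
                   backward=lambda g, t=y: t._accumulate(g.reshape(t.data.shape)))
        y_hat = Tensor(y_hat.data.reshape(reshape), parents=(y_hat,),
                       backward=lambda g, t=y_hat: t._accumulate(
                           g.reshape(t.data.shape)))
    diff = laplacian(y, spatial_dims) - laplacian(y_hat, spatial_dims)
    return _charbonnier_core(diff, epsilon, reduction)


def total_loss(y, y_hat, loss_config: LossConfig | None = None,
               spatial_dims: int | None = None) -> Tensor:
    """L_char + α · L_edge."""
    cfg = loss_config or LossConfig()
    l_char = charbonnier_loss(y, y_hat, cfg.epsilon, cfg.reduction)
    l_edge = edge_loss(y, y_hat, cfg.epsilon, spatial_dims, cfg.reduction)
    return add(l_char, mul(l_edge, cfg.alpha))


def cosine_lr(epoch: int, total_epochs: int, initial_lr: float = 1e-4,
              min_lr: float = 1e-6) -> float:
    """Single-cycle cosine annealing: initial_lr at epoch 0, min_lr at the end."""
    if not 0 <= epoch < total_epochs:
        raise ValueError("epoch must satisfy 0 <= epoch < total_epochs")
    if total_epochs == 1:
        return initial_lr
    frac = epoch / (total_epochs - 1)
    return min_lr + 0.5 * (initial_lr - min_lr) * (1.0 + np.cos(np.pi * frac))


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class RestorationResults:
    """Trained network plus its training diagnostics."""

    model: UNetRCAN
    history: pd.DataFrame            # epoch, lr, train_loss, val_loss
    best_epoch: int
    train_config: TrainConfig
    loss_config: LossConfig
    val_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def final_train_loss(self) -> float:
        return float(self.history["train_loss"].iloc[-1])

    @property
    def best_val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[self.best_epoch])

    def predict(self, image: np.ndarray, tile_shape=None, overlap: int = 32
                ) -> np.ndarray:
        return predict(self.model, image, tile_shape, overlap)

    def predict_stack(self, stack: np.ndarray, tile_shape=None,
                      overlap: int = 32) -> np.ndarray:
        return predict_stack(self.model, stack, tile_shape, overlap)

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "UNet-RCAN restoration results",
            "=" * 46,
            f"{'dims':<28}{cfg.dims}",
            f"{'parameters':<28}{self.model.num_parameters():,}",
            f"{'U-Net filters':<28}{cfg.unet_base_filters} x depth {cfg.unet_depth}",
            f"{'RCAN':<28}{cfg.n_residual_groups} RG x {cfg.n_cab_per_group} CAB"
            f" @ {cfg.rcan_filters}",
            f"{'epochs':<28}{len(h)}",
            f"{'initial lr':<28}{self.train_config.initial_lr:g}",
            f"{'loss':<28}Charbonnier + {self.loss_config.alpha:g} * edge"
            f" (eps={self.loss_config.epsilon:g})",
            f"{'first/last train loss':<28}{h['train_loss'].iloc[0]:.5f} / "
            f"{h['train_loss'].iloc[-1]:.5f}",
            f"{'best val loss (epoch)':<28}{self.best_val_loss:.5f}"
            f" ({self.best_epoch})",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, directory):
        directory = self.model.save(directory)
        self.history.to_csv(directory / "history.csv", index=False)
        return directory


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def fit_network(problem: RestorationModel,
                train_config: TrainConfig | None = None,
                loss_config: LossConfig | None = None,
                verbose: bool = False) -> RestorationResults:
    """Train a UNet-RCAN on the problem's patches; fully seeded."""
    tcfg = train_config or TrainConfig()
    lcfg = loss_config or LossConfig()
    n = len(problem.noisy)
    if n == 0:
        raise ValueError("no training patches")
    from .dataset import train_val_split

    class _Idx:
        noisy, gt = problem.noisy, problem.gt

        def __len__(self):
            return n

    train_idx, val_idx = train_val_split(_Idx(), tcfg.val_fraction, tcfg.seed)
    if len(train_idx) == 0:
        raise ValueError("validation split left no training patches")
    model = UNetRCAN(problem.config)
    params = model.parameters()
    opt = Adam(params, lr=tcfg.initial_lr)
    rng = np.random.default_rng(tcfg.seed)
    dims = model.config.dims

    def batches(indices):
        for i in range(0, len(indices), tcfg.batch_size):
            yield indices[i:i + tcfg.batch_size]

    def to_batch(idx):
        x = problem.noisy[idx].astype(np.float32)[:, None]
        y = problem.gt[idx].astype(np.float32)[:, None]
        return x, y

    rows = []
    best_state, best_val, best_epoch = None, np.inf, 0
    for epoch in range(tcfg.epochs):
        opt.lr = cosine_lr(epoch, tcfg.epochs, tcfg.initial_lr, tcfg.min_lr)
        order = rng.permutation(train_idx) if tcfg.shuffle else train_idx
        losses = []
        for batch in batches(order):
            x, y = to_batch(batch)
            pred = model(Tensor(x))
            loss = total_loss(Tensor(y), pred, lcfg, spatial_dims=dims)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, patch indices "
                    f"{batch.tolist()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        val_losses = []
        for batch in batches(val_idx):
            x, y = to_batch(batch)
            pred = model(Tensor(x))
            val_losses.append(total_loss(Tensor(y), pred, lcfg,
                                         spatial_dims=dims).item())
        train_loss = float(np.mean(losses))
        val_loss = float(np.mean(val_losses)) if val_losses else train_loss
        rows.append({"epoch": epoch, "lr": opt.lr,
                     "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:4d}  lr {opt.lr:.2e}  "
                  f"train {train_loss:.5f}  val {val_loss:.5f}")
    if best_state is not None:
        model.load_state_dict(best_state)
    return RestorationResults(model=model, history=pd.DataFrame(rows),
                              best_epoch=best_epoch, train_config=tcfg,
                              loss_config=lcfg, val_indices=val_idx)
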