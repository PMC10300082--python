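"""Training patch preparation: extraction, normalization, content filtering.

The pipeline order is fixed: patches are cut at identical offsets from the
noisy and ground-truth members, each patch is normalized to its own
maximum, the L2 norm of every *normalized ground-truth* patch is computed,
norms are divided by the largest norm in the dataset, and patches whose
normalized norm falls below the content threshold (default 0.3, sensible
range 0.2–0.4) are discarded.  The max-norm patch always survives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_THRESHOLD = 0.3
PATCH_SHAPE_2D = (256, 256)
PATCH_SHAPE_3D = (16, 160, 160)   # (z, y, x)


@dataclass
class PatchSet:
    """Filtered, normalized (noisy, ground-truth) training patches."""

    noisy: np.ndarray              # (n, *patch_shape)
    gt: np.ndarray
    norms: np.ndarray              # normalized L2 norm per patch, in [0, 1]
    threshold: float
    offsets: np.ndarray            # (n, ndim) corner offset of each patch
    source_ids: np.ndarray         # source image index per patch
    empty_flags: np.ndarray = field(default=None)  # all-zero patches

    def __post_init__(self):
        if self.empty_flags is None:
            self.empty_flags = np.zeros(len(self.noisy), dtype=bool)

    def __len__(self) -> int:
        return len(self.noisy)

    @property
    def patch_shape(self) -> tuple:
        return self.noisy.shape[1:]

    def save(self, path) -> Path:
        """Persist as a compressed archive with a JSON manifest."""
        path = Path(path)
        manifest = json.dumps({"threshold": self.threshold,
                               "patch_shape": list(self.patch_shape),
                               "n_patches": len(self)})
        np.savez_compressed(path, noisy=self.noisy, gt=self.gt,
                            norms=self.norms, offsets=self.offsets,
                            source_ids=self.source_ids,
                            empty_flags=self.empty_flags,
                            manifest=np.array(manifest))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path) -> "PatchSet":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            return cls(noisy=z["noisy"], gt=z["gt"], norms=z["norms"],
                       threshold=manifest["threshold"], offsets=z["offsets"],
                       source_ids=z["source_ids"], empty_flags=z["empty_flags"])


def extract_patches(noisy: np.ndarray, gt: np.ndarray, patch_shape,
                    stride=None, max_patches: int | None = None,
                    seed: int | None = None, mode: str = "random"
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut aligned patch pairs; returns (noisy, gt, offsets).

    ``mode='tile'`` walks a regular grid with the given stride (default:
    non-overlapping); ``mode='random'`` draws ``max_patches`` uniform
    offsets with the given seed.
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if noisy.shape != gt.shape:
        raise ValueError("noisy and ground-truth images must share geometry")
    patch_shape = tuple(int(p) for p in patch_shape)
    if len(patch_shape) != noisy.ndim:
        raise ValueError(f"patch rank {len(patch_shape)} does not match "
                         f"image rank {noisy.ndim}")
    if any(p > s for p, s in zip(patch_shape, noisy.shape)):
        raise ValueError(f"patch {patch_shape} larger than image {noisy.shape}")
    limits = [s - p for s, p in zip(noisy.shape, patch_shape)]
    if mode == "tile":
        stride = tuple(int(s) for s in (stride or patch_shape))
        axes = [np.arange(0, lim + 1, st) for lim, st in zip(limits, stride)]
        mesh = np.meshgrid(*axes, indexing="ij")
        offsets = np.stack([m.ravel() for m in mesh], axis=1)
        if max_patches is not None:
            offsets = offsets[:max_patches]
    elif mode == "random":
        if max_patches is None:
            raise ValueError("random mode requires max_patches")
        rng = np.random.default_rng(seed)
        offsets = np.stack([rng.integers(0, lim + 1, size=max_patches)
                            for lim in limits], axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    slicers = [tuple(slice(o, o + p) for o, p in zip(off, patch_shape))
               for off in offsets]
    return (np.stack([noisy[s] for s in slicers]),
            np.stack([gt[s] for s in slicers]),
            offsets.astype(np.int64))


def normalize_patch(patch: np.ndarray) -> tuple[np.ndarray, bool]:
    """Divide by the patch maximum; all-zero patches pass through flagged."""
    patch = np.asarray(patch, dtype=np.float64)
    top = patch.max(initial=0.0)
    if top <= 0:
        return patch.copy(), True
    return patch / top, False


def filter_patches(noisy_patches: np.ndarray, gt_patches: np.ndarray,
                   threshold: float = DEFAULT_THRESHOLD,
                   offsets: np.ndarray | None = None,
                   source_ids: np.ndarray | None = None) -> PatchSet:
    """Normalize patches, rank by ground-truth content, filter.

    Norms are computed on the normalized ground-truth member (content
    ranking must not be inflated by noise) and divided by the maximum norm
    of the dataset, so the best patch always has normalized norm 1 and
    survives any threshold ≤ 1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    noisy_patches = np.asarray(noisy_patches, dtype=np.float64)
    gt_patches = np.asarray(gt_patches, dtype=np.float64)
    if len(noisy_patches) == 0:
        raise ValueError("empty patch list")
    n = len(noisy_patches)
    if offsets is None:
        offsets = np.zeros((n, noisy_patches.ndim - 1), dtype=np.int64)
    if source_ids is None:
        source_ids = np.zeros(n, dtype=np.int64)
    norm_noisy = np.empty_like(noisy_patches)
    norm_gt = np.empty_like(gt_patches)
    empty = np.zeros(n, dtype=bool)
    for i in range(n):
        norm_noisy[i], _ = normalize_patch(noisy_patches[i])
        norm_gt[i], empty[i] = normalize_patch(gt_patches[i])
    norms = np.linalg.norm(norm_gt.reshape(n, -1), axis=1)
    top = norms.max()
    if top <= 0:
        raise ValueError("all patches are empty; nothing to rank")
    norms = norms / top
    keep = norms >= threshold
    return PatchSet(noisy=norm_noisy[keep], gt=norm_gt[keep],
                    norms=norms[keep], threshold=threshold,
                    offsets=np.asarray(offsets)[keep],
                    source_ids=np.asarray(source_ids)[keep],
                    empty_flags=empty[keep])


def build_patch_set(pairs, patch_shape, n_patches: int,
                    threshold: float = DEFAULT_THRESHOLD, seed: int = 0,
                    mode: str = "random") -> PatchSet:
    """Extract + normalize + filter across several (noisy, gt) image pairs."""
    per_pair = int(np.ceil(n_patches / len(pairs)))
    all_noisy, all_gt, all_off, all_src = [], [], [], []
    for i, (noisy, gt) in enumerate(pairs):
        pn, pg, off = extract_patches(noisy, gt, patch_shape,
                                      max_patches=per_pair,
                                      seed=seed + i, mode=mode)
        all_noisy.append(pn)
        all_gt.append(pg)
        all_off.append(off)
        all_src.append(np.full(len(pn), i, dtype=np.int64))
    return filter_patches(np.concatenate(all_noisy)[:n_patches],
                          np.concatenate(all_gt)[:n_patches],
                          threshold=threshold,
                          offsets=np.concatenate(all_off)[:n_patches],
                          source_ids=np.concatenate(all_src)[:n_patches])


def train_val_split(patch_set: PatchSet, val_fraction: float = 0.1,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 90/10 (by default) split; returns (train_idx, val_idx)."""
    n = len(patch_set)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])
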