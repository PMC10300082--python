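"""Rigid xy-drift correction by Fourier-domain cross-correlation.

The drift between a noisy acquisition and its high-SNR partner is the lag
maximizing their circular normalized cross-correlation, computed with
forward/inverse FFTs on mean-subtracted images.  Shifting back aligns the
pair; the vacated border is zero-filled and reported as an invalid margin
mask so downstream patch extraction can avoid wrapped or empty content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Drift:
    """Estimated rigid offset of image b relative to image a."""

    dy: float
    dx: float
    peak_value: float     # normalized correlation at the maximum, in [-1, 1]

    @property
    def integer(self) -> tuple[int, int]:
        return int(round(self.dy)), int(round(self.dx))


def _wrap(index: int, n: int) -> int:
    return index - n if index > n // 2 else index


def estimate_drift(img_a: np.ndarray, img_b: np.ndarray,
                   subpixel: bool = False) -> Drift:
    """Lag (dy, dx) such that ``img_b ≈ roll(img_a, (dy, dx))``."""
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("estimate_drift expects single 2D frames")
    a0, b0 = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise ValueError("constant image: cross-correlation is undefined")
    corr = np.fft.ifftn(np.fft.fftn(b0) * np.conj(np.fft.fftn(a0))).real
    corr /= na * nb
    py, px = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[py, px])
    dy, dx = float(_wrap(py, a.shape[0])), float(_wrap(px, a.shape[1]))
    if subpixel:
        dy += _parabolic_offset(corr[(py - 1) % a.shape[0], px], peak,
                                corr[(py + 1) % a.shape[0], px])
        dx += _parabolic_offset(corr[py, (px - 1) % a.shape[1]], peak,
                                corr[py, (px + 1) % a.shape[1]])
    return Drift(dy=dy, dx=dx, peak_value=peak)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2 * c0 + cp
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def apply_drift(img: np.ndarray, drift: Drift) -> tuple[np.ndarray, np.ndarray]:
    """Translate ``img`` by −drift; returns (aligned image, valid mask).

    Wrapped borders are zeroed out and flagged invalid in the mask, whose
    invalid margin width equals |drift| on each shifted edge.
    """
    img = np.asarray(img, dtype=np.float64)
    dy, dx = drift.integer
    if abs(dy) > img.shape[0] // 2 or abs(dx) > img.shape[1] // 2:
        raise ValueError(f"drift {dy, dx} exceeds half the image extent")
    out = np.roll(img, (-dy, -dx), axis=(0, 1))
    mask = np.ones_like(out, dtype=bool)
    if dy > 0:
        out[-dy:, :] = 0.0
        mask[-dy:, :] = False
    elif dy < 0:
        out[:-dy, :] = 0.0
        mask[:-dy, :] = False
    if dx > 0:
        out[:, -dx:] = 0.0
        mask[:, -dx:] = False
    elif dx < 0:
        out[:, :-dx] = 0.0
        mask[:, :-dx] = False
    return out, mask


def register_stack(noisy: np.ndarray, gt: np.ndarray,
                   subpixel: bool = False) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-frame drift estimation and correction of a noisy stack.

    Each noisy frame is aligned onto its ground-truth partner
    independently (no temporal smoothing).  Returns the aligned stack and
    a report table (frame, dy, dx, peak).
    """
    noisy = np.asarray(noisy, float)
    gt = np.asarray(gt, float)
    if noisy.ndim == 2:
        noisy, gt = noisy[None], gt[None]
    if noisy.shape != gt.shape:
        raise ValueError("noisy and ground-truth stacks must share geometry")
    rows, frames = [], []
    for t in range(noisy.shape[0]):
        d = estimate_drift(gt[t], noisy[t], subpixel=subpixel)
        aligned, _ = apply_drift(noisy[t], d)
        frames.append(aligned)
        rows.append({"frame": t, "dy": d.dy, "dx": d.dx, "peak": d.peak_value})
    return np.stack(frames), pd.DataFrame(rows)
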