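"""Semi-synthetic noise calibration.

A high-SNR acquisition can stand in for many noisy ones: scale it by a
coefficient λ and draw a Poisson count at every pixel using the scaled
value as the expectation.  λ is fitted so that the histogram of the
synthetic noisy image matches the histogram of a real fast acquisition in
mean squared error, after discarding the first (empty/background) bin and
normalizing each histogram to its own maximum.  The fit is repeated
``n_repeats`` times (default 5) with fresh Poisson draws and the λ
estimates are averaged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass
class NoiseCalibration:
    """Result of the λ histogram fit."""

    lam: float
    n_repeats: int = 5
    bin_width: float = 1.0
    per_repeat_lams: list = field(default_factory=list)
    fit_mse: float = float("nan")

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "NoiseCalibration":
        return cls(**json.loads(Path(path).read_text()))


def poissonize(high_snr: np.ndarray, lam: float, seed: int = 0) -> np.ndarray:
    """Scale by λ and Poisson-sample every pixel."""
    img = np.asarray(high_snr, dtype=np.float64)
    if lam <= 0:
        raise ValueError("lam must be > 0")
    neg = np.argwhere(img < 0)
    if neg.size:
        raise ValueError(f"negative pixel at index {tuple(neg[0])}; "
                         "input must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(lam * img).astype(np.float64)


def histogram_distance(img_a: np.ndarray, img_b: np.ndarray,
                       bin_width: float = 1.0) -> float:
    """MSE between max-normalized count histograms, first bin discarded.

    Both images are binned on a common grid spanning [0, max(both)], so the
    distance is symmetric and invariant to a common rescaling of the grid.
    """
    a = np.asarray(img_a, dtype=np.float64).ravel()
    b = np.asarray(img_b, dtype=np.float64).ravel()
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("images must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    top = max(a.max(initial=0.0), b.max(initial=0.0))
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    ha, hb = ha[1:].astype(float), hb[1:].astype(float)  # drop the first bin
    if ha.size == 0 or (ha.max() == 0 and hb.max() == 0):
        raise ValueError("histograms are empty after removing the first bin")
    if ha.max() > 0:
        ha /= ha.max()
    if hb.max() > 0:
        hb /= hb.max()
    return float(np.mean((ha - hb) ** 2))


def default_search_grid(high_snr: np.ndarray, reference: np.ndarray,
                        n_points: int = 25) -> np.ndarray:
    """Log-spaced λ grid over two decades around the count-ratio guess."""
    guess = float(np.mean(reference)) / max(float(np.mean(high_snr)), 1e-30)
    guess = max(guess, 1e-12)
    return np.geomspace(guess / 10.0, guess * 10.0, n_points)


def fit_lambda(high_snr: np.ndarray, reference: np.ndarray,
               search_grid: np.ndarray | None = None, n_repeats: int = 5,
               seed: int = 0, bin_width: float = 1.0,
               refine: bool = True) -> NoiseCalibration:
    """Fit the Poisson scaling coefficient λ by histogram matching.

    Each repeat scans the search grid, drawing a fresh poissonized image
    per candidate, picks the MSE-minimizing λ and (optionally) refines it
    on a finer local grid between the best point's neighbours.  The final
    λ is the mean over repeats.
    """
    high_snr = np.asarray(high_snr, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    grid = (np.asarray(search_grid, dtype=float) if search_grid is not None
            else default_search_grid(high_snr, reference))
    grid = np.sort(grid)
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    lams, mses = [], []
    for rep in range(n_repeats):
        rep_rng = seeds[rep]
        child = iter(rep_rng.spawn(len(grid) + 32))
        scores = [histogram_distance(
            poissonize(high_snr, lam, next(child).generate_state(1)[0] % (2 ** 31)),
            reference, bin_width) for lam in grid]
        best = int(np.argmin(scores))
        if best in (0, len(grid) - 1):
            warnings.warn("λ fit attained the search-grid boundary; widen "
                          "the grid for a reliable estimate", stacklevel=2)
        best_lam, best_mse = float(grid[best]), float(scores[best])
        if refine and 0 < best < len(grid) - 1:
            fine = np.geomspace(grid[best - 1], grid[best + 1], 11)
            fine_scores = [histogram_distance(
                poissonize(high_snr, lam,
                           next(child).generate_state(1)[0] % (2 ** 31)),
                reference, bin_width) for lam in fine]
            fb = int(np.argmin(fine_scores))
            if fine_scores[fb] < best_mse:
                best_lam, best_mse = float(fine[fb]), float(fine_scores[fb])
        lams.append(best_lam)
        mses.append(best_mse)
    return NoiseCalibration(lam=float(np.mean(lams)), n_repeats=n_repeats,
                            bin_width=bin_width, per_repeat_lams=lams,
                            fit_mse=float(np.mean(mses)))
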