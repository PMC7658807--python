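"""Actin remodeling metrics for single-plane time-lapse stacks.

A remodeling filament network decorrelates over time while a stabilized
one does not.  The two headline statistics quantify that contrast: for
each frame, the mean Pearson correlation against all other frames, and
the mean per-pixel absolute difference against all other frames; the
stack-level summaries are the unweighted means over frames.  A static
(actin-stabilized) cell scores correlation 1 and difference 0; a rapidly
remodeling one scores lower correlation and higher difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZeroVarianceError",
    "TimeLapseStack",
    "DynamicsResult",
    "corr2d",
    "mean_abs_diff",
    "framewise_dynamics",
    "correlation_by_lag",
    "overlay_rgb",
]


class ZeroVarianceError(ValueError):
    """Correlation is undefined on a constant pixel selection."""


@dataclass
class TimeLapseStack:
    """Ordered grayscale frames of one cell at a fixed frame interval.

    ``frames`` is a (T, H, W) array; ``cell_mask`` optionally restricts
    every metric to the cell's pixels (default: whole frame).
    """

    frames: np.ndarray
    frame_interval: float = 2.5
    cell_mask: np.ndarray | None = None
    cell_id: str = ""
    genotype: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T>=2, H, W) array")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask).astype(bool)
            if self.cell_mask.shape != self.frames.shape[1:]:
                raise ValueError("cell_mask shape must match frame shape")
            if self.cell_mask.sum() < 2:
                raise ValueError("cell_mask must select >= 2 pixels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class DynamicsResult:
    """Per-frame and stack-level dynamics statistics for one cell."""

    per_frame_correlation: np.ndarray
    per_frame_difference: np.ndarray
    stack_correlation: float
    stack_difference: float
    n_frames: int
    difference_mode: str = "absolute_raw"


def _select(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match image shape")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need >= 2 selected pixels")
    return a, b


def corr2d(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation between two images over the (masked) pixels.

    Symmetric in its arguments and invariant under positive affine
    transforms of either image.  Raises :class:`ZeroVarianceError` when
    either selection is constant, rather than silently returning 0.
    """
    x, y = _select(a, b, mask)
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(x @ x)
    sy = np.sqrt(y @ y)
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined: constant pixel selection")
    return float(np.clip((x @ y) / (sx * sy), -1.0, 1.0))


def mean_abs_diff(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
    squared: bool = False,
) -> float:
    """Mean per-pixel absolute (or, optionally, squared) difference."""
    x, y = _select(a, b, mask)
    d = np.abs(x - y)
    if squared:
        d = d * d
    return float(d.mean())


def framewise_dynamics(
    stack: TimeLapseStack,
    normalize: bool = False,
    squared: bool = False,
) -> DynamicsResult:
    """All-pairs dynamics statistics for a time-lapse stack.

    For frame i, the per-frame correlation (difference) is the mean of
    ``corr2d`` (``mean_abs_diff``) between frame i and every other frame
    j != i; stack summaries are unweighted means over frames.

    Parameters
    ----------
    normalize
        Divide each frame by its own mean intensity before the difference
        computation (correlation is affine-invariant and never normalized).
    squared
        Use squared instead of absolute per-pixel differences.
    """
    T = stack.n_frames
    mask = stack.cell_mask
    if mask is not None:
        X = stack.frames[:, mask]
    else:
        X = stack.frames.reshape(T, -1)

    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ZeroVarianceError(
            f"frame {bad[0]} is constant under the mask; correlation undefined"
        )

    C = np.corrcoef(X)
    np.fill_diagonal(C, 0.0)
    per_corr = C.sum(axis=1) / (T - 1)

    Xd = X / X.mean(axis=1, keepdims=True) if normalize else X
    D = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            d = np.abs(Xd[i] - Xd[j])
            D[i, j] = D[j, i] = (d * d).mean() if squared else d.mean()
    per_diff = D.sum(axis=1) / (T - 1)

    mode = ("squared" if squared else "absolute") + (
        "_mean_normalized" if normalize else "_raw")
    return DynamicsResult(
        per_frame_correlation=per_corr,
        per_frame_difference=per_diff,
        stack_correlation=float(per_corr.mean()),
        stack_difference=float(per_diff.mean()),
        n_frames=T,
        difference_mode=mode,
    )


def correlation_by_lag(stack: TimeLapseStack) -> tuple[np.ndarray, np.ndarray]:
    """Mean frame correlation as a function of time interval.

    Optional companion output to :func:`framewise_dynamics`: the mean of
    ``corr2d`` over all frame pairs at each lag, against the lag in the
    stack's time units.  Useful for decay-curve presentations.
    """
    T = stack.n_frames
    mask = stack.cell_mask
    X = stack.frames[:, mask] if mask is not None else stack.frames.reshape(T, -1)
    if (X.std(axis=1) == 0.0).any():
        raise ZeroVarianceError("constant frame; correlation undefined")
    C = np.corrcoef(X)
    lags = np.arange(1, T)
    means = np.array([np.diagonal(C, offset=int(k)).mean() for k in lags])
    return lags * stack.frame_interval, means


def overlay_rgb(stack: TimeLapseStack, indices: tuple[int, int, int]) -> np.ndarray:
    """Three time points as the R, G and B channels of one image.

    Each selected frame is min-max scaled to [0, 1] independently; a
    static cell therefore renders as a near-white overlay while remodeled
    regions show as colored fringes.  A constant frame (zero range) maps
    to all-zero by convention.
    """
    if len(indices) != 3:
        raise ValueError("exactly three frame indices required")
    T = stack.n_frames
    out = np.zeros((*stack.frames.shape[1:], 3))
    for ch, idx in enumerate(indices):
        if not (0 <= idx < T):
            raise IndexError(f"frame index {idx} out of range [0, {T})")
        f = stack.frames[idx]
        lo, hi = f.min(), f.max()
        if hi > lo:
            out[..., ch] = (f - lo) / (hi - lo)
    return out
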