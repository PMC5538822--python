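"""FRAP trace normalization and single-exponential recovery fitting.

A fluorescence-recovery-after-photobleaching experiment records the
intensity of a bleached region of interest (ROI) and of the whole nucleus
over time. Acquisition itself photobleaches the cell, so the ROI series is
first double-normalized,

    I(t)     = (ROI(t) / ROI(0)) / (total(t) / total(0))
    Inorm(t) = (I(t) - I(bleach)) / (I(0) - I(bleach)),

which pins the pre-bleach level to 1 and the first post-bleach frame to 0
while cancelling whole-cell acquisition bleaching. The normalized recovery
is then fit per cell with the single exponential

    Y(x) = Ymax * (1 - exp(-(ln 2 / t_half) * (x - x0))),

where ``t_half`` is the recovery half-time in seconds and the plateau
``Ymax`` is the mobile fraction — the part of the protein pool that
exchanges on the experiment's timescale.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "FrapFitResult",
    "FrapConditionSummary",
    "recovery_model",
    "normalize_trace",
    "fit_recovery",
    "summarize_frap",
]


@dataclasses.dataclass(frozen=True)
class FrapTrace:
    """Raw ROI and whole-nucleus intensity series for one cell.

    ``reference_index`` marks the pre-bleach frame defining I(0);
    ``bleach_index`` marks the first post-bleach frame defining I(bleach).
    """

    time: np.ndarray
    roi: np.ndarray
    total: np.ndarray
    reference_index: int
    bleach_index: int

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        roi = np.asarray(self.roi, dtype=float)
        total = np.asarray(self.total, dtype=float)
        if not (time.shape == roi.shape == total.shape) or time.ndim != 1:
            raise ValueError("time, roi and total must be 1-D arrays of equal length")
        if not 0 <= self.reference_index < self.bleach_index <= time.size - 1:
            raise ValueError("need reference_index < bleach_index within the series")
        if roi[self.reference_index] <= 0 or total[self.reference_index] <= 0:
            raise ValueError("intensities at the reference frame must be positive")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "roi", roi)
        object.__setattr__(self, "total", total)


@dataclasses.dataclass(frozen=True)
class NormalizedTrace:
    """Double-normalized trace; time is measured relative to the bleach."""

    time: np.ndarray       # seconds relative to the bleach frame
    inorm: np.ndarray      # dimensionless; 0 at bleach, 1 at reference
    interval: float        # sampling interval (s)


@dataclasses.dataclass(frozen=True)
class FrapFitResult:
    """Single-exponential fit of one recovery curve."""

    ymax: float            # plateau = mobile fraction
    t_half: float          # recovery half-time (s)
    x0: float              # bleach-time offset (s, relative to bleach frame)
    rss: float
    converged: bool


@dataclasses.dataclass(frozen=True)
class FrapConditionSummary:
    condition: str
    n: int                       # converged fits included
    t_half_mean: float
    t_half_sd: float
    mobile_pct_mean: float       # mobile fraction as a percentage
    mobile_pct_sd: float


def recovery_model(x: np.ndarray, ymax: float, t_half: float, x0: float) -> np.ndarray:
    """Single-exponential recovery ``Ymax * (1 - exp(-(ln2/t_half)(x - x0)))``."""
    return ymax * (1.0 - np.exp(-(math.log(2) / t_half) * (x - x0)))


def normalize_trace(trace: FrapTrace, prebleach: str = "mean") -> NormalizedTrace:
    """Double-normalize a raw trace.

    The ROI series is divided by its pre-bleach level, corrected by the
    whole-nucleus ratio (removing acquisition photobleaching), then mapped
    affinely so the pre-bleach level is 1 and the first post-bleach frame
    is 0. ``prebleach="mean"`` (default) uses the mean over all pre-bleach
    frames as I(0); ``"single"`` uses the reference frame alone.
    """
    if prebleach not in ("mean", "single"):
        raise ValueError("prebleach must be 'mean' or 'single'")
    if np.any(trace.total <= 0):
        raise ValueError("whole-nucleus intensities must be positive")
    pre = slice(0, trace.bleach_index)
    roi0 = trace.roi[pre].mean() if prebleach == "mean" else trace.roi[trace.reference_index]
    tot0 = trace.total[pre].mean() if prebleach == "mean" else trace.total[trace.reference_index]
    i = (trace.roi / roi0) / (trace.total / tot0)
    i0 = i[pre].mean() if prebleach == "mean" else i[trace.reference_index]
    i_bleach = i[trace.bleach_index]
    depth = i0 - i_bleach
    if depth <= 0:
        raise ValueError("no bleach depth: I(0) must exceed I(bleach)")
    inorm = (i - i_bleach) / depth
    t = trace.time - trace.time[trace.bleach_index]
    interval = float(np.median(np.diff(trace.time)))
    return NormalizedTrace(time=t, inorm=inorm, interval=interval)


def fit_recovery(norm: NormalizedTrace) -> FrapFitResult:
    """Least-squares fit of the post-bleach recovery.

    Initial guesses come from the data: Ymax from the last-quartile mean,
    t_half from the first crossing of Ymax/2, x0 from the recorded bleach
    time. Bounds keep Ymax in [0, 1.5], t_half in (0, 10x duration] and x0
    within one frame of the bleach. A fit is flagged non-converged when the
    optimizer fails or the plateau is indistinguishable from zero (the
    half-time is then unidentifiable).
    """
    post = norm.time >= 0
    x = norm.time[post]
    y = norm.inorm[post]
    if x.size < 5:
        raise ValueError("need at least 5 post-bleach points")
    duration = float(x[-1] - x[0])

    q = max(1, x.size // 4)
    ymax0 = float(np.clip(y[-q:].mean(), 1e-3, 1.5))
    above = np.nonzero(y >= ymax0 / 2)[0]
    t_half0 = float(x[above[0]]) if above.size and x[above[0]] > 0 else duration / 10
    t_half0 = float(np.clip(t_half0, 1e-6, 10 * duration))
    dt = norm.interval

    try:
        popt, pcov = curve_fit(
            recovery_model,
            x,
            y,
            p0=[ymax0, t_half0, 0.0],
            bounds=([0.0, 1e-9, -dt], [1.5, 10 * duration, dt]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return FrapFitResult(ymax=math.nan, t_half=math.nan, x0=math.nan,
                             rss=math.nan, converged=False)
    ymax, t_half, x0 = (float(v) for v in popt)
    resid = y - recovery_model(x, *popt)
    rss = float(resid @ resid)
    converged = bool(np.all(np.isfinite(pcov))) and ymax > 1e-2
    return FrapFitResult(ymax=ymax, t_half=t_half, x0=x0, rss=rss, converged=converged)


def summarize_frap(fits: Sequence[FrapFitResult], condition: str) -> FrapConditionSummary:
    """Mean and SD of half-time and mobile fraction over converged fits."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError(f"no converged fits for condition {condition!r}")
    t = np.array([f.t_half for f in ok])
    m = np.array([f.ymax for f in ok]) * 100.0
    return FrapConditionSummary(
        condition=condition,
        n=len(ok),
        t_half_mean=float(t.mean()),
        t_half_sd=float(t.std(ddof=1)) if t.size > 1 else 0.0,
        mobile_pct_mean=float(m.mean()),
        mobile_pct_sd=float(m.std(ddof=1)) if m.size > 1 else 0.0,
    )
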