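"""Ratiometric calcium quantification from two-channel fluorescence movies.

Neural activity is reported as the normalised deviation of the green/red
fluorescence ratio from its pre-stimulus baseline:

    R      = (I_green - B_green) / (I_red - B_red)
    dRR0   = (R - R0) / R0

where ``I`` is the median of the 40% brightest pixels in a circular ROI
(radius 8 px) centred on the intensity maximum of a Gaussian-smoothed image
of the neuron, ``B`` the median over a background annulus (radii 20-22 px),
and ``R0`` the mean of R over a pre-stimulus window of at least 15 s.  The
calcium-insensitive red reference cancels frame-wise intensity fluctuations
from focus changes or motion blur: any gain common to both channels divides
out of R exactly.  The dRR0 series is finally smoothed with a Gaussian of
sigma = 5 frames.

Control animals expressing calcium-insensitive GFP in place of the indicator
quantify how much apparent dRR0 the instrument itself produces; a trace
counts as real signal only when it exceeds the control mean by more than one
control standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ROISpec",
    "RatioTrace",
    "locate_roi",
    "quantify_frame",
    "compute_trace",
    "smooth_trace",
    "gfp_threshold",
    "exceeds_control",
    "bin2x2",
    "split_dual_view",
]


@dataclass
class ROISpec:
    """Geometry of the ROI and background annulus (camera pixels)."""

    radius: float = 8.0
    bg_inner: float = 20.0
    bg_outer: float = 22.0
    brightest_frac: float = 0.40
    locator_sigma: float = 2.0
    search_radius: float = 24.0  # window half-size around prev_center

    def __post_init__(self) -> None:
        if not (0 < self.radius < self.bg_inner < self.bg_outer):
            raise ValueError("require 0 < radius < bg_inner < bg_outer")
        if not (0 < self.brightest_frac <= 1):
            raise ValueError("brightest_frac must be in (0, 1]")


@dataclass
class RatioTrace:
    """Per-frame ratiometric quantities; NaN rows are gaps (invalid frames)."""

    time_s: np.ndarray
    I_green: np.ndarray
    I_red: np.ndarray
    B_green: np.ndarray
    B_red: np.ndarray
    R: np.ndarray
    R0: float
    dRR0: np.ndarray
    valid: np.ndarray
    centers: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.time_s)),
            "time_s": self.time_s,
            "I_green": self.I_green, "I_red": self.I_red,
            "B_green": self.B_green, "B_red": self.B_red,
            "R": self.R, "dRR0": self.dRR0, "valid": self.valid,
        })

    def write(self, csv_path, meta_path=None, **metadata) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        meta = {"R0": self.R0, **metadata}
        meta_path = meta_path or Path(csv_path).with_suffix(".meta.json")
        Path(meta_path).write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# ROI localisation and per-frame quantification
# ---------------------------------------------------------------------------

def locate_roi(frame, spec: ROISpec, prev_center=None):
    """Neuron centre: argmax of the Gaussian-smoothed image.

    With ``prev_center`` the search is confined to a window of half-size
    ``spec.search_radius`` around it, which keeps the tracker on a dim
    neuron even when a brighter object enters the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty image")
    smooth = gaussian_filter(frame, spec.locator_sigma)
    r0, c0 = 0, 0
    if prev_center is not None:
        w = int(round(spec.search_radius))
        pr, pc = int(round(prev_center[0])), int(round(prev_center[1]))
        r0 = max(0, pr - w)
        c0 = max(0, pc - w)
        smooth = smooth[r0:pr + w + 1, c0:pc + w + 1]
    if np.ptp(smooth) == 0:
        raise ValueError("no peak: flat image")
    idx = np.unravel_index(np.argmax(smooth), smooth.shape)
    return (idx[0] + r0, idx[1] + c0)


def _distance_grid(shape, center):
    r = np.arange(shape[0])[:, None] - center[0]
    c = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(r, c)


def quantify_frame(green, red, center, spec: ROISpec):
    """Median ROI and background intensities for one frame pair.

    The ROI pixel set comprises pixel centres within ``radius`` of
    ``center``; ``I`` is the median of the ``ceil(brightest_frac * N)``
    largest ROI intensities, ``B`` the median over the annulus with
    ``bg_inner < distance <= bg_outer``.  Raises ``ValueError`` when the
    annulus is clipped by the image edge (callers mark the frame invalid).
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green / red frame shape mismatch")
    if (center[0] - spec.bg_outer < -0.5 or center[1] - spec.bg_outer < -0.5
            or center[0] + spec.bg_outer > green.shape[0] - 0.5
            or center[1] + spec.bg_outer > green.shape[1] - 0.5):
        raise ValueError("ROI/annulus clipped by image edge")
    dist = _distance_grid(green.shape, center)
    roi = dist <= spec.radius
    annulus = (dist > spec.bg_inner) & (dist <= spec.bg_outer)
    n = int(roi.sum())
    k = math.ceil(spec.brightest_frac * n)

    def _top_median(values):
        v = np.sort(values)[::-1][:k]
        return float(np.median(v))

    return (_top_median(green[roi]), _top_median(red[roi]),
            float(np.median(green[annulus])), float(np.median(red[annulus])))


# ---------------------------------------------------------------------------
# Trace assembly
# ---------------------------------------------------------------------------

def smooth_trace(values, sigma_frames: float = 5.0):
    """Gap-aware Gaussian smoothing (kernel truncated at 4 sigma).

    The kernel is renormalised over the valid (finite) samples under it, so
    constants pass through unchanged next to gaps; gaps remain NaN.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).any():
        raise ValueError("need at least one valid sample")
    half = int(math.ceil(4 * sigma_frames))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma_frames) ** 2)
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    out = np.full_like(values, np.nan)
    out[valid] = num[valid] / den[valid]
    return out


def bin2x2(stack):
    """Mean-bin each frame 2x2 (2048^2 captures are analysed at 1024^2)."""
    stack = np.asarray(stack)
    n, h, w = stack.shape
    return stack[:, : h - h % 2, : w - w % 2].reshape(
        n, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def split_dual_view(stack, split_col: int):
    """Split a side-by-side dual-view stack into (green, red) half-stacks."""
    return stack[:, :, :split_col], stack[:, :, split_col:]


def compute_trace(
    green_stack,
    red_stack,
    spec: ROISpec | None = None,
    baseline_window: tuple[float, float] = (0.0, 15.0),
    frame_rate: float = 30.0,
    *,
    min_baseline_s: float = 15.0,
    smooth_sigma_frames: float = 5.0,
    initial_center=None,
) -> RatioTrace:
    """Full ratiometric pipeline over a two-channel stack.

    Per frame: locate the neuron on the red (calcium-insensitive) channel,
    quantify both channels, and form R = (I_green - B_green)/(I_red - B_red)
    where the denominator is positive.  R0 is the mean of valid raw R over
    ``baseline_window`` (``[0, stimulus onset)``, at least ``min_baseline_s``
    long); the dRR0 series is smoothed last.  Stacks captured at 2048^2 are
    2x2 mean-binned first.
    """
    spec = spec or ROISpec()
    green_stack = np.asarray(green_stack, dtype=float)
    red_stack = np.asarray(red_stack, dtype=float)
    if green_stack.shape != red_stack.shape:
        raise ValueError("green / red stack shape mismatch")
    if green_stack.shape[1:] == (2048, 2048):
        green_stack = bin2x2(green_stack)
        red_stack = bin2x2(red_stack)
    t0, t1 = baseline_window
    if t1 - t0 < min_baseline_s:
        raise ValueError(
            f"baseline window {t1 - t0:.1f} s shorter than the required "
            f"{min_baseline_s:.1f} s")

    n = len(green_stack)
    time_s = np.arange(n) / frame_rate
    cols = {k: np.full(n, np.nan) for k in
            ("I_green", "I_red", "B_green", "B_red", "R")}
    centers = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    prev = initial_center
    for i in range(n):
        try:
            center = locate_roi(red_stack[i], spec, prev_center=prev)
            ig, ir, bg, br = quantify_frame(green_stack[i], red_stack[i],
                                            center, spec)
        except ValueError:
            continue  # gap
        prev = center
        centers[i] = center
        cols["I_green"][i], cols["I_red"][i] = ig, ir
        cols["B_green"][i], cols["B_red"][i] = bg, br
        if ir - br > 0:
            cols["R"][i] = (ig - bg) / (ir - br)
            valid[i] = True

    in_window = (time_s >= t0) & (time_s < t1) & valid
    if not in_window.any():
        raise ValueError("no valid frames in the baseline window")
    R0 = float(np.mean(cols["R"][in_window]))
    dRR0 = np.where(valid, (cols["R"] - R0) / R0, np.nan)
    dRR0 = smooth_trace(dRR0, smooth_sigma_frames)
    return RatioTrace(time_s=time_s, R0=R0, dRR0=dRR0, valid=valid,
                      centers=centers, R=cols["R"],
                      I_green=cols["I_green"], I_red=cols["I_red"],
                      B_green=cols["B_green"], B_red=cols["B_red"])


# ---------------------------------------------------------------------------
# GFP control comparison
# ---------------------------------------------------------------------------

def gfp_threshold(control_traces, reversal_windows):
    """Apparent-activity threshold from calcium-insensitive controls.

    Pools the dRR0 samples of the control traces inside their marked
    reversal windows and returns ``(mean, sd, threshold)`` with
    ``threshold = mean + 1 * sd``.

    ``reversal_windows[i]`` is a list of ``(start_s, end_s)`` intervals for
    ``control_traces[i]``.
    """
    samples = []
    for trace, windows in zip(control_traces, reversal_windows):
        for (a, b) in windows:
            sel = (trace.time_s >= a) & (trace.time_s <= b) & \
                np.isfinite(trace.dRR0)
            samples.append(trace.dRR0[sel])
    if not samples or sum(s.size for s in samples) == 0:
        raise ValueError("no reversal-window samples in control traces")
    pooled = np.concatenate(samples)
    mean = float(np.mean(pooled))
    sd = float(np.std(pooled))
    return mean, sd, mean + sd


def exceeds_control(trace: RatioTrace, window, threshold: float) -> bool:
    """True when the trace's mean dRR0 inside ``window`` exceeds the
    GFP-control threshold — i.e. the signal is more than one control SD
    above the control mean."""
    a, b = window
    sel = (trace.time_s >= a) & (trace.time_s <= b) & np.isfinite(trace.dRR0)
    if not sel.any():
        raise ValueError("no valid samples in window")
    return float(np.mean(trace.dRR0[sel])) > threshold
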