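"""Worm segmentation, centerline extraction and the body-coordinate frame.

Each dark-field behaviour frame is thresholded (Otsu), the largest bright
connected component is taken as the worm, and its closed boundary contour is
split at the two sharpest boundary points — the head and tail tips — into two
side arcs.  Midpoints of arclength-matched side points give the centerline;
half the side-to-side distance gives the width profile.  Together with a
ventral-side convention these define body coordinates (s, w): ``s`` the
fraction of centerline arclength from the anterior tip, ``w`` the fraction
across the local body width from the ventral edge.

Locomotion velocity is the signed phase velocity of the bend wave: the
spatial shift that best aligns consecutive frames' tangent-angle-vs-arclength
profiles, in body lengths per second, positive when the wave travels
anterior-to-posterior (forward crawling).

Segmentation can fail on physically degenerate poses — most commonly when
the worm touches itself in the deep ventral bend of an omega turn — and then
returns ``ok=False`` with a reason code rather than raising, producing gaps
in downstream traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage import measure
from skimage.filters import threshold_otsu

from .synthetic import WormPosture

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "BodyCoordinate",
    "segment_frame",
    "segment_stack",
    "track_head",
    "body_to_pixel",
    "pixel_to_body",
    "wave_velocity",
    "centerline_rms_error",
    "postures_to_dataframe",
]

logger = logging.getLogger("wormloop")


@dataclass
class SegmentationConfig:
    n_points: int = 100            # resampled centerline points
    min_area_px: int = 50          # smallest blob accepted as a worm
    contour_smooth_sigma: float = 3.0  # smoothing (contour samples) before curvature
    tip_refine_window: int = 12    # raw-contour window for tip refinement
    ventral_side: int = 1          # ventral-edge convention propagated to postures
    min_tip_separation_frac: float = 0.25  # of the perimeter


@dataclass
class BodyCoordinate:
    """(s, w) body coordinates: s in [0,1] from the anterior tip along the
    centerline, w in [0,1] across the body from the ventral edge."""

    s: float
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.w <= 1.0):
            raise ValueError(f"body coordinate out of range: s={self.s}, w={self.w}")


@dataclass
class SegmentationResult:
    ok: bool
    reason: str | None = None
    boundary: np.ndarray | None = None   # closed subpixel contour, (M, 2)
    head_index: int = -1
    tail_index: int = -1
    side_a: np.ndarray | None = None     # head->tail arc, resampled
    side_b: np.ndarray | None = None
    posture: WormPosture | None = None
    mask: np.ndarray | None = None       # thresholded worm silhouette


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _contour_curvature(contour, sigma):
    """|curvature| of a closed contour after periodic Gaussian smoothing."""
    r = gaussian_filter1d(contour[:, 0], sigma, mode="wrap")
    c = gaussian_filter1d(contour[:, 1], sigma, mode="wrap")
    dr, dc = np.gradient(r), np.gradient(c)
    ddr, ddc = np.gradient(dr), np.gradient(dc)
    denom = (dr * dr + dc * dc) ** 1.5 + 1e-12
    return np.abs(dr * ddc - dc * ddr) / denom


def _refine_tip(contour, idx, window):
    """Sharpest-corner refinement: within +-window raw contour points, pick
    the point farthest from the chord joining the window ends."""
    n = len(contour)
    ids = (np.arange(idx - window, idx + window + 1)) % n
    pts = contour[ids]
    chord = pts[-1] - pts[0]
    norm = np.linalg.norm(chord)
    if norm < 1e-9:
        return idx
    u = chord / norm
    rel = pts - pts[0]
    d = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0])
    return int(ids[int(np.argmax(d))])


def _resample_polyline(points, n):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate polyline")
    u = np.linspace(0.0, s[-1], n)
    return np.stack([np.interp(u, s, points[:, 0]),
                     np.interp(u, s, points[:, 1])], axis=1)


def _refine_midline(centerline, half_width, contour, n_iter=2):
    """Recenter midline nodes between the boundary crossings of their
    normal rays.

    Midpoints of arclength-paired side points drift off the true midline on
    body bends (the inner side is shorter than the outer); intersecting each
    node's normal with the subpixel contour and taking the midpoint removes
    that bias and measures the half-width perpendicular to the body axis.
    Tips are kept fixed.
    """
    cl = centerline.copy()
    hw = half_width.copy()
    seg_p = contour
    seg_q = np.roll(contour, -1, axis=0)
    d = seg_q - seg_p
    for _ in range(n_iter):
        t_vec = np.gradient(cl, axis=0)
        t_vec /= np.linalg.norm(t_vec, axis=1, keepdims=True)
        nrm = np.stack([-t_vec[:, 1], t_vec[:, 0]], axis=1)
        for i in range(1, len(cl) - 1):
            c, n = cl[i], nrm[i]
            b = seg_p - c
            det = -n[0] * d[:, 1] + d[:, 0] * n[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                u = (-b[:, 0] * d[:, 1] + d[:, 0] * b[:, 1]) / det
                t = (n[0] * b[:, 1] - n[1] * b[:, 0]) / det
            hit = np.isfinite(u) & (t >= 0) & (t < 1)
            u = u[hit]
            pos = u[u > 0]
            neg = u[u < 0]
            if pos.size == 0 or neg.size == 0:
                continue
            u_plus, u_minus = pos.min(), neg.max()
            if u_plus - u_minus > 4.0 * max(hw[i], 1.0):
                continue  # ray escaped through a tip; keep the node
            cl[i] = c + 0.5 * (u_plus + u_minus) * n
            hw[i] = 0.5 * (u_plus - u_minus)
    return cl, hw


def segment_frame(
    frame: np.ndarray,
    config: SegmentationConfig | None = None,
    head_hint=None,
) -> SegmentationResult:
    """Segment one behaviour frame and extract the worm posture.

    The largest bright connected component above the Otsu threshold is the
    worm.  Head and tail are the two boundary points of locally extremal
    sharpness, at least a quarter perimeter apart; ``head_hint`` (a pixel
    point, e.g. ground truth or a user click on frame 0) picks which tip is
    the head — without it the assignment is arbitrary and should be fixed
    by :func:`track_head`.

    Raises ``ValueError`` on an empty/degenerate image or when no worm-like
    component exists; returns ``ok=False`` with a reason code for poses
    inconsistent with a non-self-touching worm.
    """
    config = config or SegmentationConfig()
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("expected a nonempty single-channel image")
    if np.ptp(frame) == 0:
        raise ValueError("no worm found: flat image")

    thr = threshold_otsu(frame)
    binary = frame > thr
    labels, n_lab = ndimage.label(binary)
    if n_lab == 0:
        raise ValueError("no worm found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_lab + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < config.min_area_px:
        raise ValueError("no worm found: largest component below minimum area")
    mask = labels == biggest

    # A self-touching pose (omega turn) encloses background: detect holes.
    if ndimage.binary_fill_holes(mask).sum() != mask.sum():
        return SegmentationResult(ok=False, reason="self-intersection")

    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)[:-1]  # drop duplicated closing point

    curv = _contour_curvature(contour, config.contour_smooth_sigma)
    n = len(contour)
    tip1 = int(np.argmax(curv))
    min_sep = int(config.min_tip_separation_frac * n)
    dist = np.minimum((np.arange(n) - tip1) % n, (tip1 - np.arange(n)) % n)
    far = dist >= min_sep
    if not far.any():
        return SegmentationResult(ok=False, reason="degenerate contour")
    tip2 = int(np.argmax(np.where(far, curv, -np.inf)))
    tip1 = _refine_tip(contour, tip1, config.tip_refine_window)
    tip2 = _refine_tip(contour, tip2, config.tip_refine_window)
    if tip1 == tip2:
        return SegmentationResult(ok=False, reason="degenerate contour")

    head_idx, tail_idx = tip1, tip2
    if head_hint is not None:
        hint = np.asarray(head_hint, dtype=float)
        if (np.linalg.norm(contour[tip2] - hint)
                < np.linalg.norm(contour[tip1] - hint)):
            head_idx, tail_idx = tip2, tip1

    # split the closed contour at the tips into the two side arcs, head->tail
    if head_idx < tail_idx:
        arc1 = contour[head_idx:tail_idx + 1]
        arc2 = np.vstack([contour[tail_idx:], contour[:head_idx + 1]])[::-1]
    else:
        arc1 = np.vstack([contour[head_idx:], contour[:tail_idx + 1]])
        arc2 = contour[tail_idx:head_idx + 1][::-1]

    N = config.n_points
    try:
        side_a = _resample_polyline(arc1, N)
        side_b = _resample_polyline(arc2, N)
    except ValueError:
        return SegmentationResult(ok=False, reason="degenerate contour")

    mid = 0.5 * (side_a + side_b)
    half_width = 0.5 * np.linalg.norm(side_a - side_b, axis=1)
    mid, half_width = _refine_midline(mid, half_width, contour)

    # uniform-arclength resample of the midline (interpolating the width)
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return SegmentationResult(ok=False, reason="degenerate contour")
    u = np.linspace(0.0, s[-1], N)
    centerline = np.stack([np.interp(u, s, mid[:, 0]),
                           np.interp(u, s, mid[:, 1])], axis=1)
    hw = np.interp(u, s, half_width)
    hw[0] = hw[-1] = 0.0

    try:
        posture = WormPosture(centerline, hw, ventral_side=config.ventral_side)
    except ValueError:
        # midline inconsistent with a non-self-touching worm (e.g. a coil
        # whose ribbon overlap left no hole to detect)
        return SegmentationResult(ok=False, reason="self-intersection")
    return SegmentationResult(ok=True, boundary=contour,
                              head_index=head_idx, tail_index=tail_idx,
                              side_a=side_a, side_b=side_b, posture=posture,
                              mask=mask)


def track_head(prev: SegmentationResult, cur: SegmentationResult) -> SegmentationResult:
    """Propagate head identity frame-to-frame.

    Swaps cur's head/tail assignment when its head tip is nearer prev's
    tail tip than prev's head tip, re-orienting the posture accordingly.
    The ventral-side convention is copied from prev: with the centerline
    oriented head-first on both frames, continuity of the pose means the
    physical ventral edge stays on the same side of the tangent.
    """
    if not (prev.ok and cur.ok):
        raise ValueError("track_head requires two ok segmentations")
    prev_head = prev.posture.centerline[0]
    prev_tail = prev.posture.centerline[-1]
    cur_head = cur.posture.centerline[0]
    d_head = np.linalg.norm(cur_head - prev_head)
    d_tail = np.linalg.norm(cur_head - prev_tail)
    if d_head == d_tail:
        logger.warning("track_head: ambiguous head identity, keeping current")
        return cur
    if d_head > d_tail:
        cur = SegmentationResult(
            ok=True, boundary=cur.boundary,
            head_index=cur.tail_index, tail_index=cur.head_index,
            side_a=None if cur.side_a is None else cur.side_a[::-1].copy(),
            side_b=None if cur.side_b is None else cur.side_b[::-1].copy(),
            mask=cur.mask,
            posture=WormPosture(
                cur.posture.centerline[::-1].copy(),
                cur.posture.half_width[::-1].copy(),
                ventral_side=cur.posture.ventral_side,
                time=cur.posture.time,
            ),
        )
    cur.posture.ventral_side = prev.posture.ventral_side
    return cur


def segment_stack(frames, config=None, head_hint=None, ventral_hint=None):
    """Segment every frame of a stack with head-identity propagation.

    ``head_hint`` (a pixel point) anchors the head on the first ok frame;
    ``ventral_hint`` is a pixel point known to lie on the ventral half of
    the body there (e.g. ground truth or a user click), fixing the
    ventral-side sign that then propagates with head identity.  Returns a
    list of SegmentationResult, one per frame.
    """
    results = []
    prev_ok = None
    for frame in frames:
        try:
            res = segment_frame(frame, config,
                                head_hint=head_hint if prev_ok is None else None)
        except ValueError as exc:
            res = SegmentationResult(ok=False, reason=str(exc))
        if res.ok and prev_ok is None and ventral_hint is not None:
            if pixel_to_body(res.posture, ventral_hint).w > 0.5:
                res.posture.ventral_side = -res.posture.ventral_side
        if res.ok and prev_ok is not None:
            res = track_head(prev_ok, res)
        if res.ok:
            prev_ok = res
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Body coordinates
# ---------------------------------------------------------------------------

def _posture_interpolators(posture: WormPosture):
    s = posture.arclength_fractions()
    n = posture.normals()
    return s, posture.centerline, posture.half_width, n


def body_to_pixel(posture: WormPosture, coord: BodyCoordinate) -> np.ndarray:
    """Map a body coordinate to a (row, col) pixel point.

    The point sits on the centerline at arclength fraction ``s``, displaced
    along the local normal so that ``w=0`` lies on the ventral edge, ``w=1``
    on the opposite edge, linearly in between.
    """
    if not isinstance(coord, BodyCoordinate):
        coord = BodyCoordinate(*coord)
    s_grid, cl, hw, nrm = _posture_interpolators(posture)
    c = np.array([np.interp(coord.s, s_grid, cl[:, 0]),
                  np.interp(coord.s, s_grid, cl[:, 1])])
    h = np.interp(coord.s, s_grid, hw)
    n = np.array([np.interp(coord.s, s_grid, nrm[:, 0]),
                  np.interp(coord.s, s_grid, nrm[:, 1])])
    nn = np.linalg.norm(n)
    if nn > 0:
        n = n / nn
    return c + (1.0 - 2.0 * coord.w) * h * posture.ventral_side * n


def pixel_to_body(posture: WormPosture, point, *, oversample: int = 10) -> BodyCoordinate:
    """Inverse of :func:`body_to_pixel` for points inside the worm.

    The nearest centerline point (on a densely resampled midline) gives
    ``s``; the signed normal offset relative to the local half-width gives
    ``w``.  The round-trip error is <= 1 px for interior points away from
    the tips, where the width degenerates and ``w`` defaults to 0.5.
    """
    point = np.asarray(point, dtype=float)
    s_grid, cl, hw, nrm = _posture_interpolators(posture)
    n_dense = posture.n_points * oversample
    sd = np.linspace(0.0, 1.0, n_dense)
    cld = np.stack([np.interp(sd, s_grid, cl[:, 0]),
                    np.interp(sd, s_grid, cl[:, 1])], axis=1)
    i = int(np.argmin(np.linalg.norm(cld - point, axis=1)))
    s = float(sd[i])
    h = float(np.interp(s, s_grid, hw))
    n = np.array([np.interp(s, s_grid, nrm[:, 0]),
                  np.interp(s, s_grid, nrm[:, 1])])
    n /= max(np.linalg.norm(n), 1e-12)
    if h < 1e-6:
        return BodyCoordinate(s=s, w=0.5)
    d = float(np.dot(point - cld[i], n)) * posture.ventral_side
    w = 0.5 * (1.0 - d / h)
    return BodyCoordinate(s=s, w=float(np.clip(w, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Bend-wave velocity
# ---------------------------------------------------------------------------

def _angle_profile(posture: WormPosture) -> np.ndarray:
    d = np.diff(posture.centerline, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))
    return theta - theta.mean()


def _profile_shift(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Sub-sample spatial shift delta (in samples) such that b(i) ~ a(i - delta),
    from the lag maximizing the Pearson correlation of overlapping segments,
    refined by parabolic interpolation."""
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.full(lags.shape, -np.inf)
    n = len(a)
    for k, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        if len(x) < 8 or np.std(x) == 0 or np.std(y) == 0:
            continue
        corr[k] = np.corrcoef(x, y)[0, 1]
    k = int(np.argmax(corr))
    lag = float(lags[k])
    if 0 < k < len(lags) - 1 and np.isfinite(corr[k - 1]) and np.isfinite(corr[k + 1]):
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += 0.5 * (y0 - y2) / denom
    return lag


def wave_velocity(postures, frame_rate: float, *, max_lag_frac: float = 0.3):
    """Signed bend-wave phase velocity series (body lengths/s).

    ``velocity[i]`` is estimated from the posture pair ``(i, i+1)``: the
    spatial shift of the tangent-angle profile between consecutive frames
    times the frame rate.  Positive = wave travelling anterior-to-posterior
    (forward locomotion).  Entries adjacent to failed frames (``None`` in
    ``postures``) and the final entry are NaN.
    """
    postures = list(postures)
    ok = [p is not None for p in postures]
    if sum(ok) < 2:
        raise ValueError("need at least 2 ok frames")
    v = np.full(len(postures), np.nan)
    for i in range(len(postures) - 1):
        if not (ok[i] and ok[i + 1]):
            continue
        a = _angle_profile(postures[i])
        b = _angle_profile(postures[i + 1])
        max_lag = max(2, int(max_lag_frac * len(a)))
        delta = _profile_shift(a, b, max_lag)
        v[i] = delta / (len(a) - 1) * frame_rate
    return v


# ---------------------------------------------------------------------------
# Utilities and I/O
# ---------------------------------------------------------------------------

def centerline_rms_error(extracted: WormPosture, truth: WormPosture,
                         *, oversample: int = 10) -> float:
    """RMS of nearest distances (px) from extracted centerline points to the
    densely resampled ground-truth centerline."""
    s = truth.arclength_fractions()
    sd = np.linspace(0.0, 1.0, truth.n_points * oversample)
    dense = np.stack([np.interp(sd, s, truth.centerline[:, 0]),
                      np.interp(sd, s, truth.centerline[:, 1])], axis=1)
    d = np.min(np.linalg.norm(
        extracted.centerline[:, None, :] - dense[None, :, :], axis=2), axis=1)
    return float(np.sqrt(np.mean(d ** 2)))


def postures_to_dataframe(results, frame_rate: float,
                          velocity=None) -> pd.DataFrame:
    """Per-frame posture summary (frame, time_s, ok, head/tail px, length,
    velocity) suitable for CSV export."""
    rows = []
    for i, res in enumerate(results):
        row = {"frame": i, "time_s": i / frame_rate, "ok": res.ok,
               "reason": res.reason}
        if res.ok:
            p = res.posture
            row.update(head_row=p.centerline[0, 0], head_col=p.centerline[0, 1],
                       tail_row=p.centerline[-1, 0], tail_col=p.centerline[-1, 1],
                       length_px=p.length_px)
        rows.append(row)
    df = pd.DataFrame(rows)
    if velocity is not None:
        df["velocity_bl_s"] = np.asarray(velocity, dtype=float)
    return df
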