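"""Synthetic behaviour and fluorescence movies with full ground truth.

Every downstream stage (segmentation, targeting, ratiometric quantification,
trial analysis) is testable offline against these scenes.  The behaviour
generator renders a bright worm silhouette on a dark background — emulating
dark-field contrast — as a ribbon around an analytic centerline whose
tangent-angle profile is a travelling sinusoid; the signed phase velocity of
that bend wave (body lengths/s, positive = anterior-to-posterior = forward
crawling) follows a user schedule.  Stage tracking is emulated by pinning the
worm centroid near the frame centre (an optional drift moves it, erroring if
the worm would leave the frame).

The fluorescence generator places Gaussian neuron spots in a green and a red
channel.  The red (mCherry-like) spot is calcium-insensitive; the green
(GCaMP-like) spot follows the RC-circuit transient model on top of its
baseline.  A per-frame multiplicative gain common to both channels emulates
focus/motion-induced intensity fluctuations — exactly the artifact the
ratiometric dRR0 metric is designed to cancel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .trials import eval_transient

__all__ = [
    "WormPosture",
    "SyntheticScene",
    "FluorScene",
    "make_posture",
    "render_silhouette",
    "make_behavior_scene",
    "make_fluor_scene",
    "make_gfp_control_scene",
    "make_self_touching_frame",
    "ribbon_area",
    "write_behavior_scene",
    "write_fluor_scene",
]

# Width profile: smooth bump, zero at both tips, maximum at 30% of length.
# sin(pi q(s)) with a warped argument q; the fractional exponent makes the
# half-width grow like arclength^0.58 at both tips, so the tips rasterize as
# sharp, clearly visible spikes rather than sub-pixel slivers.
_WIDTH_EXPONENT = np.log(0.5) / np.log(0.3)
_WIDTH_K = (0.3 / 0.7) ** _WIDTH_EXPONENT  # puts the maximum at s = 0.3

# Rendering defaults (8-bit behaviour camera emulation)
_WORM_INTENSITY = 200
_BG_INTENSITY = 8
_BG_NOISE_SD = 2.0

# Fluorescence defaults (16-bit camera emulation)
_SPOT_SIGMA_PX = 3.0
_RED_PEAK = 2000.0
_GREEN_PEAK = 1500.0
_CAMERA_OFFSET = 100.0


@dataclass
class WormPosture:
    """Centerline + width profile defining the body-coordinate frame.

    ``centerline`` is an (N, 2) array of (row, col) pixel coordinates,
    anterior tip first, near-arclength parameterised; ``half_width`` the
    per-point body half-width in px, zero at both tips; ``ventral_side``
    says which side of the tangent the ventral edge lies on (+1 = the
    left-normal ``(-t_col, t_row)`` side).
    """

    centerline: np.ndarray
    half_width: np.ndarray
    ventral_side: int = 1
    time: float = 0.0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.half_width = np.asarray(self.half_width, dtype=float)
        if self.centerline.shape[0] < 20:
            raise ValueError("centerline needs >= 20 points")
        if self.centerline.shape[0] != self.half_width.shape[0]:
            raise ValueError("centerline / half_width length mismatch")
        if np.any(self.half_width < 0):
            raise ValueError("half_width must be >= 0")
        if self.half_width[0] != 0 or self.half_width[-1] != 0:
            raise ValueError("half_width must vanish at both tips")
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if seg.max() > 1.5 * seg.min():
            raise ValueError("centerline spacing varies by >= 50%")
        if self.ventral_side not in (+1, -1):
            raise ValueError("ventral_side must be +1 or -1")

    @property
    def n_points(self) -> int:
        return self.centerline.shape[0]

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    def arclength_fractions(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return s / s[-1]

    def tangents(self) -> np.ndarray:
        """Unit tangents via central differences, anterior-to-posterior."""
        t = np.gradient(self.centerline, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def normals(self) -> np.ndarray:
        """Left normals ``(-t_col, t_row)``; the ventral edge lies at
        ``centerline + ventral_side * half_width * normal``."""
        t = self.tangents()
        return np.stack([-t[:, 1], t[:, 0]], axis=1)


@dataclass
class SyntheticScene:
    """Behaviour movie plus per-frame ground truth."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    truth_postures: list[WormPosture]
    truth_events: list[tuple[str, float, float]]
    frame_rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.truth_postures):
            raise ValueError("frames / truth_postures length mismatch")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


@dataclass
class FluorScene:
    """Two-channel fluorescence movie plus ground-truth transient."""

    green: np.ndarray  # (n_frames, H, W) uint16
    red: np.ndarray
    truth_trace: np.ndarray  # ground-truth dRR0 per frame
    neuron_tracks: np.ndarray  # (n_frames, 2) spot centre (row, col)
    gain_green: np.ndarray  # per-frame multiplicative factor, green channel
    gain_red: np.ndarray
    frame_rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError("green / red stacks must have equal shape")
        if np.any(self.truth_trace < -1):
            raise ValueError("truth_trace must be >= -1")


# ---------------------------------------------------------------------------
# Posture synthesis and rendering
# ---------------------------------------------------------------------------

def width_profile(s, max_half_width_px):
    """Half-width (px) at arclength fraction ``s``: a smooth bump that is
    zero at both tips and maximal at 30% of the body length."""
    s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    a = s ** _WIDTH_EXPONENT
    b = _WIDTH_K * (1.0 - s) ** _WIDTH_EXPONENT
    q = np.divide(a, a + b, out=np.zeros_like(a), where=(a + b) > 0)
    hw = max_half_width_px * np.sin(np.pi * q)
    hw[s <= 0] = 0.0
    hw[s >= 1] = 0.0
    return hw


def make_posture(
    length_px: float,
    max_half_width_px: float,
    *,
    phase: float = 0.0,
    amplitude_rad: float = 0.55,
    wavelengths: float = 1.3,
    heading_rad: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    n_points: int = 100,
    ventral_side: int = 1,
    time: float = 0.0,
) -> WormPosture:
    """Analytic undulating posture.

    The tangent angle along the body is ``heading + amplitude *
    sin(2 pi wavelengths (s - phase))``; advancing ``phase`` at rate v
    (body lengths/s) makes the bend wave travel anterior-to-posterior at
    +v.  The centerline is the arclength integral of the tangent, shifted
    so its centroid sits at ``center`` (row, col).
    """
    s = np.linspace(0.0, 1.0, n_points)
    psi = heading_rad + amplitude_rad * np.sin(2 * np.pi * wavelengths * (s - phase))
    ds = length_px / (n_points - 1)
    # midpoint rule keeps consecutive spacing exactly ds
    psi_mid = 0.5 * (psi[:-1] + psi[1:])
    dr = np.sin(psi_mid) * ds
    dc = np.cos(psi_mid) * ds
    rows = np.concatenate([[0.0], np.cumsum(dr)])
    cols = np.concatenate([[0.0], np.cumsum(dc)])
    cl = np.stack([rows, cols], axis=1)
    cl += np.asarray(center) - cl.mean(axis=0)
    return WormPosture(
        centerline=cl,
        half_width=width_profile(s, max_half_width_px),
        ventral_side=ventral_side,
        time=time,
    )


def _ribbon_polygon(posture: WormPosture) -> np.ndarray:
    n = posture.normals()
    hw = posture.half_width[:, None]
    side_a = posture.centerline + hw * n
    side_b = posture.centerline - hw * n
    return np.vstack([side_a, side_b[::-1]])


def render_silhouette(posture: WormPosture, frame_shape) -> np.ndarray:
    """Boolean mask of the worm ribbon (offset curves at +-half_width)."""
    poly = _ribbon_polygon(posture)
    rr, cc = _draw_polygon(poly[:, 0], poly[:, 1], shape=frame_shape)
    mask = np.zeros(frame_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def ribbon_area(posture: WormPosture) -> float:
    """Analytic area (px^2) of the width-profile ribbon: integral of the
    full width over arclength."""
    s = posture.arclength_fractions()
    return float(np.trapezoid(2.0 * posture.half_width, s * posture.length_px))


def make_self_touching_frame(
    frame_shape=(256, 256),
    length_px: float = 200.0,
    max_half_width_px: float = 10.0,
    seed: int | None = None,
):
    """Render a coiled, self-touching pose (the deep ventral bend of an
    omega turn) whose ribbon overlaps itself, defeating contour-based
    segmentation.  Returns (frame, posture)."""
    n_points = 100
    s = np.linspace(0.0, 1.0, n_points)
    psi = 2 * np.pi * 1.35 * s  # >1 full turn of constant curvature: a closed coil
    ds = length_px / (n_points - 1)
    psi_mid = 0.5 * (psi[:-1] + psi[1:])
    rows = np.concatenate([[0.0], np.cumsum(np.sin(psi_mid) * ds)])
    cols = np.concatenate([[0.0], np.cumsum(np.cos(psi_mid) * ds)])
    cl = np.stack([rows, cols], axis=1)
    cl += np.array([frame_shape[0] / 2, frame_shape[1] / 2]) - cl.mean(axis=0)
    posture = WormPosture(cl, width_profile(s, max_half_width_px))
    rng = np.random.default_rng(seed)
    # polygon fill would even-odd-cancel the self-overlap, so stamp disks
    # along the centerline instead: a true union that keeps the enclosed hole
    mask = np.zeros(frame_shape, dtype=bool)
    sd = np.linspace(0.0, 1.0, 600)
    sg = posture.arclength_fractions()
    rd = np.interp(sd, sg, cl[:, 0])
    cd = np.interp(sd, sg, cl[:, 1])
    hwd = np.interp(sd, sg, posture.half_width)
    from skimage.draw import disk as _draw_disk
    for r0, c0, h in zip(rd, cd, hwd):
        if h >= 0.5:
            rr, cc = _draw_disk((r0, c0), h, shape=frame_shape)
            mask[rr, cc] = True
    img = np.full(frame_shape, float(_BG_INTENSITY))
    img += rng.normal(0.0, _BG_NOISE_SD, frame_shape)
    img[mask] = _WORM_INTENSITY
    return np.clip(img, 0, 255).astype(np.uint8), posture


def _render_frame(posture, frame_shape, rng):
    img = np.full(frame_shape, float(_BG_INTENSITY))
    img += rng.normal(0.0, _BG_NOISE_SD, frame_shape)
    img[render_silhouette(posture, frame_shape)] = _WORM_INTENSITY
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Behaviour scenes
# ---------------------------------------------------------------------------

def make_behavior_scene(
    length_px: float = 150.0,
    width_px: float = 18.0,
    n_frames: int = 150,
    frame_rate: float = 30.0,
    locomotion_schedule=((0.3, 5.0),),
    seed: int | None = 0,
    *,
    frame_shape=(256, 256),
    amplitude_rad: float = 0.55,
    wavelengths: float = 1.3,
    heading_rad: float = 0.0,
    ventral_side: int = 1,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    stimulus_events=(),
    initial_phase: float = 0.0,
) -> SyntheticScene:
    """Render a behaviour movie from a bend-wave schedule.

    ``locomotion_schedule`` is a sequence of ``(speed_bl_per_s, duration_s)``
    intervals; positive speed drives the bend wave anterior-to-posterior
    (forward crawling), negative backwards (a reversal).  ``width_px`` is
    the maximum full body width.  ``drift_px_per_frame`` translates the
    worm centroid per frame (emulated residual stage error); the generator
    raises if the worm would leave the frame, naming the frame index.
    """
    if length_px < 50:
        raise ValueError("length_px must be >= 50")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate

    # piecewise-constant wave speed -> phase(t) by integration
    speeds = np.zeros(n_frames)
    t_edges = np.cumsum([0.0] + [d for _, d in locomotion_schedule])
    tgrid = np.arange(n_frames) * dt
    for (v, _), lo, hi in zip(locomotion_schedule, t_edges[:-1], t_edges[1:]):
        speeds[(tgrid >= lo) & (tgrid < hi)] = v
    phase = initial_phase + np.concatenate([[0.0], np.cumsum(speeds[:-1] * dt)])

    center0 = np.array([frame_shape[0] / 2.0, frame_shape[1] / 2.0])
    drift = np.asarray(drift_px_per_frame, dtype=float)

    frames = np.empty((n_frames, *frame_shape), dtype=np.uint8)
    postures: list[WormPosture] = []
    for i in range(n_frames):
        posture = make_posture(
            length_px, width_px / 2.0,
            phase=phase[i], amplitude_rad=amplitude_rad,
            wavelengths=wavelengths, heading_rad=heading_rad,
            center=tuple(center0 + i * drift),
            ventral_side=ventral_side, time=tgrid[i],
        )
        poly = _ribbon_polygon(posture)
        if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
                or poly[:, 0].max() >= frame_shape[0]
                or poly[:, 1].max() >= frame_shape[1]):
            raise ValueError(f"worm exits the frame at frame {i}")
        frames[i] = _render_frame(posture, frame_shape, rng)
        postures.append(posture)

    events = [
        ("forward" if v > 0 else "reversal" if v < 0 else "pause",
         float(lo), float(min(hi, n_frames * dt)))
        for (v, _), lo, hi in zip(locomotion_schedule, t_edges[:-1], t_edges[1:])
    ]
    events += [("stimulus", float(a), float(a + b)) for a, b in stimulus_events]
    return SyntheticScene(frames, postures, events, frame_rate, seed=seed)


# ---------------------------------------------------------------------------
# Fluorescence scenes
# ---------------------------------------------------------------------------

def _spot(frame_shape, center, peak, sigma):
    r = np.arange(frame_shape[0])[:, None]
    c = np.arange(frame_shape[1])[None, :]
    return peak * np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2)
                         / (2.0 * sigma ** 2))


def make_fluor_scene(
    trace_params=(1.0, 3.0, 10.0, 15.0),
    noise_sd: float = 10.0,
    gain_jitter: float = 0.0,
    track=None,
    n_frames: int = 900,
    frame_rate: float = 30.0,
    seed: int | None = 0,
    *,
    frame_shape=(128, 128),
    spot_sigma_px: float = _SPOT_SIGMA_PX,
    gain_green_const: float = 1.0,
    gain_red_const: float = 1.0,
) -> FluorScene:
    """Two-channel fluorescence movie of one neuron spot.

    The red spot amplitude is constant times a per-frame common gain
    ``g_t = 1 + gain_jitter * U(-1, 1)``; the green spot is its baseline
    times ``(1 + f(t))`` — ``f`` the RC transient with ``trace_params =
    (A, tau1_s, tau2_s, onset_s)`` — times the same common gain and a
    constant channel gain.  Gaussian noise of SD ``noise_sd`` counts is
    added everywhere.  ``track`` is an (n_frames, 2) array of spot centres
    (row, col); the frame centre when None.
    """
    A, tau1, tau2, onset = trace_params
    if A != 0 and not (tau2 > tau1 > 0):
        raise ValueError(f"require tau2 > tau1 > 0, got tau1={tau1}, tau2={tau2}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    f = (eval_transient(A, tau1, tau2, t - onset) if A != 0
         else np.zeros(n_frames))

    if track is None:
        track = np.tile([frame_shape[0] / 2.0, frame_shape[1] / 2.0],
                        (n_frames, 1))
    track = np.asarray(track, dtype=float)

    common_gain = 1.0 + gain_jitter * rng.uniform(-1.0, 1.0, n_frames)
    gain_g = common_gain * gain_green_const
    gain_r = common_gain * gain_red_const

    green = np.empty((n_frames, *frame_shape), dtype=np.uint16)
    red = np.empty_like(green)
    for i in range(n_frames):
        g = (_CAMERA_OFFSET + _spot(frame_shape, track[i],
                                    _GREEN_PEAK * (1.0 + f[i]), spot_sigma_px)
             ) * gain_g[i]
        r = (_CAMERA_OFFSET + _spot(frame_shape, track[i], _RED_PEAK,
                                    spot_sigma_px)) * gain_r[i]
        if noise_sd > 0:
            g = g + rng.normal(0.0, noise_sd, frame_shape)
            r = r + rng.normal(0.0, noise_sd, frame_shape)
        green[i] = np.clip(g, 0, 65535).astype(np.uint16)
        red[i] = np.clip(r, 0, 65535).astype(np.uint16)

    return FluorScene(green, red, np.asarray(f, dtype=float), track,
                      gain_g, gain_r, frame_rate, seed=seed)


def random_walk_track(n_frames, frame_shape, step_sd_px, seed=None):
    """Smooth bounded random-walk spot track emulating residual motion."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd_px, (n_frames, 2))
    track = np.cumsum(steps, axis=0)
    track -= track.mean(axis=0)
    lim = min(frame_shape) / 4.0
    track = np.clip(track, -lim, lim)
    return track + np.array([frame_shape[0] / 2.0, frame_shape[1] / 2.0])


def make_gfp_control_scene(
    noise_sd: float = 10.0,
    gain_jitter: float = 0.1,
    motion_sd_px: float = 0.5,
    n_frames: int = 900,
    frame_rate: float = 30.0,
    seed: int | None = 0,
    **kwargs,
) -> FluorScene:
    """Calcium-insensitive control movie: the transient amplitude is forced
    to zero while motion and gain jitter are retained, so any apparent
    dRR0 is pure instrument noise / motion artifact."""
    frame_shape = kwargs.get("frame_shape", (128, 128))
    track = (random_walk_track(n_frames, frame_shape, motion_sd_px, seed)
             if motion_sd_px > 0 else None)
    return make_fluor_scene(
        trace_params=(0.0, 1.0, 2.0, 0.0),
        noise_sd=noise_sd, gain_jitter=gain_jitter, track=track,
        n_frames=n_frames, frame_rate=frame_rate, seed=seed, **kwargs,
    )


# ---------------------------------------------------------------------------
# Scene I/O: multi-page TIFF + JSON ground-truth sidecar
# ---------------------------------------------------------------------------

def _posture_to_json(p: WormPosture) -> dict:
    return {
        "centerline": p.centerline.tolist(),
        "half_width": p.half_width.tolist(),
        "ventral_side": p.ventral_side,
        "time": p.time,
    }


def write_behavior_scene(scene: SyntheticScene, tiff_path, truth_path=None) -> None:
    import tifffile

    Path(tiff_path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, scene.frames, photometric="minisblack")
    truth_path = truth_path or Path(tiff_path).with_suffix(".truth.json")
    payload = {
        "frame_rate": scene.frame_rate,
        "seed": scene.seed,
        "events": [list(e) for e in scene.truth_events],
        "postures": [_posture_to_json(p) for p in scene.truth_postures],
    }
    Path(truth_path).write_text(json.dumps(payload))


def read_behavior_scene(tiff_path, truth_path=None) -> SyntheticScene:
    import tifffile

    frames = tifffile.imread(tiff_path)
    truth_path = truth_path or Path(tiff_path).with_suffix(".truth.json")
    payload = json.loads(Path(truth_path).read_text())
    postures = [
        WormPosture(np.asarray(p["centerline"]), np.asarray(p["half_width"]),
                    ventral_side=p["ventral_side"], time=p["time"])
        for p in payload["postures"]
    ]
    return SyntheticScene(frames, postures,
                          [tuple(e) for e in payload["events"]],
                          payload["frame_rate"], seed=payload.get("seed"))


def write_fluor_scene(scene: FluorScene, green_path, red_path, truth_path) -> None:
    import tifffile

    Path(green_path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(green_path, scene.green, photometric="minisblack")
    tifffile.imwrite(red_path, scene.red, photometric="minisblack")
    payload = {
        "frame_rate": scene.frame_rate,
        "seed": scene.seed,
        "truth_trace": scene.truth_trace.tolist(),
        "neuron_tracks": scene.neuron_tracks.tolist(),
    }
    Path(truth_path).write_text(json.dumps(payload))
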