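"""End-to-end wiring: synthetic trial -> segmentation -> trace -> trial record.

Convenience layer over the core modules for running a complete simulated
stimulation trial, the same path a real experiment follows: a behaviour
movie is segmented and converted to a bend-wave velocity series, a
two-channel fluorescence movie sharing the trial's event schedule is
quantified to a dRR0 trace, and the two series feed the trial-level
classification, exclusion and transient fit.
"""

from __future__ import annotations

import numpy as np

from .fluor import compute_trace, smooth_trace
from .synthetic import (
    SyntheticScene,
    make_behavior_scene,
    make_fluor_scene,
    random_walk_track,
)
from .trials import TrialRecord, analyze_trial, exclude_trials
from .vision import SegmentationConfig, segment_stack, wave_velocity

__all__ = ["behavior_velocity", "run_synthetic_trial"]

#: Gaussian smoothing applied to the per-frame bend-wave velocity (frames).
#: Single-frame phase estimates carry pixel-level jitter; 3 frames (~0.1 s
#: at 30 fps) is far below any behavioural timescale.
VELOCITY_SMOOTH_SIGMA_FRAMES = 3.0


def _hints(scene: SyntheticScene):
    truth0 = scene.truth_postures[0]
    sg = truth0.arclength_fractions()
    i = int(np.searchsorted(sg, 0.3))
    ventral = (truth0.centerline[i]
               + 0.6 * truth0.half_width[i] * truth0.ventral_side
               * truth0.normals()[i])
    return truth0.centerline[0], ventral


def behavior_velocity(scene: SyntheticScene,
                      config: SegmentationConfig | None = None,
                      smooth_sigma_frames: float = VELOCITY_SMOOTH_SIGMA_FRAMES):
    """Segment a behaviour scene and return (segmentations, velocity, time).

    The frame-0 head and ventral-side hints are taken from the scene's
    ground truth, standing in for the user annotations a real session
    starts with.  The velocity series is lightly smoothed (gap-aware).
    """
    head_hint, ventral_hint = _hints(scene)
    segs = segment_stack(scene.frames, config, head_hint=head_hint,
                         ventral_hint=ventral_hint)
    v = wave_velocity([r.posture if r.ok else None for r in segs],
                      scene.frame_rate)
    if smooth_sigma_frames > 0:
        v = smooth_trace(v, smooth_sigma_frames)
    t = np.arange(len(segs)) / scene.frame_rate
    return segs, v, t


def run_synthetic_trial(
    seed: int,
    *,
    stimulus: str = "ALM",
    amplitude: float = 1.0,
    tau1_s: float = 3.0,
    tau2_s: float = 10.0,
    onset_s: float = 15.0,
    reversal_delay_s: float = 1.0,
    reversal_duration_s: float = 4.0,
    duration_s: float = 30.0,
    frame_rate: float = 30.0,
    forward_speed: float = 0.25,
    noise_sd: float = 5.0,
    gain_jitter: float = 0.1,
    motion_sd_px: float = 0.3,
):
    """Simulate and analyse one full stimulation trial.

    The behaviour scene crawls forward, reverses ``reversal_delay_s`` after
    the stimulus for ``reversal_duration_s``, then resumes; the fluorescence
    scene carries a transient of the given parameters starting at stimulus
    onset.  Returns ``(record, truth)`` where ``truth`` holds the generating
    parameters for comparison.
    """
    n_frames = int(round(duration_s * frame_rate))
    rev_start = onset_s + reversal_delay_s
    schedule = [(forward_speed, rev_start),
                (-forward_speed, reversal_duration_s),
                (forward_speed, duration_s)]
    behavior = make_behavior_scene(
        length_px=200.0, width_px=20.0, n_frames=n_frames,
        frame_rate=frame_rate, locomotion_schedule=schedule, seed=seed,
        stimulus_events=[(onset_s, 2.7)])
    _, velocity, vtime = behavior_velocity(behavior)

    track = random_walk_track(n_frames, (128, 128), motion_sd_px,
                              seed=None if seed is None else seed + 1)
    fluor_scene = make_fluor_scene(
        trace_params=(amplitude, tau1_s, tau2_s, onset_s),
        noise_sd=noise_sd, gain_jitter=gain_jitter, track=track,
        n_frames=n_frames, frame_rate=frame_rate,
        seed=None if seed is None else seed + 2)
    trace = compute_trace(fluor_scene.green, fluor_scene.red,
                          baseline_window=(0.0, onset_s),
                          frame_rate=frame_rate)

    record = TrialRecord(
        trial_id=f"sim-{seed}", stimulus=stimulus, trace=trace,
        velocity=velocity, velocity_time_s=vtime, stimulus_onset_s=onset_s)
    exclude_trials([record])
    analyze_trial(record)
    truth = {"A": amplitude, "tau1_s": tau1_s, "tau2_s": tau2_s,
             "reversal_window": (rev_start, rev_start + reversal_duration_s),
             "truth_trace": fluor_scene.truth_trace,
             "scene": behavior}
    return record, truth
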