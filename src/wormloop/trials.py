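"""Trial-level analysis: calcium-transient model fitting and behaviour statistics.

AVA calcium transients are modelled like the voltage on a capacitor in an RC
circuit driven by a square pulse: a saturating-exponential rise of timescale
``tau1`` followed, once the stimulus-evoked activity peaks, by an exponential
decay with timescale ``tau2 - tau1``.  Fitting the model to each trial's
dRR0 trace yields a per-trial amplitude ``A`` and a trial-specific velocity
averaging window ``[t0, t0 + tau1]``, which makes amplitudes and velocities
comparable across trials even when the worm fails to reverse.

Velocity is the signed bend-wave phase velocity in body lengths per second;
a reversal is a bout of negative velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TransientFit",
    "TrialRecord",
    "ReversalStats",
    "eval_transient",
    "fit_transient",
    "classify_trial",
    "exclude_trials",
    "window_mean_velocity",
    "amplitude_velocity_correlation",
    "reversal_fraction",
    "results_table",
    "group_summary",
]

#: Default classification window after stimulus onset (s).
DEFAULT_CLASSIFY_WINDOW_S = 5.0
#: Default look-back window for the pre-stimulus spontaneous-reversal screen (s).
DEFAULT_PRE_WINDOW_S = 15.0
#: Maximum number of distinct reversal bouts tolerated in the response window.
DEFAULT_MAX_REVERSAL_BOUTS = 2
#: Minimum duration of a negative-velocity run to count as a bout (s).
DEFAULT_MIN_BOUT_S = 0.2


# ---------------------------------------------------------------------------
# Transient model
# ---------------------------------------------------------------------------

@dataclass
class TransientFit:
    """Fitted transient parameters.

    ``A`` is the dimensionless dRR0 amplitude, ``tau1_s`` the rise
    timescale and ``tau2_s`` the decay-timescale parameter (the decay
    e-folding time is ``tau2_s - tau1_s``).
    """

    A: float
    tau1_s: float
    tau2_s: float
    sse: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.tau2_s > self.tau1_s > 0):
            raise ValueError(
                f"require tau2 > tau1 > 0, got tau1={self.tau1_s}, tau2={self.tau2_s}"
            )
        if not math.isfinite(self.A):
            raise ValueError("amplitude A must be finite")


def eval_transient(A, tau1_s, tau2_s, t):
    """Evaluate the piecewise transient model at times ``t`` (s after onset).

    ``0`` for ``t <= 0``; ``A (1 - exp(-4 t / tau1))`` on the rise branch
    ``0 < t <= tau1``; ``A exp(-(t - tau1) / (tau2 - tau1))`` for ``t > tau1``.
    The two branches disagree at ``t = tau1`` by ``A e^-4`` (~1.8% of A);
    the printed piecewise form is implemented verbatim, decay branch taking
    over strictly after ``tau1``.
    """
    if not (tau2_s > tau1_s > 0):
        raise ValueError(
            f"require tau2 > tau1 > 0, got tau1={tau1_s}, tau2={tau2_s}"
        )
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rise = (t > 0) & (t <= tau1_s)
    decay = t > tau1_s
    out[rise] = A * (1.0 - np.exp(-4.0 * t[rise] / tau1_s))
    out[decay] = A * np.exp(-(t[decay] - tau1_s) / (tau2_s - tau1_s))
    return out if out.ndim else float(out)


def _fit_sse(params, t, y):
    A = params[0]
    tau1 = math.exp(params[1])
    tau2 = tau1 + math.exp(params[2])
    r = y - eval_transient(A, tau1, tau2, t)
    return float(r @ r)


def fit_transient(
    dRR0,
    time_s,
    t0: float,
    *,
    max_iter: int = 2000,
    xatol: float = 1e-6,
) -> TransientFit:
    """Least-squares fit of the transient model by Nelder-Mead.

    Fits ``A``, ``tau1`` and ``tau2`` to the valid dRR0 samples from the
    stimulus onset ``t0`` to the end of the trace.  The simplex runs on the
    reparameterisation ``(A, log tau1, log(tau2 - tau1))``, which enforces
    ``tau2 > tau1 > 0`` without constraints.  Three deterministic starts are
    tried -- ``A0`` the post-stimulus maximum, ``tau1_0`` the time-to-max,
    and ``(tau2 - tau1)_0`` in ``{tau1_0, 2 tau1_0, 4 tau1_0}`` -- and the
    best sum of squared residuals wins.

    Parameters
    ----------
    dRR0, time_s : arrays of equal length; NaNs in ``dRR0`` mark gaps.
    t0 : stimulus onset time on the ``time_s`` axis (model time zero).
    """
    dRR0 = np.asarray(dRR0, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    sel = (time_s >= t0) & np.isfinite(dRR0)
    t = time_s[sel] - t0
    y = dRR0[sel]
    if t.size == 0:
        raise ValueError("no valid samples after stimulus onset")
    if t.size < 10:
        raise ValueError(f"need >= 10 valid samples after onset, got {t.size}")

    a0 = float(np.max(y))
    if a0 <= 0:
        a0 = max(float(np.max(np.abs(y))), 1e-6)
    # time-to-max, clipped away from the grid origin
    tau1_0 = max(float(t[int(np.argmax(y))]), 2.0 * float(np.median(np.diff(t))) if t.size > 1 else 0.1)
    tau1_0 = max(tau1_0, 1e-3)

    best = None
    n_converged = 0
    for mult in (1.0, 2.0, 4.0):
        x0 = np.array([a0, math.log(tau1_0), math.log(mult * tau1_0)])
        res = optimize.minimize(
            _fit_sse,
            x0,
            args=(t, y),
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": 1e-12,
                "maxiter": max_iter,
                "maxfev": 4 * max_iter,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        n_converged += bool(res.success)

    A = float(best.x[0])
    tau1 = math.exp(best.x[1])
    tau2 = tau1 + math.exp(best.x[2])
    return TransientFit(A=A, tau1_s=tau1, tau2_s=tau2, sse=float(best.fun),
                        converged=bool(best.success))


# ---------------------------------------------------------------------------
# Trial records and classification
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One stimulation trial: trace, velocity, classification and fit.

    ``velocity`` is in body lengths/s on the ``velocity_time_s`` grid, NaN
    where the behaviour segmentation failed.  ``classification`` is
    ``"reverser"``, ``"non-reverser"`` or ``"excluded"`` (with
    ``exclusion_reason`` set).  ``manual_class`` overrides the automated
    windowed-minimum rule when given, preserving a manual-review workflow.
    """

    trial_id: str
    stimulus: str
    velocity: np.ndarray
    velocity_time_s: np.ndarray
    stimulus_onset_s: float
    trace: object | None = None  # RatioTrace, optional for purely behavioural trials
    classification: str | None = None
    exclusion_reason: str | None = None
    fit: TransientFit | None = None
    mean_velocity: float = float("nan")
    manual_class: str | None = None
    stimulus_regions: tuple = field(default_factory=tuple)


def classify_trial(
    velocity,
    time_s,
    t0: float,
    window_s: float = DEFAULT_CLASSIFY_WINDOW_S,
) -> str:
    """Classify a trial as ``"reverser"`` or ``"non-reverser"``.

    Reverser iff the minimum valid velocity within ``[t0, t0 + window_s]``
    drops below zero; velocity outside the window is ignored.  Raises
    ``ValueError`` when no valid sample falls in the window (the caller
    should mark the trial excluded with reason "no velocity data").
    """
    velocity = np.asarray(velocity, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    sel = (time_s >= t0) & (time_s <= t0 + window_s) & np.isfinite(velocity)
    if not sel.any():
        raise ValueError("no velocity data in classification window")
    return "reverser" if float(np.min(velocity[sel])) < 0 else "non-reverser"


def _count_bouts(velocity, time_s, min_bout_s):
    """Count maximal runs of negative velocity lasting >= min_bout_s."""
    velocity = np.asarray(velocity, dtype=float)
    neg = np.isfinite(velocity) & (velocity < 0)
    bouts = 0
    i = 0
    n = neg.size
    while i < n:
        if neg[i]:
            j = i
            while j + 1 < n and neg[j + 1]:
                j += 1
            if time_s[j] - time_s[i] + 0.5 * _median_dt(time_s) >= min_bout_s:
                bouts += 1
            i = j + 1
        else:
            i += 1
    return bouts


def _median_dt(time_s):
    d = np.diff(np.asarray(time_s, dtype=float))
    return float(np.median(d)) if d.size else 0.0


def exclude_trials(
    records: list[TrialRecord],
    *,
    pre_window_s: float = DEFAULT_PRE_WINDOW_S,
    response_window_s: float = DEFAULT_CLASSIFY_WINDOW_S,
    max_reversal_bouts: int = DEFAULT_MAX_REVERSAL_BOUTS,
    min_bout_s: float = DEFAULT_MIN_BOUT_S,
) -> list[TrialRecord]:
    """Flag trials with spontaneous pre-stimulus reversals or prolonged
    multi-bout responses; returns the same records, mutated in place.

    A trial is excluded when any valid velocity sample is negative within
    ``[t0 - pre_window_s, t0)``, or when more than ``max_reversal_bouts``
    distinct negative-velocity bouts (each >= ``min_bout_s``) occur in the
    response window.
    """
    for rec in records:
        v = np.asarray(rec.velocity, dtype=float)
        ts = np.asarray(rec.velocity_time_s, dtype=float)
        t0 = rec.stimulus_onset_s
        pre = (ts >= t0 - pre_window_s) & (ts < t0) & np.isfinite(v)
        if pre.any() and np.min(v[pre]) < 0:
            rec.classification = "excluded"
            rec.exclusion_reason = "pre-stimulus reversal"
            continue
        resp = (ts >= t0) & (ts <= t0 + response_window_s)
        if _count_bouts(v[resp], ts[resp], min_bout_s) > max_reversal_bouts:
            rec.classification = "excluded"
            rec.exclusion_reason = "multiple reversals"
    return records


def window_mean_velocity(velocity, time_s, t0: float, fit: TransientFit) -> float:
    """Mean valid velocity over the fit-defined window ``[t0, t0 + tau1]``.

    Both endpoints are inclusive; NaN is returned when no valid sample
    falls inside the window (missing-value contract, not an error).
    """
    velocity = np.asarray(velocity, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    sel = (time_s >= t0) & (time_s <= t0 + fit.tau1_s) & np.isfinite(velocity)
    if not sel.any():
        return float("nan")
    return float(np.mean(velocity[sel]))


def analyze_trial(
    rec: TrialRecord,
    *,
    window_s: float = DEFAULT_CLASSIFY_WINDOW_S,
) -> TrialRecord:
    """Run the per-trial pipeline on one record: classify, fit, window-average.

    Excluded records keep ``fit=None``.  The manual classification override,
    when present, takes precedence over the windowed-minimum rule.
    """
    if rec.classification == "excluded":
        rec.fit = None
        return rec
    try:
        auto = classify_trial(rec.velocity, rec.velocity_time_s,
                              rec.stimulus_onset_s, window_s)
    except ValueError:
        rec.classification = "excluded"
        rec.exclusion_reason = "no velocity data"
        rec.fit = None
        return rec
    rec.classification = rec.manual_class or auto
    if rec.trace is not None:
        rec.fit = fit_transient(rec.trace.dRR0, rec.trace.time_s,
                                rec.stimulus_onset_s)
        rec.mean_velocity = window_mean_velocity(
            rec.velocity, rec.velocity_time_s, rec.stimulus_onset_s, rec.fit)
    return rec


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class ReversalStats:
    """Fraction of reversing trials with its binomial standard error."""

    f: float
    n: int
    sigma_f: float

    @classmethod
    def from_counts(cls, n_reversers: int, n: int) -> "ReversalStats":
        if n < 1:
            raise ValueError("empty group")
        f = n_reversers / n
        return cls(f=f, n=n, sigma_f=math.sqrt(f * (1.0 - f) / n))


def reversal_fraction(records: list[TrialRecord]) -> dict[str, ReversalStats]:
    """Per-stimulus fraction of reversers with standard error
    ``sigma_f = sqrt(f (1 - f) / n)``; excluded trials do not count."""
    groups: dict[str, list[TrialRecord]] = {}
    for rec in records:
        if rec.classification == "excluded":
            continue
        groups.setdefault(rec.stimulus, []).append(rec)
    if not groups:
        raise ValueError("no non-excluded trials")
    out = {}
    for stim, recs in groups.items():
        k = sum(r.classification == "reverser" for r in recs)
        out[stim] = ReversalStats.from_counts(k, len(recs))
    return out


def amplitude_velocity_correlation(records: list[TrialRecord]):
    """Pearson correlation between fitted amplitude A and windowed mean
    velocity across all non-excluded trials (reversers and non-reversers).

    Returns ``(r, table)`` where ``table`` is a per-trial DataFrame.
    """
    rows = [
        (r.trial_id, r.stimulus, r.classification, r.fit.A, r.mean_velocity)
        for r in records
        if r.classification != "excluded" and r.fit is not None
        and math.isfinite(r.mean_velocity)
    ]
    if len(rows) < 3:
        raise ValueError("need >= 3 non-excluded trials with fits")
    table = pd.DataFrame(
        rows, columns=["trial_id", "stimulus", "class", "A", "mean_velocity"])
    a = table["A"].to_numpy()
    v = table["mean_velocity"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(v) == 0:
        raise ValueError("zero variance in amplitude or velocity")
    r, _ = stats.pearsonr(a, v)
    return float(r), table


def results_table(records: list[TrialRecord]) -> pd.DataFrame:
    """Per-trial results table (one row per trial, excluded ones included)."""
    rows = []
    for r in records:
        rows.append({
            "trial_id": r.trial_id,
            "stimulus": r.stimulus,
            "class": r.classification,
            "exclusion_reason": r.exclusion_reason,
            "A": r.fit.A if r.fit else float("nan"),
            "tau1_s": r.fit.tau1_s if r.fit else float("nan"),
            "tau2_s": r.fit.tau2_s if r.fit else float("nan"),
            "sse": r.fit.sse if r.fit else float("nan"),
            "mean_velocity": r.mean_velocity,
        })
    return pd.DataFrame(rows)


def group_summary(records: list[TrialRecord]) -> pd.DataFrame:
    """Group-level summary per stimulus: n, f, sigma_f, mean_A, sem_A."""
    stats_by_stim = reversal_fraction(records)
    rows = []
    for stim, rs in stats_by_stim.items():
        amps = [r.fit.A for r in records
                if r.stimulus == stim and r.classification != "excluded"
                and r.fit is not None]
        amps = np.asarray(amps, dtype=float)
        rows.append({
            "stimulus": stim,
            "n": rs.n,
            "f": rs.f,
            "sigma_f": rs.sigma_f,
            "mean_A": float(np.mean(amps)) if amps.size else float("nan"),
            "sem_A": float(np.std(amps, ddof=1) / np.sqrt(amps.size))
            if amps.size > 1 else float("nan"),
        })
    return pd.DataFrame(rows)
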