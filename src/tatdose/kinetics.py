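"""Mono-exponential time-activity-curve fitting for dynamic PET.

Each voxel's (or VOI's) activity is modelled as A(t) = A0 exp(-lambda_eff t)
with lambda_eff = lambda_phy + lambda_bio fitted directly from
decay-UNcorrected frames (pass decay_corrected=True if the scanner already
removed physical decay; lambda_phy is then added back).  The cumulated
activity is the analytic integral A_tilde = A0 / lambda_eff, i.e. the tail
beyond the last frame is the fitted exponential.

Fitting is deterministic: the initial values come from a weighted
log-linear regression on the positive frames, refined by damped
Gauss-Newton least squares.  lambda_eff is constrained to
[0.1*lambda_phy, inf): biological clearance may be mildly negative
(tracer accumulation, flagged) but never cancels physical decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FrameSchedule", "KineticFit", "fit_tac", "fit_activity_map", "residence_time"]

#: lower bound on lambda_eff as a fraction of lambda_phy
LAMBDA_EFF_FLOOR = 0.1
#: voxels whose peak activity falls below this fraction of the volume peak
#: use the trapezoid-plus-physical-tail fallback integrator
FIT_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic acquisition frame timing, minutes post-injection."""

    start_min: tuple[float, ...]
    end_min: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.start_min, float)
        e = np.asarray(self.end_min, float)
        if s.size != e.size or s.size < 1:
            raise ValueError("frame starts and ends must match and be nonempty")
        if np.any(e <= s) or np.any(s[1:] < e[:-1]):
            raise ValueError("frames must be nonoverlapping and increasing")

    @property
    def n_frames(self) -> int:
        return len(self.start_min)

    @property
    def midpoints_h(self) -> np.ndarray:
        """Frame midpoints in hours (the fitting time coordinate)."""
        return (np.asarray(self.start_min) + np.asarray(self.end_min)) / 2.0 / 60.0

    @property
    def durations_h(self) -> np.ndarray:
        return (np.asarray(self.end_min) - np.asarray(self.start_min)) / 60.0

    def to_dict(self) -> dict:
        return {"start_min": list(self.start_min), "end_min": list(self.end_min)}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(tuple(d["start_min"]), tuple(d["end_min"]))


@dataclass
class KineticFit:
    a0: float  # Bq (or Bq/mL for concentration curves) at t = 0
    lambda_eff: float  # 1/h
    lambda_bio: float  # 1/h, = lambda_eff - lambda_phy
    cumulated_activity: float  # Bq*h, = a0 / lambda_eff
    rss: float
    ok: bool
    flags: list[str] = field(default_factory=list)


def _loglinear_init(t: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized weighted log-linear regression ln A = ln A0 - lam t on
    positive frames; a has shape (n_frames, n_curves)."""
    pos = a > 0
    w = np.where(pos, a, 0.0)  # weight by activity ~ inverse log-variance
    logs = np.where(pos, np.log(np.where(pos, a, 1.0)), 0.0)
    sw = w.sum(axis=0)
    sw = np.where(sw > 0, sw, 1.0)
    tm = (w * t[:, None]).sum(axis=0) / sw
    lm = (w * logs).sum(axis=0) / sw
    var = (w * (t[:, None] - tm) ** 2).sum(axis=0)
    cov = (w * (t[:, None] - tm) * (logs - lm)).sum(axis=0)
    slope = np.where(var > 0, -cov / np.where(var > 0, var, 1.0), 0.0)
    a0 = np.exp(lm + slope * tm)
    return a0, slope


def _gauss_newton(
    t: np.ndarray,
    a: np.ndarray,
    a0: np.ndarray,
    lam: np.ndarray,
    lam_lo: float,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Gauss-Newton refinement of A0, lambda for curves in columns."""
    a0 = a0.copy()
    lam = np.clip(lam, lam_lo, None)

    def rss_of(a0v, lamv):
        r = a0v[None, :] * np.exp(-lamv[None, :] * t[:, None]) - a
        return (r**2).sum(axis=0)

    best = rss_of(a0, lam)
    for _ in range(n_iter):
        model = a0[None, :] * np.exp(-lam[None, :] * t[:, None])
        r = model - a
        j1 = model / np.where(a0 > 0, a0, 1.0)[None, :]  # d model / d a0
        j2 = -t[:, None] * model  # d model / d lambda
        g11 = (j1 * j1).sum(axis=0)
        g12 = (j1 * j2).sum(axis=0)
        g22 = (j2 * j2).sum(axis=0) + 1e-300
        b1 = (j1 * r).sum(axis=0)
        b2 = (j2 * r).sum(axis=0)
        det = g11 * g22 - g12**2
        det = np.where(np.abs(det) > 1e-300, det, 1e-300)
        da0 = (g22 * b1 - g12 * b2) / det
        dlam = (g11 * b2 - g12 * b1) / det
        step = 1.0
        improved = np.zeros(a0.shape, dtype=bool)
        for _ in range(8):  # backtracking line search, vectorized
            trial_a0 = np.where(improved, a0, np.maximum(a0 - step * da0, 0.0))
            trial_lam = np.where(improved, lam, np.clip(lam - step * dlam, lam_lo, None))
            trial = rss_of(trial_a0, trial_lam)
            better = trial < best - 1e-30 * (1 + best)
            a0 = np.where(better & ~improved, trial_a0, a0)
            lam = np.where(better & ~improved, trial_lam, lam)
            best = np.where(better & ~improved, trial, best)
            improved |= better
            step *= 0.5
            if improved.all():
                break
        if not improved.any():
            break
    return a0, lam, best


def fit_tac(
    times_h,
    activities,
    lambda_phy: float,
    decay_corrected: bool = False,
) -> KineticFit:
    """Fit A(t) = A0 exp(-lambda_eff t) to one time-activity curve.

    times_h are frame midpoints in hours; activities in Bq (or any linear
    activity unit -- the cumulated activity comes out in unit*h).
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 frames for a mono-exponential fit")
    if np.any(a < 0):
        raise ValueError("activities must be nonnegative")
    if np.count_nonzero(a > 0) < 2:
        return KineticFit(0.0, np.nan, np.nan, 0.0, 0.0, ok=False, flags=["all_zero"])

    if decay_corrected:
        # refit on the physical-decay-restored curve
        a = a * np.exp(-lambda_phy * t)

    lam_lo = LAMBDA_EFF_FLOOR * lambda_phy
    a0, lam = _loglinear_init(t, a[:, None])
    a0, lam, rss = _gauss_newton(t, a[:, None], a0, lam, lam_lo)
    a0_f, lam_f, rss_f = float(a0[0]), float(lam[0]), float(rss[0])

    flags = []
    if lam_f <= lam_lo * (1 + 1e-9):
        flags.append("lambda_eff_at_lower_bound")
    lam_bio = lam_f - lambda_phy
    if lam_bio < 0:
        flags.append("tracer_accumulation")
    ok = a0_f > 0 and np.isfinite(rss_f)
    if not ok:
        flags.append("fit_failed")
    a_tilde = a0_f / lam_f if lam_f > 0 else 0.0
    return KineticFit(a0_f, lam_f, lam_bio, a_tilde, rss_f, ok=ok, flags=flags)


def fit_activity_map(
    pet4d: np.ndarray,
    schedule: FrameSchedule,
    lambda_phy: float,
    mask: Optional[np.ndarray] = None,
    decay_corrected: bool = False,
    fit_floor_fraction: float = FIT_FLOOR_FRACTION,
) -> dict:
    """Voxelwise mono-exponential fit of a dynamic series.

    pet4d has shape (nx, ny, nz, n_frames).  Returns a dict with
    'cumulated' (unit*h), 'lambda_bio' (1/h), 'a0', 'fallback' (bool map of
    voxels integrated by trapezoid + physical tail instead of fitting) and
    counters.  Outside the mask the cumulated activity is 0.
    """
    pet4d = np.asarray(pet4d, dtype=float)
    if pet4d.ndim != 4 or pet4d.shape[-1] != schedule.n_frames:
        raise ValueError("PET series shape does not match the frame schedule")
    shape = pet4d.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match the PET volume")
    if not mask.any():
        raise ValueError("empty mask")

    t = schedule.midpoints_h
    a = pet4d[mask].T  # (n_frames, n_voxels)
    if decay_corrected:
        a = a * np.exp(-lambda_phy * t)[:, None]

    peak = a.max(axis=0)
    global_peak = peak.max() if peak.size else 0.0
    fit_sel = peak > fit_floor_fraction * global_peak
    n_vox = a.shape[1]

    a0 = np.zeros(n_vox)
    lam = np.full(n_vox, np.nan)
    cum = np.zeros(n_vox)
    fallback = ~fit_sel

    lam_lo = LAMBDA_EFF_FLOOR * lambda_phy
    if fit_sel.any():
        af = a[:, fit_sel]
        a0_i, lam_i = _loglinear_init(t, af)
        a0_i, lam_i, _ = _gauss_newton(t, af, a0_i, lam_i, lam_lo)
        a0[fit_sel] = a0_i
        lam[fit_sel] = lam_i
        cum[fit_sel] = np.where(lam_i > 0, a0_i / lam_i, 0.0)

    if fallback.any():
        afb = a[:, fallback]
        tail = np.where(lambda_phy > 0, afb[-1] / max(lambda_phy, 1e-300), 0.0)
        cum[fallback] = np.trapezoid(afb, t, axis=0) + tail
        lam[fallback] = lambda_phy  # lambda_bio -> 0 for fallback voxels

    out_cum = np.zeros(shape)
    out_lbio = np.zeros(shape)
    out_a0 = np.zeros(shape)
    out_fb = np.zeros(shape, dtype=bool)
    out_cum[mask] = cum
    out_lbio[mask] = lam - lambda_phy
    out_a0[mask] = a0
    out_fb[mask] = fallback
    return {
        "cumulated": out_cum,
        "lambda_bio": out_lbio,
        "a0": out_a0,
        "fallback": out_fb,
        "n_fit": int(fit_sel.sum()),
        "n_fallback": int(fallback.sum()),
    }


def residence_time(cumulated_activity: float, injected_activity: float) -> float:
    """Residence time tau = A_tilde / A_injected, hours."""
    if not injected_activity > 0:
        raise ValueError("injected activity must be positive")
    return cumulated_activity / injected_activity
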