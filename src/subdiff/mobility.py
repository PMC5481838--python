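"""Per-trajectory mobility statistics and MSD-based estimation.

Implements the quantities the analysis chain is built on:

* radius of gyration R_g and mean step size <|dr|>, and the immobile-particle
  filter built on their ratio.  For a stationary particle whose apparent
  motion is pure localization noise (per-coordinate std sigma), R_g -> sigma*sqrt(2)
  and <|dr|> -> sigma*sqrt(pi), so R_g/<|dr|> is the constant sqrt(2/pi)
  independent of sigma; the filter thresholds the ratio normalised by that
  constant (default threshold 2.11, the 5%-false-positive point measured on
  immobile controls).
* time-averaged (tMSD), ensemble (eMSD) and mean-tMSD (arithmetic/geometric)
  mean-squared-displacement curves, and the time-averaged mean maximal
  excursion (MME) moments.
* log-log power-law fits MSD(t) = K_alpha * t^alpha, where K_alpha is the
  curve value at t = 1 s.
* localization-error corrections for the second and fourth displacement
  moments from per-localization uncertainty estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trackio import Trajectory, TrajectoryEnsemble

__all__ = [
    "TrajectorySummary", "MSDCurve", "MobilityFit",
    "radius_of_gyration", "mean_step_size", "immobile_filter",
    "tmsd", "emsd", "mean_tmsd", "fit_alpha_K",
    "mme_displacement", "mean_mme", "correct_moments_for_localization_error",
    "IMMOBILE_RATIO_CONSTANT",
]

# R_g / <|dr|> of a pure-noise trajectory: sqrt(2 sigma^2) / (sigma sqrt(pi))
IMMOBILE_RATIO_CONSTANT = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class TrajectorySummary:
    track_id: int
    Rg: float
    mean_step: float
    normalized_ratio: float
    mean_intensity_first10: float
    mobile: bool


@dataclass
class MSDCurve:
    """A lag-time curve of a displacement moment.

    lag_times are in seconds; values in squared length units (nm^2 for nm
    input) for moment 2, or the k-th power for MME moments.  averaging records
    the estimator; n_contributing and sem the per-lag bookkeeping.
    """
    lag_times: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    n_contributing: np.ndarray | None = None
    averaging: str = "time_single"
    moment: int = 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag_times must be strictly increasing")


@dataclass(frozen=True)
class MobilityFit:
    alpha: float
    K_alpha: float
    alpha_stderr: float
    logK_stderr: float
    fit_range: tuple[int, int]
    weights_used: str


# ------------------------------------------------------------ geometry

def radius_of_gyration(trajectory: Trajectory) -> float:
    """RMS distance of the localizations from their centroid (same units as xy)."""
    xy = trajectory.xy
    c = xy.mean(axis=0)
    return float(np.sqrt(((xy - c) ** 2).sum(axis=1).mean()))


def mean_step_size(trajectory: Trajectory) -> float:
    """Mean Euclidean norm of consecutive displacements."""
    if len(trajectory) < 2:
        raise ValueError("mean step size needs at least 2 localizations")
    d = trajectory.steps
    return float(np.hypot(d[:, 0], d[:, 1]).mean())


def immobile_filter(ensemble: TrajectoryEnsemble, threshold: float = 2.11):
    """Partition an ensemble into mobile / immobile trajectories.

    The normalised ratio (R_g / <|dr|>) / sqrt(2/pi) equals ~1 for immobile
    particles regardless of localization error and grows with genuine motion;
    trajectories at or below ``threshold`` are classified immobile.

    Returns (mobile_ensemble, immobile_ensemble, summaries).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mobile, immobile, summaries = [], [], []
    for t in ensemble:
        rg = radius_of_gyration(t)
        ms = mean_step_size(t)
        ratio = np.inf if ms == 0 else (rg / ms) / IMMOBILE_RATIO_CONSTANT
        if ms == 0 and rg == 0:
            ratio = 1.0  # completely frozen trajectory: indistinguishable from noise-free immobile
        inten = t.intensity[:10]
        inten = inten[np.isfinite(inten)]
        is_mobile = ratio > threshold
        summaries.append(TrajectorySummary(
            track_id=t.id, Rg=rg, mean_step=ms, normalized_ratio=float(ratio),
            mean_intensity_first10=float(inten.mean()) if len(inten) else np.nan,
            mobile=bool(is_mobile)))
        (mobile if is_mobile else immobile).append(t)
    mk = lambda trajs: TrajectoryEnsemble(trajs, frame_interval=ensemble.frame_interval,
                                          length_unit=ensemble.length_unit)
    return mk(mobile), mk(immobile), summaries


# ------------------------------------------------------------ MSD estimators

def tmsd(trajectory: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    tMSD(tau) = 1/(T - tau) * sum_i |r(i+tau) - r(i)|^2 over all windows.
    """
    T = len(trajectory)
    if max_lag is None:
        max_lag = T - 1
    if not 1 <= max_lag < T:
        raise ValueError(f"max_lag must be in [1, {T - 1}]")
    xy = trajectory.xy
    vals = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        d = xy[tau:] - xy[:-tau]
        vals[tau - 1] = (d ** 2).sum(axis=1).mean()
    dt = trajectory.frame_interval
    lags = np.arange(1, max_lag + 1) * dt
    n = T - np.arange(1, max_lag + 1)
    return MSDCurve(lags, vals, n_contributing=n, averaging="time_single")


def emsd(ensemble: TrajectoryEnsemble, max_lag: int | None = None) -> MSDCurve:
    """Ensemble MSD: mean over particles of |r_i(t) - r_i(0)|^2.

    Each particle is referenced to its own first observed frame (stationary
    increments assumed); sem is the across-particle standard error.
    """
    if len(ensemble) == 0:
        raise ValueError("emsd needs at least one trajectory")
    longest = max(len(t) for t in ensemble)
    if max_lag is None:
        max_lag = longest - 1
    max_lag = min(max_lag, longest - 1)
    s1 = np.zeros(max_lag)
    s2 = np.zeros(max_lag)
    n = np.zeros(max_lag, dtype=int)
    for t in ensemble:
        d = ((t.xy[1:] - t.xy[0]) ** 2).sum(axis=1)[:max_lag]
        m = len(d)
        s1[:m] += d
        s2[:m] += d ** 2
        n[:m] += 1
    valid = n > 0
    vals = np.full(max_lag, np.nan)
    sem = np.full(max_lag, np.nan)
    vals[valid] = s1[valid] / n[valid]
    var = np.maximum(s2[valid] / n[valid] - vals[valid] ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sem[valid] = np.sqrt(var / np.maximum(n[valid] - 1, 1))
    dt = ensemble.frame_interval
    lags = np.arange(1, max_lag + 1) * dt
    return MSDCurve(lags, vals, sem=sem, n_contributing=n, averaging="ensemble")


def _stack_tmsds(ensemble: TrajectoryEnsemble, max_lag: int, moment_curves=None):
    curves = moment_curves or [tmsd(t, min(max_lag, len(t) - 1)) for t in ensemble]
    lags = np.arange(1, max_lag + 1) * ensemble.frame_interval
    stack = np.full((len(curves), max_lag), np.nan)
    for i, c in enumerate(curves):
        m = min(len(c.values), max_lag)
        stack[i, :m] = c.values[:m]
    return lags, stack


def mean_tmsd(ensemble: TrajectoryEnsemble, mode: str = "geometric",
              max_lag: int | None = None) -> MSDCurve:
    """Arithmetic or geometric mean of the per-trajectory tMSD curves.

    The geometric mean is the preferred estimator of the ensemble-mean
    subdiffusion exponent; non-positive tMSD values (possible after
    localization-error correction) are excluded per lag and recorded in
    n_contributing.
    """
    if mode not in ("arithmetic", "geometric"):
        raise ValueError("mode must be 'arithmetic' or 'geometric'")
    if len(ensemble) == 0:
        raise ValueError("mean_tmsd needs at least one trajectory")
    longest = max(len(t) for t in ensemble)
    if max_lag is None:
        max_lag = longest - 1
    max_lag = min(max_lag, longest - 1)
    lags, stack = _stack_tmsds(ensemble, max_lag)
    ok = np.isfinite(stack)
    if mode == "geometric":
        ok &= stack > 0
    n = ok.sum(axis=0)
    vals = np.full(max_lag, np.nan)
    sem = np.full(max_lag, np.nan)
    for j in range(max_lag):
        col = stack[ok[:, j], j]
        if len(col) == 0:
            continue
        if mode == "arithmetic":
            vals[j] = col.mean()
            sem[j] = col.std(ddof=1) / np.sqrt(len(col)) if len(col) > 1 else np.nan
        else:
            lg = np.log(col)
            vals[j] = np.exp(lg.mean())
            if len(col) > 1:
                sem[j] = vals[j] * lg.std(ddof=1) / np.sqrt(len(col))
    avg = "time_mean_arithmetic" if mode == "arithmetic" else "time_mean_geometric"
    keep = np.isfinite(vals)
    return MSDCurve(lags[keep], vals[keep], sem=sem[keep], n_contributing=n[keep],
                    averaging=avg)


def mme_displacement(trajectory: Trajectory, max_lag: int | None = None,
                     moment: int = 2) -> MSDCurve:
    """Time-averaged mean maximal excursion (MME) moment of one trajectory.

    For each window origin i and lag tau the excursion is the maximum of
    |r(i+j) - r(i)| over 1 <= j <= tau; the k-th power is averaged over the
    same windows as the tMSD.
    """
    if moment not in (2, 4):
        raise ValueError("moment must be 2 or 4")
    T = len(trajectory)
    if max_lag is None:
        max_lag = T - 1
    if not 1 <= max_lag < T:
        raise ValueError(f"max_lag must be in [1, {T - 1}]")
    xy = trajectory.xy
    vals = np.empty(max_lag)
    run = None
    for tau in range(1, max_lag + 1):
        d = xy[tau:] - xy[:-tau]
        r2 = (d ** 2).sum(axis=1)
        run = r2.copy() if run is None else np.maximum(run[: len(r2)], r2)
        vals[tau - 1] = (run ** (moment // 2)).mean()
    dt = trajectory.frame_interval
    lags = np.arange(1, max_lag + 1) * dt
    n = T - np.arange(1, max_lag + 1)
    return MSDCurve(lags, vals, n_contributing=n, averaging="mme", moment=moment)


def mean_mme(ensemble: TrajectoryEnsemble, max_lag: int | None = None,
             moment: int = 2) -> MSDCurve:
    """Ensemble (arithmetic) mean of per-trajectory time-averaged MME moments."""
    if len(ensemble) == 0:
        raise ValueError("mean_mme needs at least one trajectory")
    longest = max(len(t) for t in ensemble)
    if max_lag is None:
        max_lag = longest - 1
    max_lag = min(max_lag, longest - 1)
    curves = [mme_displacement(t, min(max_lag, len(t) - 1), moment) for t in ensemble]
    lags = np.arange(1, max_lag + 1) * ensemble.frame_interval
    stack = np.full((len(curves), max_lag), np.nan)
    for i, c in enumerate(curves):
        stack[i, : len(c.values)] = c.values
    ok = np.isfinite(stack)
    n = ok.sum(axis=0)
    vals = np.nanmean(np.where(ok, stack, np.nan), axis=0)
    sem = np.nanstd(np.where(ok, stack, np.nan), axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    keep = n > 0
    return MSDCurve(lags[keep], vals[keep], sem=sem[keep], n_contributing=n[keep],
                    averaging="mme", moment=moment)


# ------------------------------------------------------------ fitting

def fit_alpha_K(curve: MSDCurve, fit_range: tuple[int, int] | None = None,
                weights: str = "auto") -> MobilityFit:
    """Weighted least squares of log(moment) on log(t).

    alpha is the slope; K_alpha the curve value at t = 1 s (back-transformed
    intercept).  ``fit_range`` is a 1-based inclusive (first, last) lag-index
    pair; ``weights`` is "sem" (inverse-sem weighting in log space), "none",
    or "auto" (sem when the curve carries sem, else none).
    """
    lo, hi = (1, len(curve.values)) if fit_range is None else fit_range
    if not 1 <= lo < hi <= len(curve.values):
        raise ValueError(f"fit_range {fit_range} outside curve of length {len(curve.values)}")
    t = curve.lag_times[lo - 1: hi]
    y = curve.values[lo - 1: hi]
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("non-positive or missing values in fit range; "
                         "exclude or correct them first")
    if weights == "auto":
        weights = "sem" if curve.sem is not None else "none"
    if weights == "sem":
        sem = curve.sem[lo - 1: hi]
        with np.errstate(divide="ignore"):
            w = np.where(np.isfinite(sem) & (sem > 0), (y / sem) ** 2, 0.0)
        if not np.any(w > 0):
            w = np.ones_like(y)
    else:
        w = np.ones_like(y)
    x = np.log(t)
    ly = np.log(y)
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * ly).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    alpha = (w * (x - xm) * (ly - ym)).sum() / sxx
    intercept = ym - alpha * xm
    resid = ly - (intercept + alpha * x)
    dof = max(len(y) - 2, 1)
    s2 = (w * resid ** 2).sum() / dof
    alpha_se = float(np.sqrt(s2 / sxx))
    logK_se = float(np.sqrt(s2 * (1.0 / W + xm ** 2 / sxx)))
    return MobilityFit(alpha=float(alpha), K_alpha=float(np.exp(intercept)),
                       alpha_stderr=alpha_se, logK_stderr=logK_se,
                       fit_range=(lo, hi), weights_used=weights)


# ------------------------------------------------------------ corrections

def correct_moments_for_localization_error(curve: MSDCurve,
                                           uncertainties: np.ndarray,
                                           moment: int = 2,
                                           second_moment_corrected: MSDCurve | None = None
                                           ) -> MSDCurve:
    """Remove the localization-noise bias from a displacement-moment curve.

    With per-coordinate noise std sigma_i on localization i (sigma_x = sigma_y)
    the displacement error per coordinate has variance sigma_i^2 + sigma_j^2, so

    * moment 2:  <r^2>_obs = <r^2> + 2(<sigma_x^2> + <sigma_y^2>)
                          = <r^2> + 4<sigma^2>
    * moment 4:  <r^4>_obs = <r^4> + 8*S2*<r^2> + 8*Q   with
                 S2 = 2<sigma^2>,  Q = <(sigma_i^2 + sigma_j^2)^2>
                    = 2(<sigma^4> + <sigma^2>^2),
      where <r^2> is the *corrected* second moment (pass it via
      ``second_moment_corrected``; for moment 4 it is required).

    Values driven <= 0 by the correction are flagged NaN (excluded from fits).
    """
    sig = np.asarray(uncertainties, dtype=float)
    sig = sig[np.isfinite(sig)]
    if len(sig) == 0 or np.all(sig == 0):
        return curve
    m2 = float((sig ** 2).mean())
    m4 = float((sig ** 4).mean())
    vals = curve.values.copy()
    if moment == 2:
        vals = vals - 4.0 * m2
    elif moment == 4:
        if second_moment_corrected is None:
            raise ValueError("fourth-moment correction needs the corrected second moment")
        S2 = 2.0 * m2
        Q = 2.0 * (m4 + m2 ** 2)
        r2 = np.interp(curve.lag_times, second_moment_corrected.lag_times,
                       second_moment_corrected.values)
        vals = vals - 8.0 * S2 * r2 - 8.0 * Q
    else:
        raise ValueError("moment must be 2 or 4")
    vals[vals <= 0] = np.nan
    out = MSDCurve(curve.lag_times, vals, sem=curve.sem,
                   n_contributing=curve.n_contributing, averaging=curve.averaging,
                   moment=curve.moment, meta=dict(curve.meta))
    out.meta["localization_corrected"] = True
    return out
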