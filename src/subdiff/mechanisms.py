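"""Mechanism-discrimination battery for subdiffusive subpopulations.

Given an ensemble of trajectory segments sharing one mobility state, four
statistics separate candidate subdiffusion mechanisms:

* **VAC** — autocorrelation of velocities coarse-grained over a period delta,
  normalised by its tau = 0 value.  Fractional Brownian motion (fBM) and
  random walks on fractals (RWF) show delta-insensitive negative values at
  tau = delta (for fBM exactly 2^(alpha-1) - 1); CTRW shows none; confined
  Brownian motion shows none at small delta but increasingly negative values
  as delta grows ("weak confinement").
* **moment ratios** — <r^4>/<r^2>^2 of the regular and mean-maximal-excursion
  (MME) displacement statistics.  Gaussian-propagator processes (Brownian,
  fBM) give 2.0 for the regular ratio; RWF gives smaller, (alpha, d_f)-
  dependent values.
* **growing sphere** — the fraction of particles inside a sphere of radius
  r0 * t^(alpha/2): constant for fBM, a growing power law for RWF.
* a rule-based classifier combining the three.

The fBM MME ratio has no closed form; the expectation is a self-similarity
constant estimated by Monte Carlo over exact fBM paths (shipped as a frozen
table, recomputable via ``method="mc"``).  RWF expectations are configurable
reference values (defaults: the numerically computed values for d_f = 1.84 at
alpha = 0.67 / 0.55).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._fgn import sample_fgn
from .mobility import MSDCurve, mean_mme, tmsd, mme_displacement
from .trackio import Trajectory, TrajectoryEnsemble

__all__ = [
    "VACCurve", "MomentRatioCurve", "GrowingSphereCurve", "MechanismReport",
    "vac", "moment_ratios", "expected_ratio_fbm", "expected_ratio_rwf",
    "mme_ratio_fbm_mc", "growing_sphere", "classify_mechanism",
    "DEFAULT_RWF_TABLE", "ClassifierConfig",
]


@dataclass
class VACCurve:
    delta: float                 # velocity timescale, seconds
    tau: np.ndarray              # seconds, starting at 0
    values: np.ndarray           # normalised; values[0] == 1
    n_trajectories: int
    noise_corrected: bool = False


@dataclass
class MomentRatioCurve:
    tau: np.ndarray
    regular_ratio: np.ndarray
    mme_ratio: np.ndarray
    corrected: bool = False


@dataclass
class GrowingSphereCurve:
    t: np.ndarray
    fraction_inside: np.ndarray
    r0: float
    alpha_used: float


@dataclass
class MechanismReport:
    subpopulation: str
    label: str                   # CTRW-like | weak-confinement | fBM/RWF-antipersistent
                                 # | fBM-dominant | RWF-dominant | indeterminate
    vac: dict = field(default_factory=dict)         # delta -> VACCurve
    ratios: MomentRatioCurve | None = None
    sphere: GrowingSphereCurve | None = None
    evidence: dict = field(default_factory=dict)


# ------------------------------------------------------------ VAC

def _segment_list(segments) -> list[Trajectory]:
    out = []
    for s in segments:
        out.append(s.trajectory if hasattr(s, "trajectory") else s)
    return out


def vac(segments, deltas: list[int], tau_max: int | None = None,
        noise_correction: bool = True) -> dict[float, VACCurve]:
    """Velocity autocorrelation per coarse-graining period delta (in frames).

    v(t) = (r(t + delta) - r(t)) / (delta * dt); the correlation over t is
    computed per trajectory, averaged over the ensemble and normalised by its
    tau = 0 value.  Cells where a trajectory is too short are absent, not zero.
    When per-localization uncertainties are present the analytically known
    white-noise contribution (+4<sigma^2>/dt_v^2 at tau=0, -2<sigma^2>/dt_v^2
    at tau=delta, per coordinate pair summed) is subtracted before normalising.
    """
    trajs = _segment_list(segments)
    if not trajs:
        raise ValueError("no segments given")
    dt = trajs[0].frame_interval
    out = {}
    for delta in deltas:
        if tau_max is None:
            tmax = 2 * delta
        else:
            tmax = tau_max
        taus = np.arange(0, tmax + 1)
        acc = np.zeros(len(taus))
        cnt = np.zeros(len(taus), dtype=int)
        sig2_acc, sig2_n = 0.0, 0
        for tr in trajs:
            T = len(tr)
            if T < delta + 1:
                continue
            v = (tr.xy[delta:] - tr.xy[:-delta]) / (delta * dt)
            nv = len(v)
            for j, tau in enumerate(taus):
                if tau >= nv:
                    break
                prod = (v[tau:] * v[:nv - tau]).sum(axis=1)
                acc[j] += prod.mean()
                cnt[j] += 1
            sig = tr.uncertainty[np.isfinite(tr.uncertainty)]
            if len(sig):
                sig2_acc += float((sig ** 2).mean())
                sig2_n += 1
        valid = cnt > 0
        if not valid[0]:
            continue
        curve = np.full(len(taus), np.nan)
        curve[valid] = acc[valid] / cnt[valid]
        if noise_correction and sig2_n > 0:
            sig2 = sig2_acc / sig2_n          # per-coordinate <sigma^2>
            unit = (delta * dt) ** 2
            curve[0] -= 4.0 * sig2 / unit     # 2 coords x 2 sigma^2
            if delta < len(curve):
                curve[delta] += 2.0 * sig2 / unit
        norm = curve[0]
        if norm <= 0:
            continue
        out[delta] = VACCurve(delta=delta * dt, tau=taus * dt, values=curve / norm,
                              n_trajectories=int(cnt[0]),
                              noise_corrected=bool(noise_correction and sig2_n > 0))
    return out


def vac_at_delta(curve: VACCurve) -> float:
    """Normalised VAC value at tau = delta (the mechanism fingerprint)."""
    idx = int(round(curve.delta / (curve.tau[1] - curve.tau[0])))
    return float(curve.values[idx])


# ------------------------------------------------------------ moment ratios

def moment_ratios(segments, tau_range: tuple[int, int] | None = None,
                  uncertainties: np.ndarray | None = None) -> MomentRatioCurve:
    """Ensemble-averaged <r^4>/<r^2>^2 for regular and MME statistics.

    Per-trajectory time-averaged second and fourth moments are averaged over
    the ensemble before taking the ratio.  When ``uncertainties`` are given,
    both moments are first corrected for localization error.
    """
    trajs = _segment_list(segments)
    if not trajs:
        raise ValueError("no segments given")
    max_len = max(len(t) for t in trajs)
    lo, hi = (1, max_len - 1) if tau_range is None else tau_range
    nlag = hi
    dt = trajs[0].frame_interval

    def accumulate_stacked(kind):
        # fast path: equal-length trajectories allow stacked vector ops
        xy = np.stack([t.xy for t in trajs])          # (n, T, 2)
        T = xy.shape[1]
        ml = min(nlag, T - 1)
        mean2 = np.full(nlag, np.nan); mean4 = np.full(nlag, np.nan)
        run = None
        for tau in range(1, ml + 1):
            d = xy[:, tau:] - xy[:, :-tau]
            r2 = d[..., 0] ** 2 + d[..., 1] ** 2       # (n, T - tau)
            if kind == "mme":
                run = r2.copy() if run is None else np.maximum(run[:, :r2.shape[1]], r2)
                r2 = run
            mean2[tau - 1] = r2.mean(axis=1).mean()
            mean4[tau - 1] = (r2 ** 2).mean(axis=1).mean()
        return mean2, mean4

    def accumulate(kind):
        s2 = np.zeros(nlag); s4 = np.zeros(nlag); n = np.zeros(nlag, dtype=int)
        for tr in trajs:
            ml = min(nlag, len(tr) - 1)
            if ml < 1:
                continue
            if kind == "regular":
                xy = tr.xy
                for tau in range(1, ml + 1):
                    d = xy[tau:] - xy[:-tau]
                    r2 = (d ** 2).sum(axis=1)
                    s2[tau - 1] += r2.mean()
                    s4[tau - 1] += (r2 ** 2).mean()
                    n[tau - 1] += 1
            else:
                m2 = mme_displacement(tr, ml, 2).values
                m4 = mme_displacement(tr, ml, 4).values
                s2[:ml] += m2; s4[:ml] += m4; n[:ml] += 1
        valid = n > 0
        mean2 = np.full(nlag, np.nan); mean4 = np.full(nlag, np.nan)
        mean2[valid] = s2[valid] / n[valid]
        mean4[valid] = s4[valid] / n[valid]
        return mean2, mean4

    if len({len(t) for t in trajs}) == 1:
        reg2, reg4 = accumulate_stacked("regular")
        mme2, mme4 = accumulate_stacked("mme")
    else:
        reg2, reg4 = accumulate("regular")
        mme2, mme4 = accumulate("mme")
    corrected = False
    if uncertainties is not None and len(uncertainties):
        sig = np.asarray(uncertainties, float)
        sig = sig[np.isfinite(sig)]
        if len(sig) and sig.any():
            m2s = float((sig ** 2).mean()); m4s = float((sig ** 4).mean())
            S2 = 2.0 * m2s
            Q = 2.0 * (m4s + m2s ** 2)
            reg2c = reg2 - 2.0 * S2
            reg4 = reg4 - 8.0 * S2 * reg2c - 8.0 * Q
            reg2 = reg2c
            corrected = True
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = reg4 / reg2 ** 2
        mr = mme4 / mme2 ** 2
    rr[reg2 <= 0] = np.nan
    taus = np.arange(1, nlag + 1) * dt
    sel = slice(lo - 1, hi)
    return MomentRatioCurve(tau=taus[sel], regular_ratio=rr[sel], mme_ratio=mr[sel],
                            corrected=corrected)


# ------------------------------------------------------------ expectations

def _load_fbm_mme_table():
    with resources.files("subdiff.data").joinpath("fbm_mme_table.csv").open() as fh:
        rows = [line.split(",") for line in fh.read().strip().splitlines()
                if line and not line.startswith("#")]
    arr = np.array([[float(a), float(b)] for a, b in rows[1:]])
    return arr[:, 0], arr[:, 1]


_FBM_MME_TABLE = None


def mme_ratio_fbm_mc(alpha: float, n_steps: int = 512, n_paths: int = 100_000,
                     seed: int = 0) -> float:
    """Monte-Carlo estimate of the fBM MME moment ratio <rmax^4>/<rmax^2>^2.

    By self-similarity the ratio is lag-independent, so it is estimated from
    the maximal excursion of exact fBM paths over a single window of
    ``n_steps`` frames.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    hurst = alpha / 2.0
    s2 = s4 = 0.0
    done = 0
    batch = 20_000
    while done < n_paths:
        b = min(batch, n_paths - done)
        x = np.cumsum(sample_fgn(rng, hurst, n_steps, b), axis=1)
        y = np.cumsum(sample_fgn(rng, hurst, n_steps, b), axis=1)
        rmax2 = (x ** 2 + y ** 2).max(axis=1)
        s2 += rmax2.sum()
        s4 += (rmax2 ** 2).sum()
        done += b
    m2 = s2 / done
    m4 = s4 / done
    return float(m4 / m2 ** 2)


def expected_ratio_fbm(kind: str, alpha: float, method: str = "table",
                       seed: int = 0) -> float:
    """Expected moment ratio of a 2D fBM process with MSD exponent alpha.

    regular: exactly 2.0 (Gaussian propagator).  mme: no closed form exists;
    returned from the shipped Monte-Carlo table (cubic-free linear
    interpolation over a dense alpha grid) or recomputed with
    ``method="mc"``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if kind == "regular":
        return 2.0
    if kind != "mme":
        raise ValueError("kind must be 'regular' or 'mme'")
    if method == "mc":
        return mme_ratio_fbm_mc(alpha, seed=seed)
    global _FBM_MME_TABLE
    if _FBM_MME_TABLE is None:
        _FBM_MME_TABLE = _load_fbm_mme_table()
    grid, vals = _FBM_MME_TABLE
    if not grid[0] <= alpha <= grid[-1]:
        raise ValueError(f"alpha {alpha} outside tabulated range [{grid[0]}, {grid[-1]}]")
    return float(np.interp(alpha, grid, vals))


# RWF expectations: {(kind, alpha): value} at the reference fractal dimension
DEFAULT_RWF_TABLE = {
    "d_f": 1.84,
    ("regular", 0.67): 1.76,
    ("regular", 0.55): 1.66,
    ("mme", 0.67): 1.28,
    ("mme", 0.55): 1.20,
}


def expected_ratio_rwf(kind: str, alpha: float, d_f: float = 1.84,
                       reference_table: dict | None = None) -> float:
    """Expected RWF moment ratio from a reference table.

    The RWF propagator has no simple closed form; expectations are supplied as
    numerically computed reference values per (kind, alpha) at a fixed fractal
    dimension.  Exact tabulated points are returned verbatim; other alphas are
    linearly interpolated inside the tabulated range.  Queries at another d_f,
    or outside the range, raise.
    """
    table = DEFAULT_RWF_TABLE if reference_table is None else reference_table
    if abs(table.get("d_f", d_f) - d_f) > 1e-9:
        raise ValueError(f"no reference values for d_f={d_f}; table is for d_f={table['d_f']}")
    pts = sorted((a, v) for (kd, a), v in
                 ((key, val) for key, val in table.items() if isinstance(key, tuple))
                 if kd == kind)
    if not pts:
        raise ValueError(f"no reference values for kind {kind!r}")
    alphas = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    exact = np.isclose(alphas, alpha)
    if exact.any():
        return float(vals[exact][0])
    if not alphas[0] <= alpha <= alphas[-1]:
        raise ValueError(f"alpha {alpha} outside tabulated range "
                         f"[{alphas[0]}, {alphas[-1]}] and no computation backend")
    return float(np.interp(alpha, alphas, vals))


# ------------------------------------------------------------ growing sphere

def growing_sphere(segments, alpha: float, r0: float | None = None,
                   max_lag: int | None = None) -> GrowingSphereCurve:
    """Fraction of surviving particles inside a sphere of radius r0 * t^(alpha/2).

    Displacements are measured from each segment's origin; N(t) counts the
    segments still observed at elapsed time t.  When ``r0`` is None it is set
    so the fraction at the first lag is ~0.5 (the median first-lag
    displacement), maximising the sensitivity of the flat-vs-growing verdict.
    """
    trajs = _segment_list(segments)
    if not trajs:
        raise ValueError("no segments given")
    dt = trajs[0].frame_interval
    max_len = max(len(t) for t in trajs)
    nlag = (max_len - 1) if max_lag is None else min(max_lag, max_len - 1)
    if r0 is None:
        first = [np.hypot(*(t.xy[1] - t.xy[0])) for t in trajs if len(t) > 1]
        r0 = float(np.median(first)) / dt ** (alpha / 2.0)
        if r0 <= 0:
            r0 = 1.0
    t = np.arange(1, nlag + 1) * dt
    radius = r0 * t ** (alpha / 2.0)
    inside = np.zeros(nlag)
    n = np.zeros(nlag, dtype=int)
    for tr in trajs:
        d = np.hypot(*(tr.xy[1:] - tr.xy[0]).T)[:nlag]
        m = len(d)
        inside[:m] += d <= radius[:m]
        n[:m] += 1
    valid = n > 0
    frac = np.full(nlag, np.nan)
    frac[valid] = inside[valid] / n[valid]
    return GrowingSphereCurve(t=t[valid], fraction_inside=frac[valid],
                              r0=float(r0), alpha_used=float(alpha))


def sphere_growth_exponent(curve: GrowingSphereCurve, skip_frac: float = 0.1) -> float:
    """Least-squares power-law exponent of the curve after the initial transient."""
    n = len(curve.t)
    start = max(1, int(n * skip_frac))
    t = curve.t[start:]
    f = curve.fraction_inside[start:]
    ok = np.isfinite(f) & (f > 0)
    if ok.sum() < 2:
        return np.nan
    return float(np.polyfit(np.log(t[ok]), np.log(f[ok]), 1)[0])


# ------------------------------------------------------------ classifier

@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds of the rule cascade (all on normalised quantities)."""
    zero_band: float = 0.05          # |VAC| below this = "no correlation"
    confinement_band: float = 0.03   # VAC at delta_max below -this = growing negative
    alpha_brownian_min: float = 0.8  # "alpha near 1" for weak confinement
    regular_ratio_tol: float = 0.15  # closeness of regular ratio to the fBM value 2.0
    flat_exponent: float = 0.05      # |growth exponent| below this = flat sphere


def classify_mechanism(vac_curves: dict[float, VACCurve],
                       ratios: MomentRatioCurve,
                       sphere: GrowingSphereCurve,
                       alpha: float,
                       d_f: float | None = None,
                       config: ClassifierConfig = ClassifierConfig(),
                       subpopulation: str = "") -> MechanismReport:
    """Rule cascade assigning a dominant subdiffusion mechanism.

    (i) no correlation at any delta -> CTRW-like; (ii) none at the smallest
    delta but growing negative correlation with delta and alpha near 1 ->
    weak confinement; (iii) delta-insensitive negative VAC -> antipersistent
    (fBM/RWF), refined by the regular moment ratio's proximity to the
    Gaussian value 2.0 vs the RWF expectation and the growing-sphere flatness.
    """
    deltas = sorted(vac_curves)
    if not deltas:
        return MechanismReport(subpopulation, "indeterminate",
                               evidence={"reason": "no VAC curves"})
    at_delta = {d: vac_at_delta(vac_curves[d]) for d in deltas}
    v = np.array([at_delta[d] for d in deltas])
    evidence = {"vac_at_delta": at_delta, "alpha": alpha}

    all_zero = bool(np.all(np.abs(v) < config.zero_band))
    small_zero = abs(v[0]) < config.zero_band
    growing_negative = (v[-1] < -config.confinement_band
                        and v[-1] < v[0] - config.confinement_band / 2)
    all_negative = bool(np.all(v < -config.zero_band))
    spread = float(v.max() - v.min())
    insensitive = spread < max(0.1, 0.4 * abs(v.mean()))
    evidence.update(dict(all_zero=all_zero, growing_negative=growing_negative,
                         all_negative=all_negative, delta_spread=spread))

    tail = ratios.regular_ratio[np.isfinite(ratios.regular_ratio)]
    reg_tail = float(np.median(tail[len(tail) // 2:])) if len(tail) else np.nan
    growth = sphere_growth_exponent(sphere)
    evidence.update(dict(regular_ratio_tail=reg_tail, sphere_growth_exponent=growth))

    if all_zero and not growing_negative:
        label = "CTRW-like"
    elif small_zero and growing_negative and alpha >= config.alpha_brownian_min:
        label = "weak-confinement"
    elif all_negative and insensitive:
        near_gauss = np.isfinite(reg_tail) and abs(reg_tail - 2.0) <= config.regular_ratio_tol
        flat = np.isfinite(growth) and abs(growth) <= config.flat_exponent
        rwf_expect = None
        if d_f is not None:
            try:
                rwf_expect = expected_ratio_rwf("regular", alpha, d_f)
            except ValueError:
                rwf_expect = None
        evidence["rwf_regular_expectation"] = rwf_expect
        if near_gauss and flat:
            label = "fBM-dominant"
        elif (rwf_expect is not None and np.isfinite(reg_tail)
              and abs(reg_tail - rwf_expect) < abs(reg_tail - 2.0)
              and not flat):
            label = "RWF-dominant"
        elif flat:
            label = "fBM-dominant"
        else:
            label = "fBM/RWF-antipersistent"
    elif small_zero and growing_negative:
        label = "weak-confinement" if alpha >= config.alpha_brownian_min else "indeterminate"
    else:
        label = "indeterminate"
    return MechanismReport(subpopulation=subpopulation, label=label,
                           vac=vac_curves, ratios=ratios, sphere=sphere,
                           evidence=evidence)
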