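"""Synthetic single-particle-tracking inputs.

Generates the stochastic processes used to validate the analysis chain:

* 2D Brownian walks (independent Gaussian increments),
* fractional Brownian motion (fBM) with MSD exponent ``alpha`` (Hurst
  ``alpha/2``), synthesised exactly by circulant embedding,
* continuous-time random walks (CTRW) with Pareto waiting times, sampled on
  the regular frame grid,
* circular confinement by an un-crossable disc boundary,
* Gaussian localization noise, and
* uniform (Poisson) point scatters for the spatial null models.

All lengths are in arbitrary units with one frame per step; conversion to
nm / seconds happens only on export.  Step sizes are calibrated so that the
*mean 2D step magnitude* E|dr| equals ``step_scale`` (per-coordinate increment
std = step_scale / sqrt(pi/2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fgn import sample_fgn
from .trackio import Trajectory, TrajectoryEnsemble

__all__ = [
    "SimulationConfig", "simulate_brownian", "simulate_fbm", "simulate_ctrw",
    "simulate", "apply_confinement", "add_localization_noise", "random_scatter",
    "STEP_CALIBRATION",
]

# E|dr| = sigma * sqrt(pi/2) for a 2D Gaussian step with per-coordinate std sigma
STEP_CALIBRATION = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated ensemble.

    alpha is the MSD exponent (1 = Brownian); step_scale the mean step
    magnitude E|dr| in length units per frame; confinement_radius activates the
    un-crossable disc boundary; boundary_rule is "reflect" (specular reflection
    of the offending sub-step) or "resample" (redraw the offending step).
    """
    n_particles: int = 500
    n_steps: int = 500
    process: str = "brownian"            # brownian | fbm | ctrw
    alpha: float = 1.0
    step_scale: float = 1.0
    confinement_radius: float | None = None
    boundary_rule: str = "reflect"
    waiting_exponent: float = 0.5        # CTRW only
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.process not in ("brownian", "fbm", "ctrw"):
            raise ValueError(f"unknown process {self.process!r}")
        if not 0.0 < self.alpha < 2.0:
            if not (self.process == "brownian" and self.alpha == 1.0):
                raise ValueError("alpha must be in (0, 2)")
        if self.step_scale < 0:
            raise ValueError("step_scale must be >= 0")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise ValueError("confinement_radius must be > 0 when set")
        if self.boundary_rule not in ("reflect", "resample"):
            raise ValueError(f"unknown boundary_rule {self.boundary_rule!r}")
        if self.process == "ctrw" and not 0.0 < self.waiting_exponent < 1.0:
            raise ValueError("waiting_exponent must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def coord_sigma(self) -> float:
        """Per-coordinate increment std realizing E|dr| = step_scale."""
        return self.step_scale / STEP_CALIBRATION


def _wrap(config: SimulationConfig, paths: np.ndarray) -> TrajectoryEnsemble:
    """paths: (n_particles, n_steps, 2) absolute positions."""
    n, T, _ = paths.shape
    frames = np.arange(T)
    trajs = [Trajectory(id=i, frames=frames, xy=paths[i]) for i in range(n)]
    return TrajectoryEnsemble(trajs, frame_interval=1.0, length_unit="au")


def _increments(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(n, steps, 2) per-frame displacements of the free (unconfined) walk."""
    n, steps = config.n_particles, config.n_steps - 1
    sigma = config.coord_sigma
    if config.process == "brownian" or (config.process == "fbm" and config.alpha == 1.0):
        return rng.standard_normal((n, steps, 2)) * sigma
    if config.process == "fbm":
        hurst = config.alpha / 2.0
        dx = sample_fgn(rng, hurst, steps, n) * sigma
        dy = sample_fgn(rng, hurst, steps, n) * sigma
        return np.stack([dx, dy], axis=2)
    # CTRW: Gaussian jumps separated by Pareto waiting times, on the frame grid
    inc = np.zeros((n, steps, 2))
    beta = config.waiting_exponent
    for i in range(n):
        t = 0.0
        while True:
            t += rng.random() ** (-1.0 / beta)  # Pareto survival t^-beta, cutoff 1
            k = int(t)
            if k >= steps:
                break
            inc[i, k] += rng.standard_normal(2) * sigma
    return inc


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def _reflect_specular(p0: np.ndarray, p1: np.ndarray, radius: float) -> np.ndarray:
    """Reflect the sub-steps p0 -> p1 that exit the disc about its boundary."""
    p = p1.copy()
    start = p0.copy()
    for _ in range(8):
        d = np.hypot(p[:, 0], p[:, 1])
        out = d > radius
        if not out.any():
            return p
        a, b = start[out], p[out]
        ab = b - a
        A = (ab ** 2).sum(1)
        B = 2 * (a * ab).sum(1)
        C = (a ** 2).sum(1) - radius ** 2
        disc = np.sqrt(np.maximum(B * B - 4 * A * C, 0.0))
        t = np.clip((-B + disc) / np.maximum(2 * A, 1e-300), 0.0, 1.0)
        q = a + t[:, None] * ab                       # exit point on the circle
        nrm = q / np.maximum(np.hypot(q[:, 0], q[:, 1]), 1e-300)[:, None]
        rem = b - q
        refl = rem - 2 * (rem * nrm).sum(1)[:, None] * nrm
        p[out] = q + refl
        start[out] = q
    d = np.hypot(p[:, 0], p[:, 1])                    # numerical leftovers
    out = d > radius
    if out.any():
        p[out] *= (radius / d[out])[:, None]
    return p


def _confine(increments: np.ndarray, radius: float, rule: str, sigma: float,
             rng: np.random.Generator) -> np.ndarray:
    """Walk the increments inside the disc; returns absolute paths."""
    n, steps, _ = increments.shape
    pos = _uniform_disc(rng, n, radius)
    paths = np.empty((n, steps + 1, 2))
    paths[:, 0] = pos
    for t in range(steps):
        new = pos + increments[:, t]
        if rule == "reflect":
            new = _reflect_specular(pos, new, radius)
        else:  # resample the offending step from the Gaussian marginal
            for _ in range(50):
                d = np.hypot(new[:, 0], new[:, 1])
                out = d > radius
                if not out.any():
                    break
                new[out] = pos[out] + rng.standard_normal((int(out.sum()), 2)) * sigma
            d = np.hypot(new[:, 0], new[:, 1])
            out = d > radius
            if out.any():
                new[out] *= (radius / d[out])[:, None]
        paths[:, t + 1] = new
        pos = new
    return paths


def simulate(config: SimulationConfig) -> TrajectoryEnsemble:
    """Run a simulation described by ``config`` (any process, confined or not)."""
    rng = np.random.default_rng(config.seed)
    inc = _increments(config, rng)
    if config.confinement_radius is not None:
        paths = _confine(inc, config.confinement_radius, config.boundary_rule,
                         config.coord_sigma, rng)
    else:
        n = config.n_particles
        paths = np.concatenate(
            [np.zeros((n, 1, 2)), np.cumsum(inc, axis=1)], axis=1)
    ens = _wrap(config, paths)
    if config.noise_sigma > 0:
        ens = add_localization_noise(ens, config.noise_sigma, seed=rng)
    return ens


def simulate_brownian(config: SimulationConfig) -> TrajectoryEnsemble:
    if config.process != "brownian":
        raise ValueError("config.process must be 'brownian'")
    return simulate(config)


def simulate_fbm(config: SimulationConfig) -> TrajectoryEnsemble:
    if config.process != "fbm":
        raise ValueError("config.process must be 'fbm'")
    return simulate(config)


def simulate_ctrw(config: SimulationConfig) -> TrajectoryEnsemble:
    if config.process != "ctrw":
        raise ValueError("config.process must be 'ctrw'")
    return simulate(config)


def apply_confinement(config: SimulationConfig, radius: float,
                      boundary_rule: str | None = None) -> TrajectoryEnsemble:
    """Convenience wrapper: rerun ``config`` with an un-crossable disc boundary."""
    from dataclasses import replace
    cfg = replace(config, confinement_radius=radius,
                  boundary_rule=boundary_rule or config.boundary_rule)
    return simulate(cfg)


def add_localization_noise(ensemble: TrajectoryEnsemble, noise_sigma: float,
                           seed=0) -> TrajectoryEnsemble:
    """Perturb every coordinate by iid N(0, noise_sigma^2); record the
    per-localization uncertainty.  noise_sigma = 0 returns the input unchanged."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return ensemble
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trajs = []
    for t in ensemble:
        xy = t.xy + rng.standard_normal(t.xy.shape) * noise_sigma
        trajs.append(Trajectory(
            id=t.id, frames=t.frames, xy=xy, intensity=t.intensity,
            uncertainty=np.full(len(t), float(noise_sigma)),
            frame_interval=t.frame_interval))
    return TrajectoryEnsemble(trajs, frame_interval=ensemble.frame_interval,
                              length_unit=ensemble.length_unit)


def random_scatter(n_points: int, width: float, height: float | None = None,
                   seed: int = 0) -> np.ndarray:
    """Uniform (Poisson) scatter of ``n_points`` in a width x height rectangle.

    Returns an (n, 2) array; the null model for cluster-size distributions.
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    height = width if height is None else height
    if width <= 0 or height <= 0:
        raise ValueError("area must be positive")
    rng = np.random.default_rng(seed)
    pts = rng.random((n_points, 2))
    pts[:, 0] *= width
    pts[:, 1] *= height
    return pts
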