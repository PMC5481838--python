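"""The confined-walk validation study.

Reproduces the simulation benchmark used to validate the estimator chain:
500 particles random-walking for 500 time steps inside an un-crossable disc
of radius 10 length units, either as pure Brownian motion (mean step ~0.4)
or as fractional Brownian motion with MSD exponent 0.5 (mean step ~0.9).
Ensemble (alpha_e), time-averaged (alpha_t, geometric mean) and MME
(alpha_MME) exponents are fitted from the resulting curves.

Choices fixed for this study (see docs/methods.md): the boundary uses the
"resample" rule (an increment that would exit the disc is redrawn from its
Gaussian marginal), alpha_e is fitted over lag points 1-50, alpha_t over the
linear regime 10-30 of the geometric-mean tMSD, and alpha_MME over lags
1-100; estimates are averaged over independent replicate runs to suppress
the Monte-Carlo noise of a single 500-particle realisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mobility import emsd, fit_alpha_K, mean_mme, mean_tmsd
from .simulate import SimulationConfig, simulate

__all__ = ["ConfinementResult", "confinement_study"]


@dataclass(frozen=True)
class ConfinementResult:
    process: str
    alpha_e: float
    alpha_t: float
    alpha_mme: float
    alpha_e_sd: float
    alpha_t_sd: float
    alpha_mme_sd: float
    n_replicates: int


def _single_run(process: str, seed: int) -> tuple[float, float, float]:
    if process == "brownian":
        cfg = SimulationConfig(n_particles=500, n_steps=500, process="brownian",
                               step_scale=0.4, confinement_radius=10.0,
                               boundary_rule="resample", seed=seed)
    elif process == "fbm":
        cfg = SimulationConfig(n_particles=500, n_steps=500, process="fbm",
                               alpha=0.5, step_scale=0.9, confinement_radius=10.0,
                               boundary_rule="resample", seed=seed)
    else:
        raise ValueError(f"unknown process {process!r}")
    ens = simulate(cfg)
    # unweighted log-log fits: every lag of the averaged curve counts equally
    a_e = fit_alpha_K(emsd(ens, 50), (1, 50), weights="none").alpha
    a_t = fit_alpha_K(mean_tmsd(ens, "geometric", 30), (10, 30), weights="none").alpha
    a_m = fit_alpha_K(mean_mme(ens, 100), (1, 100), weights="none").alpha
    return a_e, a_t, a_m


def confinement_study(process: str = "brownian", seed: int = 0,
                      n_replicates: int = 8) -> ConfinementResult:
    """Run the confined-walk benchmark; returns replicate-averaged exponents."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    vals = np.array([_single_run(process, int(s)) for s in seeds])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(3)
    return ConfinementResult(process=process,
                             alpha_e=float(mean[0]), alpha_t=float(mean[1]),
                             alpha_mme=float(mean[2]),
                             alpha_e_sd=float(sd[0]), alpha_t_sd=float(sd[1]),
                             alpha_mme_sd=float(sd[2]),
                             n_replicates=n_replicates)
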