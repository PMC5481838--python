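"""Classify the subdiffusion mechanism of three simulated ensembles.

Runs the velocity-autocorrelation (VAC), moment-ratio and growing-sphere tests
on fBM, confined Brownian and CTRW ensembles and prints the rule-based labels.
"""

from subdiff import (SimulationConfig, classify_mechanism, emsd, fit_alpha_K,
                     growing_sphere, moment_ratios, simulate, vac)

DELTAS = [1, 2, 4, 8, 16, 32, 64]

cases = {
    "fBM alpha=0.5 (viscoelastic medium)":
        SimulationConfig(n_particles=400, n_steps=500, process="fbm", alpha=0.5,
                         step_scale=1.0, seed=1),
    "Brownian in a disc (weak confinement)":
        SimulationConfig(n_particles=400, n_steps=500, step_scale=0.4,
                         confinement_radius=10.0, seed=2),
    "CTRW beta=0.5 (heavy-tailed trapping)":
        SimulationConfig(n_particles=400, n_steps=500, process="ctrw",
                         waiting_exponent=0.5, step_scale=1.0, seed=3),
}

for name, cfg in cases.items():
    ens = simulate(cfg)
    trajs = list(ens)
    curves = vac(trajs, DELTAS)
    ratios = moment_ratios(trajs, (1, 100))
    alpha = fit_alpha_K(emsd(ens, 50), (2, 50)).alpha
    sphere = growing_sphere(trajs, alpha, max_lag=200)
    report = classify_mechanism(curves, ratios, sphere, alpha)
    vshort = report.evidence["vac_at_delta"]
    print(f"{name}\n  alpha={alpha:.2f}  "
          f"VAC(delta=1)={vshort[1]:+.3f}  VAC(delta=64)={vshort[64]:+.3f}  "
          f"-> {report.label}")

print("\nAntipersistent, delta-insensitive VAC marks fBM/RWF; VAC appearing "
      "only at long\ndeltas marks weak confinement; no correlation at any "
      "delta marks CTRW.")
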