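"""The confined-walk validation benchmark.

500 particles walk 500 steps inside an un-crossable disc of radius 10 units,
as Brownian motion (mean step ~0.4) and as fBM with alpha = 0.5 (mean step
~0.9).  Confinement biases the fitted exponents: alpha_t < alpha_e, and the
MME exponent exceeds both.
"""

from subdiff.validation import confinement_study

for process in ("brownian", "fbm"):
    r = confinement_study(process, seed=1, n_replicates=4)
    print(f"{process:9s} alpha_e={r.alpha_e:.3f}+/-{r.alpha_e_sd:.3f}  "
          f"alpha_t={r.alpha_t:.3f}+/-{r.alpha_t_sd:.3f}  "
          f"alpha_MME={r.alpha_mme:.3f}+/-{r.alpha_mme_sd:.3f}")

print("\nEven a purely Brownian walk appears subdiffusive (alpha < 1) under "
      "confinement,\nwith the time average consistently below the ensemble "
      "average — the same pattern\nseen for membrane-protein subpopulations.")
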