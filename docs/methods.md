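# Methods

This note documents the models, estimators, numerical choices and limitations
behind `subdiff`, in the order the analysis chain runs.

## Data model and units

The unit of analysis is the trajectory: an ordered, gap-free run of 2D
localizations of one particle, with a frame interval Δt shared across the
ensemble.  Experimental coordinates are in nm with Δt in seconds (the default
acquisition profile is 85 fps, i.e. Δt ≈ 11.8 ms, with ~25 nm localization
precision).  Simulations run in arbitrary length units with Δt = 1 frame;
nothing downstream depends on the unit system because every statistic is
either dimensionless or reported in the input units.

## Trajectory linking

Between consecutive frames the localizations are matched one-to-one so that
the summed link distance is minimal, subject to no link exceeding
`d_max = 3·√(4·D_assumed·Δt)` (≈ 459–460 nm for D = 0.5 µm²/s at 85 Hz).  The
assignment is solved exactly (`scipy.optimize.linear_sum_assignment`) on a
square cost matrix augmented with per-point "no match" dummies of cost
`d_max`; this realises the lexicographic objective *maximal number of feasible
links, then minimal total displacement*, which the test suite checks against
exhaustive enumeration on small frames.  Linking has no memory: a particle
absent for one frame terminates its track, and only tracks of ≥ 50 consecutive
frames (configurable) are kept.  Drift correction is *not* performed here —
input tables are assumed drift-corrected upstream.

## Immobile-particle rejection

For an immobile particle whose apparent motion is localization noise with
per-coordinate std σ, the localizations are iid N(0, σ²) per coordinate, so
the radius of gyration tends to σ√2 and the mean step size to σ√π
(the step is the magnitude of a 2D Gaussian with per-coordinate variance 2σ²,
a chi-distributed variable with mean σ√2·√(π/2)).  Their ratio √(2/π) is
therefore independent of σ, and the *normalised* ratio
`(R_g/⟨|Δr|⟩)/√(2/π)` equals 1 for noise-dominated tracks while growing
without bound for genuinely moving ones.  The default threshold 2.11 is the
5%-false-positive point measured on immobile controls (gold beads, fixed
cells); it is a parameter, not a constant of the method.

## MSD estimators and fits

* eMSD: mean over particles of `|r_i(t) − r_i(0)|²`, each particle referenced
  to its own first observed frame (stationary increments assumed); the
  across-particle sem is recorded per lag.
* tMSD: `1/(T−τ)·Σ|r(i+τ)−r(i)|²` over all overlapping windows of one track.
* mean tMSD: per-lag arithmetic or geometric mean across tracks.  The
  geometric mean is the preferred estimator of the ensemble exponent; it is
  mathematically ≤ the arithmetic mean, which propagates into systematically
  smaller time-averaged `K_α` — an expected feature, not an error.  Zero or
  non-positive values (possible after noise correction) are excluded per lag
  with the exclusion recorded in `n_contributing`.
* MME: within each window the *maximal* excursion from the window origin up to
  lag τ, raised to the 2nd or 4th power and time-averaged like the tMSD.

`fit_alpha_K` regresses log MSD on log t by weighted least squares; α is the
slope and `K_α` the back-transformed value at t = 1 s.  Ensemble curves are
weighted by `(value/sem)²` (inverse-variance in log space) by default; single
trajectories unweighted.  Default windows: lags 1–50 for segment-level fits,
lags 10–30 (the linear regime) for pre-segmentation ensemble time averages.
Non-positive values inside a fit window raise instead of being silently
dropped.

### Localization-error corrections

With observed = true + ε and per-coordinate noise variance σᵢ² on
localization i (σ_x = σ_y), the displacement error per coordinate has variance
σᵢ² + σⱼ², giving

* second moment: `⟨r²⟩_obs = ⟨r²⟩ + 4⟨σ²⟩`;
* fourth moment: `⟨r⁴⟩_obs = ⟨r⁴⟩ + 8·S₂·⟨r²⟩ + 8·Q` with `S₂ = 2⟨σ²⟩` and
  `Q = E[(σᵢ²+σⱼ²)²] ≈ 2(⟨σ⁴⟩+⟨σ²⟩²)`,

where `⟨r²⟩` on the right is the *corrected* second moment.  Both reduce the
immobile-particle anchors exactly: observed 4σ² → 0 and 32σ⁴ → 0.  Corrected
values driven ≤ 0 are flagged invalid and excluded from fits.  MME moments are
not noise-corrected (no closed form for the noise bias of a running maximum);
the moment-ratio routine records whether corrections were applied.

## CER segmentation and the mixture score

Each time point t is tested slowest-first: if the particle does not exceed
`R_th[i]` from its position at t within the next `n_th[i]` frames it gets
state i+1, otherwise it is promoted to the next test; escaping every threshold
assigns the fastest state k.  Escape distances are measured from the
window-origin position (not a running reference).  Trailing points whose test
window is truncated by the track end keep their label if the escape already
happened inside the truncated window and are otherwise marked unassigned —
this avoids fabricating slow states at track ends.  Runs of ≤ 3 inconsistent
labels flanked by one state are overwritten by that state, applied left to
right until stable (idempotent).  Maximal constant-state runs ≥ 50 frames
become segments; everything shorter is dropped, which deliberately trades
completeness for clean subpopulations.

Per threshold set, the pooled per-state step-size distributions are fitted
*simultaneously* with k components whose widths σᵢ are shared across
subpopulations — each component represents one physical mobility state — and
only the k×k weight matrix `a[i][j]` varies (weights in [0, 1], each
subpopulation's weights summing to 1).  The default component kernel is the
magnitude of a 2D Gaussian step (Rayleigh form, since |Δr| ≥ 0); a plain
half-Gaussian kernel is available for strict replication of Gaussian-fit
figures.  Histograms use Freedman–Diaconis bins on the pooled sample, shared
across subpopulations.  Numerically, an outer Nelder–Mead search over
log-spaced, order-preserving widths wraps per-subpopulation non-negative least
squares with a soft sum-to-one constraint; weights that land exactly on the
1.0 bound are flagged "pinned" (a pinned fit would have exceeded 1 without the
bound and is treated as corrupted).

The mixing score of a weight matrix is `Σⱼ aⱼⱼ − Σᵢ≠ⱼ aᵢʲ = 2·trace − k`,
with maximum k (identity matrix) — e.g. the documented example matrix
(0.95/0.05/0, 0.03/0.92/0.05, 0/0.07/0.93) scores 2.60 of 3.0.  This formula
is a reconstruction anchored on that worked example.  Guideline-based
selection keeps sets with all `R_th ≥ 40 nm` (resolution-limit guard), all
on-diagonal weights ≥ 0.9 and none pinned, and at least `count_min` segments
per subpopulation; final α/K_α are reported as mean ± s.d. across accepted
sets.

## Mechanism battery

* **VAC**: `v(t) = (r(t+δ) − r(t))/δ`, correlated over t per trajectory,
  ensemble-averaged, and normalised by the τ = 0 value (the normalisation is a
  package choice, recorded in the curve metadata).  For fBM the normalised
  value at τ = δ is the increment correlation `2^(α−1) − 1` for every δ; for
  differenced pure noise it is −0.5 (MA(1)); for CTRW ≈ 0; for confined
  Brownian motion it grows negative with δ on the scale of the confinement
  relaxation time.  When uncertainties are present the analytically known
  white-noise contribution (+4⟨σ²⟩/(δΔt)² at τ = 0, −2⟨σ²⟩/(δΔt)² at τ = δ)
  is subtracted before normalising.  Cells a segment is too short for are
  absent, never zero-filled.
* **Moment ratios**: per-τ `⟨r⁴⟩/⟨r²⟩²` of the regular and MME statistics,
  with per-trajectory time averages ensemble-averaged before the ratio.  For
  Gaussian-propagator processes the regular ratio converges to 2.0 in 2D.
  The fBM MME ratio has no closed form: it is a self-similarity constant
  f(α) estimated by Monte Carlo over exact fBM paths (maximal excursion of a
  512-frame window; 2·10⁵ paths per grid point), shipped as an interpolation
  table (`data/fbm_mme_table.csv`, regenerable by
  `scripts/build_fbm_mme_table.py`) giving e.g. f(1.0) = 1.497,
  f(0.67) = 1.318, f(0.55) = 1.263.  The discrete-window constant depends
  mildly on the window length (≈ ±0.02 between 128 and 2048 frames); 512
  frames matches the trajectory scale the method targets.  RWF expectations
  are configurable reference values (defaults: regular 1.76/1.66 and MME
  1.28/1.20 at d_f = 1.84 for α = 0.67/0.55), linearly interpolated in α
  inside the tabulated range; no RWF propagator is computed.
* **Growing sphere**: fraction of surviving particles within `r₀·t^(α/2)` of
  their origin.  `r₀` defaults to the median first-lag displacement scaled to
  t = Δt, which starts the curve near 0.5 where the flat-vs-growing
  discrimination is most sensitive.  Flatness is judged by the least-squares
  power-law exponent after the initial transient (|exponent| < 0.05 ⇒ flat).
* **Classifier**: a rule cascade on the normalised VAC at τ = δ across δ:
  all values inside the ±0.05 zero band and no δ-trend ⇒ CTRW-like; no
  correlation at the smallest δ but values dropping below −0.03 at large δ
  with α ≥ 0.8 ⇒ weak confinement; uniformly negative, δ-insensitive values ⇒
  antipersistent, refined to fBM-dominant (regular ratio within 0.15 of 2.0
  and flat sphere), RWF-dominant (ratio closer to the RWF expectation and a
  growing sphere) or left as fBM/RWF-antipersistent.  All thresholds are
  `ClassifierConfig` fields surfaced in the report's evidence dictionary;
  the defaults were set against the simulated ensembles below.

## Synthetic data

* **Brownian / fBM**: per-coordinate increments are exact fractional Gaussian
  noise synthesised by circulant embedding (Davies–Harte), with a Cholesky
  fallback for short series; H = α/2.  Per-coordinate std is
  `step_scale/√(π/2)` so the *mean 2D step magnitude* equals `step_scale`.
* **CTRW**: Gaussian jumps at renewal times with Pareto waiting-time survival
  `t^(−β)` (unit cutoff), sampled on the regular frame grid; the particle is
  immobile between jumps, so the first frame displacement is empty by
  construction (fits on CTRW ensembles should start at lag 2).
* **Confinement**: an un-crossable disc; initial positions uniform in the
  disc.  Two boundary rules: `reflect` (default; specular reflection of the
  offending sub-step about the circle, preserving step-length statistics) and
  `resample` (the offending increment is redrawn from its Gaussian marginal
  until the move stays inside, falling back to radial clamping after 50
  draws).  For fBM, resampling deliberately breaks the anti-persistent
  correlation at the wall.
* **Localization noise**: iid zero-mean Gaussian per coordinate, recorded in
  the per-localization uncertainty field.
* **Poisson scatters** for the spatial null models.

What these simulations do *not* emulate: photophysics (blinking, bleaching,
intensity fluctuations), localization-uncertainty heterogeneity, drift and
vibration, 3D motion projected to 2D, and RWF lattices (RWF is assessed only
through statistics and reference expectations).  Passing tests therefore
validate the estimator chain and classifier logic under the stated models,
not the imaging pipeline upstream of the localization table.

### The confined-walk benchmark

`subdiff.validation.confinement_study` runs the validation simulation: 500
particles for 500 time steps in a disc of radius 10 units, Brownian with mean
step ~0.4 or fBM (α = 0.5) with mean step ~0.9.  Study choices, fixed after
comparing boundary rules and fit windows on scratch ensembles: the `resample`
boundary rule (with reflection, the confined-fBM ensemble exponent stays at
the free value ≈ 0.49; resampling at the wall reproduces the expected upward
shift), α_e fitted on eMSD lags 1–50, α_t on the geometric-mean tMSD lags
10–30, α_MME on the mean MME lags 1–100, all unweighted, and the three
exponents averaged over 8 independent replicates to suppress the Monte-Carlo
noise of a single 500-particle realisation.  Typical outputs: Brownian
(α_e, α_t, α_MME) ≈ (0.96, 0.94, 1.03); fBM ≈ (0.54, 0.50, 0.65) — the
characteristic confinement pattern α_t < α_e < α_MME.

## Spatial analyses

Box counting uses a geometric √2 ladder of box sizes with the grid anchored at
the data bounding-box corner (a multi-origin average is available to reduce
grid artifacts); d_f is the slope of log(count) against log(1/scale) over the
fit range, which must exclude scales near the resolution limit below and the
footprint extent above — near the extent the occupied count saturates and
biases the slope down.  Clustering is single-linkage at a distance threshold
(default 40 nm ≈ the two-molecule resolution limit), implemented with a k-d
tree plus connected components and therefore order-independent; its contract
is identical to brute-force pairwise linkage.  Radial densities are
annulus-area-corrected and normalised to unit integral per state; montage
alignment translates each cell's center of mass to the origin before pooling.

## Determinism and problem sizes

Every stochastic routine takes a seed or `numpy` Generator and is bit
reproducible; the pipeline manifest records the seed and a config hash.  The
shipped tests and the acceptance script run ensembles of 10²–10⁴ particles
and Monte-Carlo batches of 10⁵ paths — sizes at which every quoted tolerance
comfortably exceeds the estimator's Monte-Carlo error on one CPU.

## Known limitations

* The mixing-score formula and the on-diagonal guideline bound are
  reconstructions anchored on a single worked example.
* The fBM MME expectation is Monte-Carlo, not analytic, and weakly depends on
  the discretisation window (documented above).
* RWF expectations are reference values at one fractal dimension; queries at
  other d_f require supplying a table.
* The classifier's CTRW rule cannot distinguish free Brownian motion from
  CTRW at α ≈ 1 (both show no velocity correlations); it is intended for
  subdiffusive inputs.
* vbSPT-style hidden-Markov segmentation is out of scope; CER is the only
  segmenter provided.
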