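"""Consecutive-escape-radii (CER) trajectory segmentation.

A trajectory is labelled time point by time point into k ordered mobility
states.  Point t is in state 1 if the particle does not move farther than
R_th[0] from its position at t within the next n_th[0] frames; otherwise it is
tested against (R_th[1], n_th[1]) for state 2, and so on; escaping every
threshold pair assigns the fastest state k.  Label sequences are smoothed
(short runs of inconsistent labels are overwritten by their flanking state)
and maximal constant-state runs of at least ``min_segment_length`` frames
become Segments.

Segmentation quality is scored through the Gaussianity of the per-state
step-size distributions: a finite mixture of k shared-width components is
fitted simultaneously to all k subpopulations (component widths shared, only
the k x k weight matrix a[i][j] varies), and the mixing score
sum_j a_jj - sum_{i != j} a_i^j (maximum k) measures how cleanly each
subpopulation is captured by its own component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .trackio import Trajectory, TrajectoryEnsemble

__all__ = [
    "ThresholdSet", "StateSequence", "Segment", "MixtureFit", "ScanResult",
    "UNASSIGNED", "cer_segment", "smooth_states", "extract_segments",
    "segment_ensemble", "pooled_steps_by_state", "step_size_distribution",
    "fit_shared_gaussian_mixture", "mixing_score", "scan_thresholds",
    "select_threshold_sets",
]

UNASSIGNED = 0  # state labels are 1..k; 0 marks points that could not be tested


@dataclass(frozen=True)
class ThresholdSet:
    """Escape radii (length units) and window lengths (frames) for k states.

    R_th[i], n_th[i] separate state i+1 from state i+2 (0-based lists of
    length k-1); state i+1 is more mobile than state i.
    """
    R_th: tuple
    n_th: tuple

    def __init__(self, R_th, n_th):
        object.__setattr__(self, "R_th", tuple(float(r) for r in R_th))
        object.__setattr__(self, "n_th", tuple(int(n) for n in n_th))
        if len(self.R_th) != len(self.n_th) or len(self.R_th) < 1:
            raise ValueError("R_th and n_th must have equal length >= 1")
        if any(r <= 0 for r in self.R_th) or any(n < 1 for n in self.n_th):
            raise ValueError("thresholds must be positive")

    @property
    def k(self) -> int:
        return len(self.R_th) + 1


@dataclass
class StateSequence:
    track_id: int
    states: np.ndarray  # per-time-point label in {UNASSIGNED, 1..k}
    k: int

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if np.any((self.states < 0) | (self.states > self.k)):
            raise ValueError("labels must be in {0..k}")


@dataclass
class Segment:
    """A maximal constant-state run of a parent trajectory ([start, stop) frames)."""
    parent_id: int
    state: int
    start: int
    stop: int
    trajectory: Trajectory

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class MixtureFit:
    """Shared-width mixture fit of k step-size distributions.

    weights[i, j] is the weight of component i (width sigmas[i]) in
    subpopulation j; each column sums to 1.  score is the mixing score.
    """
    weights: np.ndarray       # (k, k)
    sigmas: np.ndarray        # (k,), strictly increasing
    score: float
    n_steps: np.ndarray       # steps pooled per subpopulation
    n_segments: np.ndarray
    converged: bool
    pinned: bool              # any weight at the 1.0 bound
    kernel: str
    residual: float


# ------------------------------------------------------------ segmentation

def cer_segment(trajectory: Trajectory, thresholds: ThresholdSet) -> StateSequence:
    """Label every time point of a trajectory by its CER mobility state.

    Escape is measured from the window-origin position.  Trailing points whose
    test window is truncated by the track end keep their label when the escape
    was already observed inside the truncated window, and are UNASSIGNED when
    the (non-)escape cannot be decided.
    """
    T = len(trajectory)
    if T <= max(thresholds.n_th):
        raise ValueError(f"trajectory of {T} frames is too short for windows {thresholds.n_th}")
    xy = trajectory.xy
    k = thresholds.k
    states = np.zeros(T, dtype=int)
    # escape[i][t]: particle exceeds R_th[i] from xy[t] within min(n_th[i], remaining)
    for t in range(T):
        label = UNASSIGNED
        for i, (R, n) in enumerate(zip(thresholds.R_th, thresholds.n_th)):
            avail = min(n, T - 1 - t)
            if avail == 0:
                label = UNASSIGNED
                break
            d = xy[t + 1: t + 1 + avail] - xy[t]
            escaped = bool((d[:, 0] ** 2 + d[:, 1] ** 2 > R * R).any())
            if not escaped:
                if avail < n:       # truncated window, no escape seen: undecidable
                    label = UNASSIGNED
                else:
                    label = i + 1
                break
            label = k               # escaped every threshold so far
        states[t] = label
    return StateSequence(track_id=trajectory.id, states=states, k=k)


def smooth_states(sequence: StateSequence, max_gap: int = 3) -> StateSequence:
    """Overwrite runs of <= max_gap inconsistent labels flanked by one state.

    Applied left to right until stable (idempotent on its own output); e.g.
    ... 1 1 2 2 1 1 ... collapses to all 1s.
    """
    states = sequence.states.copy()
    changed = True
    while changed:
        changed = False
        runs = _run_lengths(states)
        for idx in range(1, len(runs) - 1):
            s, start, length = runs[idx]
            left = runs[idx - 1][0]
            right = runs[idx + 1][0]
            if length <= max_gap and left == right and s != left:
                states[start: start + length] = left
                changed = True
                break  # re-derive runs after each rewrite: deterministic L-to-R
    return StateSequence(track_id=sequence.track_id, states=states, k=sequence.k)


def _run_lengths(states: np.ndarray):
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((int(states[start]), start, i - start))
            start = i
    return runs


def extract_segments(trajectory: Trajectory, sequence: StateSequence,
                     min_segment_length: int = 50) -> list[Segment]:
    """Cut maximal constant-state runs of at least min_segment_length frames."""
    segments = []
    for state, start, length in _run_lengths(sequence.states):
        if state == UNASSIGNED or length < min_segment_length:
            continue
        segments.append(Segment(
            parent_id=trajectory.id, state=state, start=start, stop=start + length,
            trajectory=trajectory.slice(start, start + length)))
    return segments


def segment_ensemble(ensemble: TrajectoryEnsemble, thresholds: ThresholdSet,
                     max_gap: int = 3, min_segment_length: int = 50) -> list[Segment]:
    """CER-segment every sufficiently long trajectory of an ensemble."""
    out = []
    for t in ensemble:
        if len(t) <= max(thresholds.n_th):
            continue
        seq = smooth_states(cer_segment(t, thresholds), max_gap)
        out.extend(extract_segments(t, seq, min_segment_length))
    return out


def pooled_steps_by_state(segments: list[Segment], k: int) -> list[np.ndarray]:
    """Pool |dr| step magnitudes of all segments per state (list of k arrays)."""
    pools = [[] for _ in range(k)]
    for seg in segments:
        d = seg.trajectory.steps
        pools[seg.state - 1].append(np.hypot(d[:, 0], d[:, 1]))
    return [np.concatenate(p) if p else np.empty(0) for p in pools]


# ------------------------------------------------------------ step-size mixture

def step_size_distribution(steps: np.ndarray, bins: np.ndarray | None = None):
    """Histogram of step magnitudes, normalised to unit mass (density).

    Bins default to Freedman-Diaconis on the provided sample.  Returns
    (bin_edges, density).
    """
    steps = np.asarray(steps, dtype=float)
    if len(steps) == 0:
        raise ValueError("empty step sample")
    if bins is None:
        bins = shared_bins([steps])
    density, edges = np.histogram(steps, bins=bins, density=True)
    return edges, density


def shared_bins(samples: list[np.ndarray], max_bins: int = 200) -> np.ndarray:
    """Freedman-Diaconis bins on the pooled sample, shared across subpopulations."""
    pooled = np.concatenate([s for s in samples if len(s)])
    q75, q25 = np.percentile(pooled, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        width = max(pooled.max() - pooled.min(), 1e-9) / 20
    else:
        width = 2 * iqr / len(pooled) ** (1 / 3)
    top = pooled.max() * 1.02 + 1e-12
    n = int(np.clip(np.ceil(top / width), 10, max_bins))
    return np.linspace(0.0, top, n + 1)


def _kernel_density(s: np.ndarray, sigma: float, kernel: str) -> np.ndarray:
    if kernel == "rayleigh":   # magnitude of a 2D Gaussian step, per-coordinate std sigma
        return s / sigma ** 2 * np.exp(-s ** 2 / (2 * sigma ** 2))
    if kernel == "gaussian":   # half-normal on |dr| (plain-Gaussian replication mode)
        return np.sqrt(2 / np.pi) / sigma * np.exp(-s ** 2 / (2 * sigma ** 2))
    raise ValueError(f"unknown kernel {kernel!r}")


def _solve_weights(design: np.ndarray, target: np.ndarray, lam: float = 1e3):
    """Nonnegative least squares with a soft sum-to-one constraint."""
    k = design.shape[1]
    A = np.vstack([design, lam * np.ones((1, k))])
    b = np.concatenate([target, [lam]])
    w, _ = optimize.nnls(A, b)
    total = w.sum()
    if total > 0:
        w = w / total
    return w


def fit_shared_gaussian_mixture(step_samples: list[np.ndarray],
                                kernel: str = "rayleigh",
                                bins: np.ndarray | None = None,
                                n_segments: np.ndarray | None = None) -> MixtureFit:
    """Simultaneously fit k step-size distributions with k shared-width components.

    Component widths sigma_i are shared across subpopulations (each component
    represents one physical mobility state); only the per-subpopulation weights
    a[i][j] vary, bounded to [0, 1] with column sums 1.  Least squares over the
    histogram densities on shared bins; the outer search over log-spaced,
    order-preserving widths uses Nelder-Mead with per-subpopulation NNLS
    weights inside.
    """
    k = len(step_samples)
    if k < 2:
        raise ValueError("need at least 2 subpopulations")
    if any(len(s) == 0 for s in step_samples):
        raise ValueError("every subpopulation needs a non-empty step sample")
    if bins is None:
        bins = shared_bins(step_samples)
    centers = 0.5 * (bins[:-1] + bins[1:])
    targets = [np.histogram(s, bins=bins, density=True)[0] for s in step_samples]

    # initial widths: per-subpopulation Rayleigh scale estimates, sorted
    init_sig = np.sort([np.sqrt(np.mean(s ** 2) / 2.0) for s in step_samples])
    init_sig = np.maximum(init_sig, 1e-9)
    for i in range(1, k):  # enforce strict increase for the log-increment encoding
        init_sig[i] = max(init_sig[i], init_sig[i - 1] * 1.05)

    # order-preserving encoding: sigma_i = exp(p0 + cumsum softplus(p_1..i))
    def sigmas_from(params):
        inc = np.log1p(np.exp(np.clip(params[1:], -30, 30)))  # softplus > 0
        return np.exp(params[0] + np.concatenate([[0.0], np.cumsum(inc)]))

    def residuals(params):
        sig = sigmas_from(params)
        design = np.stack([_kernel_density(centers, s, kernel) for s in sig], axis=1)
        res = []
        for tgt in targets:
            w = _solve_weights(design, tgt)
            res.append(design @ w - tgt)
        return np.concatenate(res)

    p0 = np.empty(k)
    p0[0] = np.log(init_sig[0])
    ratios = np.diff(np.log(init_sig))
    p0[1:] = np.log(np.expm1(np.maximum(ratios, 1e-3)))

    def cost(params):
        r = residuals(params)
        return float(r @ r)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.minimize(cost, p0, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-12})
    sig = sigmas_from(sol.x)
    design = np.stack([_kernel_density(centers, s, kernel) for s in sig], axis=1)
    W = np.stack([_solve_weights(design, tgt) for tgt in targets], axis=1)  # (k, k)
    score = mixing_score(W)
    pinned = bool(np.any(W >= 1.0 - 1e-9))
    if n_segments is None:
        n_segments = np.zeros(k, dtype=int)
    return MixtureFit(weights=W, sigmas=sig, score=score,
                      n_steps=np.array([len(s) for s in step_samples]),
                      n_segments=np.asarray(n_segments),
                      converged=bool(sol.success), pinned=pinned,
                      kernel=kernel,
                      residual=float(np.sqrt(sol.fun / max(residuals(sol.x).size, 1))))


def mixing_score(weights: np.ndarray) -> float:
    """Mixing score of a k x k weight matrix: sum_j a_jj - sum_{i!=j} a_i^j.

    Columns (subpopulations) must each sum to 1; an identity matrix scores the
    maximum k, uniform weights score 2 - k.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    col = W.sum(axis=0)
    row = W.sum(axis=1)
    if np.any(np.abs(col - 1.0) > 0.05) and np.any(np.abs(row - 1.0) > 0.05):
        raise ValueError(f"subpopulation weights must sum to 1, got columns {col}, rows {row}")
    diag = np.trace(W)
    return float(2.0 * diag - W.sum())


# ------------------------------------------------------------ threshold scanning

@dataclass
class ScanResult:
    thresholds: ThresholdSet
    valid: bool
    fit: MixtureFit | None = None
    reason: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def score(self) -> float:
        return self.fit.score if self.fit is not None else np.nan


def scan_thresholds(ensemble: TrajectoryEnsemble,
                    threshold_sets: list[ThresholdSet],
                    max_gap: int = 3, min_segment_length: int = 50,
                    kernel: str = "rayleigh") -> list[ScanResult]:
    """Evaluate candidate threshold sets: segment, pool steps, fit, score.

    Sets yielding an empty subpopulation are recorded as invalid, not fatal.
    """
    results = []
    for ts in threshold_sets:
        segments = segment_ensemble(ensemble, ts, max_gap, min_segment_length)
        pools = pooled_steps_by_state(segments, ts.k)
        counts = np.array([sum(1 for s in segments if s.state == i + 1)
                           for i in range(ts.k)])
        if any(len(p) == 0 for p in pools):
            results.append(ScanResult(ts, valid=False, reason="empty subpopulation",
                                      meta={"n_segments": counts}))
            continue
        try:
            fit = fit_shared_gaussian_mixture(pools, kernel=kernel, n_segments=counts)
        except Exception as exc:  # singular fits on degenerate pools
            results.append(ScanResult(ts, valid=False, reason=f"fit failed: {exc}",
                                      meta={"n_segments": counts}))
            continue
        results.append(ScanResult(ts, valid=True, fit=fit,
                                  meta={"n_segments": counts}))
    return results


def select_threshold_sets(results: list[ScanResult],
                          min_Rth: float = 40.0,
                          diag_min: float = 0.9,
                          count_min: int = 10):
    """Filter scan results by the selection guidelines.

    1. every escape radius at least ``min_Rth`` (resolution-limit guard);
    2. every on-diagonal weight at least ``diag_min`` and none pinned at the
       1.0 bound (pinning indicates a corrupted fit);
    3. at least ``count_min`` segments in every subpopulation.

    Returns (accepted results, failure counts per guideline).
    """
    accepted = []
    failures = {"invalid": 0, "R_th": 0, "diagonal": 0, "counts": 0}
    for r in results:
        if not r.valid:
            failures["invalid"] += 1
            continue
        if any(R < min_Rth for R in r.thresholds.R_th):
            failures["R_th"] += 1
            continue
        diag = np.diag(r.fit.weights)
        if np.any(diag < diag_min) or r.fit.pinned:
            failures["diagonal"] += 1
            continue
        if np.any(r.meta["n_segments"] < count_min):
            failures["counts"] += 1
            continue
        accepted.append(r)
    return accepted, failures
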