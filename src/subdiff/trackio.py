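"""Data model and I/O for localizations and trajectories, plus frame linking.

The unit of analysis everywhere in the package is the :class:`Trajectory`
(an ordered, gap-free run of localizations) collected into a
:class:`TrajectoryEnsemble` with a common frame interval.  Localization tables
are consumed in the ThunderSTORM CSV dialect (quoted headers carrying units,
coordinates in nm); trajectories are written as long-format CSV.

Linking follows the classic global-optimum recipe: localizations in
consecutive frames are matched one-to-one so that the summed displacement is
minimal, no link may exceed ``d_max``, a particle lost for one frame or more
terminates its track ("no memory"), and only tracks of at least ``min_length``
consecutive frames are kept.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Localization", "Trajectory", "TrajectoryEnsemble", "LinkingConfig",
    "read_localizations", "write_trajectories", "read_trajectories",
    "compute_dmax", "link_trajectories",
]

_ABSENT = np.nan  # sentinel for missing intensity / uncertainty


@dataclass(frozen=True)
class Localization:
    """A single fitted molecule position (nm, 0-based frame)."""
    frame: int
    x: float
    y: float
    intensity: float = _ABSENT
    uncertainty: float = _ABSENT

    def __post_init__(self):
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if np.isfinite(self.uncertainty) and self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass
class Trajectory:
    """Gap-free run of localizations of one particle.

    Attributes
    ----------
    id : track identifier
    frames : (n,) int array, strictly consecutive
    xy : (n, 2) float array in nm
    intensity, uncertainty : (n,) float arrays (NaN where absent)
    frame_interval : seconds between frames
    """
    id: int
    frames: np.ndarray
    xy: np.ndarray
    intensity: np.ndarray | None = None
    uncertainty: np.ndarray | None = None
    frame_interval: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        n = len(self.frames)
        if self.xy.shape != (n, 2):
            raise ValueError("xy must have shape (len(frames), 2)")
        if n >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("frames must be strictly consecutive (gap => new trajectory)")
        if self.intensity is None:
            self.intensity = np.full(n, _ABSENT)
        if self.uncertainty is None:
            self.uncertainty = np.full(n, _ABSENT)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def steps(self) -> np.ndarray:
        """(n-1, 2) array of consecutive displacements."""
        return np.diff(self.xy, axis=0)

    def slice(self, start: int, stop: int, new_id: int | None = None) -> "Trajectory":
        """View [start, stop) as a new trajectory (used by segmentation)."""
        return Trajectory(
            id=self.id if new_id is None else new_id,
            frames=self.frames[start:stop],
            xy=self.xy[start:stop],
            intensity=self.intensity[start:stop],
            uncertainty=self.uncertainty[start:stop],
            frame_interval=self.frame_interval,
        )


@dataclass
class TrajectoryEnsemble:
    trajectories: list[Trajectory] = field(default_factory=list)
    frame_interval: float = 1.0
    length_unit: str = "nm"

    def __post_init__(self):
        for t in self.trajectories:
            t.frame_interval = self.frame_interval

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]

    def filter(self, keep) -> "TrajectoryEnsemble":
        return replace(self, trajectories=[t for t in self.trajectories if keep(t)])


@dataclass(frozen=True)
class LinkingConfig:
    """Parameters of the frame-to-frame linker.

    d_max defaults to three times the expected single-frame displacement of a
    normal diffuser with coefficient ``D_assumed`` (see :func:`compute_dmax`)
    and may be overridden.
    """
    D_assumed: float = 0.5e-12   # m^2/s
    frame_rate: float = 85.0     # Hz
    d_max: float | None = None   # nm; derived from D_assumed if None
    min_length: int = 50         # frames

    def __post_init__(self):
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.d_max is not None and self.d_max <= 0:
            raise ValueError("d_max must be > 0")

    def resolved_dmax(self) -> float:
        if self.d_max is not None:
            return self.d_max
        return compute_dmax(self.D_assumed, self.frame_rate)


def compute_dmax(D_assumed: float, frame_rate: float) -> float:
    """Maximum allowed single-frame displacement, in nm.

    Three times the rms frame displacement of a normal diffuser:
    ``3 * sqrt(4 * D * dt)`` with ``dt = 1/frame_rate``.  D = 0 gives 0.
    """
    if D_assumed < 0 or frame_rate <= 0:
        raise ValueError("D_assumed must be >= 0 and frame_rate > 0")
    dt = 1.0 / frame_rate
    return 3.0 * np.sqrt(4.0 * D_assumed * dt) * 1e9


# ---------------------------------------------------------------- CSV I/O

# header-driven column mapping for the ThunderSTORM export dialect
_COLUMN_ALIASES = {
    "frame": "frame",
    "x [nm]": "x", "x": "x",
    "y [nm]": "y", "y": "y",
    "uncertainty [nm]": "uncertainty", "uncertainty_xy [nm]": "uncertainty",
    "uncertainty": "uncertainty",
    "intensity [photon]": "intensity", "intensity": "intensity",
}


def read_localizations(path, dialect: str = "thunderstorm") -> pd.DataFrame:
    """Read a localization table (ThunderSTORM-style CSV) into a tidy frame.

    Returns a DataFrame with columns frame (0-based int), x, y, uncertainty,
    intensity (nm / arbitrary units; NaN where the file has no such column).
    """
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = col.strip().strip('"').lower()
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=rename)
    missing = [c for c in ("frame", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(
            f"localization table is missing mandatory column(s) {missing}; "
            f"found headers: {list(df.columns)}")
    for c in ("frame", "x", "y", "uncertainty", "intensity"):
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.isna() & df[c].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
                raise ValueError(f"non-numeric value in column '{c}' at line {line}")
            df[c] = vals
    for c in ("uncertainty", "intensity"):
        if c not in df.columns:
            df[c] = _ABSENT
    out = df[["frame", "x", "y", "uncertainty", "intensity"]].copy()
    out["frame"] = out["frame"].astype(int)
    if (out["frame"] < 0).any():
        raise ValueError("frames must be >= 0")
    # normalise 1-based exports to 0-based frames
    if len(out) and out["frame"].min() >= 1 and dialect == "thunderstorm":
        out["frame"] -= out["frame"].min()
    return out.sort_values(["frame"], kind="stable").reset_index(drop=True)


_TRAJ_COLUMNS = ["track_id", "frame", "x", "y", "intensity", "uncertainty"]


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble as long-format CSV (track_id, frame, x, y, ...).

    Coordinates are text-formatted with 6 significant digits; the header
    comment records the frame interval and units so a round trip is lossless
    at that precision.
    """
    rows = []
    for t in ensemble:
        for i in range(len(t)):
            rows.append((t.id, t.frames[i], t.xy[i, 0], t.xy[i, 1],
                         t.intensity[i], t.uncertainty[i]))
    df = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    buf = io.StringIO()
    buf.write(f"# subdiff trajectories; frame_interval_s={ensemble.frame_interval!r}; "
              f"unit={ensemble.length_unit}; y increases downward\n")
    df.to_csv(buf, index=False, float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trajectories(path) -> TrajectoryEnsemble:
    """Read a long-format trajectory CSV written by :func:`write_trajectories`."""
    frame_interval = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tokens in first[1:].split(";"):
                k, _, v = tokens.partition("=")
                if k.strip() == "frame_interval_s":
                    frame_interval = float(v)
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(io.StringIO(first + fh.read()))
    trajectories = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        trajectories.append(Trajectory(
            id=int(tid), frames=grp["frame"].to_numpy(),
            xy=grp[["x", "y"]].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            uncertainty=grp["uncertainty"].to_numpy(),
            frame_interval=frame_interval))
    return TrajectoryEnsemble(trajectories, frame_interval=frame_interval)


# ---------------------------------------------------------------- linking

def _match_frame_pair(prev_xy: np.ndarray, cur_xy: np.ndarray, d_max: float):
    """Globally optimal one-to-one matching between two frames.

    Among matchings with no link exceeding d_max, the number of links is
    maximal and the summed link distance minimal.  Implemented as a square
    assignment problem in which every localization may instead link to a
    "no match" dummy at cost d_max.
    Returns (prev_index, cur_index) arrays of the accepted links.
    """
    n, m = len(prev_xy), len(cur_xy)
    if n == 0 or m == 0:
        return np.empty(0, int), np.empty(0, int)
    dist = np.hypot(*(prev_xy[:, None, :] - cur_xy[None, :, :]).transpose(2, 0, 1))
    big = 1e9 * max(1.0, d_max)
    size = n + m
    cost = np.full((size, size), 0.0)
    cost[:n, :m] = np.where(dist <= d_max, dist, big)
    cost[:n, m:] = big
    cost[n:, :m] = big
    cost[:n, m:][:, :] = big
    # dummies: particle i unmatched costs d_max, same for each current loc
    cost[np.arange(n), m + np.arange(n)] = d_max
    cost[n + np.arange(m), np.arange(m)] = d_max
    cost[n:, m:] = 0.0
    ri, ci = linear_sum_assignment(cost)
    real = (ri < n) & (ci < m)
    ri, ci = ri[real], ci[real]
    ok = dist[ri, ci] <= d_max
    ri, ci = ri[ok], ci[ok]
    order = np.argsort(ri, kind="stable")  # deterministic output order
    return ri[order], ci[order]


def link_trajectories(table: pd.DataFrame, config: LinkingConfig = LinkingConfig()
                      ) -> TrajectoryEnsemble:
    """Link a localization table into trajectories.

    Per consecutive frame pair the assignment minimises the total displacement
    subject to no link exceeding d_max; unmatched particles terminate their
    track and tracks shorter than ``config.min_length`` are discarded.
    An empty table yields an empty ensemble.
    """
    d_max = config.resolved_dmax()
    dt = 1.0 / config.frame_rate
    if len(table) == 0:
        return TrajectoryEnsemble([], frame_interval=dt)
    cols = ["x", "y", "intensity", "uncertainty"]
    by_frame = {int(f): g[cols].to_numpy() for f, g in table.groupby("frame")}
    frames = sorted(by_frame)

    open_tracks: dict[int, list] = {}   # index in current frame -> row buffer
    finished: list[list] = []
    rows0 = by_frame[frames[0]]
    open_tracks = {i: [(frames[0], *rows0[i])] for i in range(len(rows0))}
    for prev_f, cur_f in zip(frames[:-1], frames[1:]):
        cur = by_frame[cur_f]
        if cur_f != prev_f + 1:  # lost for >= 1 frame: terminate everything
            finished.extend(open_tracks.values())
            open_tracks = {i: [(cur_f, *cur[i])] for i in range(len(cur))}
            continue
        prev = by_frame[prev_f]
        ri, ci = _match_frame_pair(prev[:, :2], cur[:, :2], d_max)
        linked_prev = dict(zip(ri.tolist(), ci.tolist()))
        new_open: dict[int, list] = {}
        for i, buf in open_tracks.items():
            if i in linked_prev:
                j = linked_prev[i]
                buf.append((cur_f, *cur[j]))
                new_open[j] = buf
            else:
                finished.append(buf)
        for j in range(len(cur)):
            if j not in new_open:
                new_open[j] = [(cur_f, *cur[j])]
        open_tracks = new_open
    finished.extend(open_tracks.values())

    trajectories = []
    tid = 0
    # deterministic ordering: by first frame then first position
    finished.sort(key=lambda buf: (buf[0][0], buf[0][1], buf[0][2]))
    for buf in finished:
        if len(buf) < config.min_length:
            continue
        arr = np.asarray(buf, dtype=float)
        trajectories.append(Trajectory(
            id=tid, frames=arr[:, 0].astype(int), xy=arr[:, 1:3],
            intensity=arr[:, 3], uncertainty=arr[:, 4], frame_interval=dt))
        tid += 1
    return TrajectoryEnsemble(trajectories, frame_interval=dt)
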