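"""Coarse-grained trajectory statistics for ssDNA on a carbon nanotube.

Works on bead-level frames (MARTINI-style mapping: one bead aggregates a few
heavy atoms).  The nanotube is modelled as an infinite cylinder along one box
axis (the simulated tube is bonded end-to-end across the periodic boundary),
so distances use the minimum-image convention along that axis only.

Statistics implemented:

* hydrogen-bond detection between base beads at a 3.5 A (0.35 nm) distance
  cutoff, excluding near-neighbours along the chain;
* near/far classification of each H-bond against the tube surface at a
  6 A (0.6 nm) cutoff;
* per-nucleotide mean H-bond counts over an analysis window;
* mean square displacement (MSD) of the molecule's centre of mass with a
  multi-origin (all lag times) estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HBOND_CUTOFF_NM = 0.35
NEARFAR_CUTOFF_NM = 0.6
CNT_RADIUS_NM = 0.6
ANALYSIS_WINDOW_FRAMES = 2000

ROLES = ("backbone", "base", "cnt")


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    """Bead positions over frames plus per-bead metadata.

    positions : (n_frames, n_beads, 3) array, nm
    beads     : DataFrame with columns bead_id, role, base, nt_index
    box       : (Lx, Ly, Lz) nm
    periodic_axis : index of the axis that is periodic (the tube axis), or None
    """

    positions: np.ndarray
    beads: pd.DataFrame
    box: tuple[float, float, float] = (20.0, 20.0, 20.759)
    cnt_radius: float = CNT_RADIUS_NM
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    periodic_axis: int | None = 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError("positions must have shape (n_frames, n_beads, 3)")
        if self.positions.shape[1] != len(self.beads):
            raise TrajectoryError("positions and bead table disagree on bead count")
        if not np.isfinite(self.positions).all():
            raise TrajectoryError("positions contain non-finite coordinates")
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_dir, dtype=float)
        self.axis_dir = d / np.linalg.norm(d)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def role_mask(self, roles: Iterable[str]) -> np.ndarray:
        roles = set(roles)
        return self.beads["role"].isin(roles).to_numpy()

    # ---- text serialization: tidy TSV of frames + JSON header ------------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        frames = []
        for f in range(self.n_frames):
            df = self.beads.copy()
            df.insert(0, "frame", f)
            df[["x", "y", "z"]] = self.positions[f]
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        header = {
            "box": list(self.box),
            "cnt_radius": self.cnt_radius,
            "axis_point": self.axis_point.tolist(),
            "axis_dir": self.axis_dir.tolist(),
            "periodic_axis": self.periodic_axis,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        table = pd.read_csv(path, sep="\t")
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        frames = np.sort(table["frame"].unique())
        beads = (
            table[table["frame"] == frames[0]][["bead_id", "role", "base", "nt_index"]]
            .reset_index(drop=True)
        )
        n_beads = len(beads)
        pos = np.empty((len(frames), n_beads, 3))
        for i, f in enumerate(frames):
            sub = table[table["frame"] == f].sort_values("bead_id")
            pos[i] = sub[["x", "y", "z"]].to_numpy()
        return cls(
            positions=pos,
            beads=beads.sort_values("bead_id").reset_index(drop=True),
            box=tuple(header["box"]),
            cnt_radius=header["cnt_radius"],
            axis_point=np.array(header["axis_point"]),
            axis_dir=np.array(header["axis_dir"]),
            periodic_axis=header["periodic_axis"],
        )


@dataclass
class HBondStats:
    """Aggregated hydrogen-bond statistics over an analysis window."""

    pairs_per_frame: list[list[tuple[int, int]]]
    per_position_mean: np.ndarray  # length 30, indexed nt 1..30 at [nt-1]
    near_count: int
    far_count: int

    @property
    def near_pct(self) -> float | None:
        total = self.near_count + self.far_count
        if total == 0:
            return None
        return 100.0 * self.near_count / total

    @property
    def far_pct(self) -> float | None:
        total = self.near_count + self.far_count
        if total == 0:
            return None
        return 100.0 * self.far_count / total

    def to_json(self) -> str:
        return json.dumps(
            {
                "near_count": self.near_count,
                "far_count": self.far_count,
                "near_pct": self.near_pct,
                "far_pct": self.far_pct,
                "per_position_mean": self.per_position_mean.tolist(),
            }
        )


@dataclass
class MSDCurve:
    lags: np.ndarray  # frame lags
    msd: np.ndarray  # nm^2

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"lag_frames": self.lags, "msd_nm2": self.msd}).to_csv(
            path, sep="\t", index=False
        )


def _pairwise_displacements(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    box: Sequence[float],
    periodic_axis: int | None,
) -> np.ndarray:
    """(n_a, n_b, 3) displacement vectors with minimum image along one axis."""
    d = coords_a[:, None, :] - coords_b[None, :, :]
    if periodic_axis is not None:
        L = box[periodic_axis]
        d[..., periodic_axis] -= L * np.round(d[..., periodic_axis] / L)
    return d


def detect_hbonds(
    traj: Trajectory,
    frame: int,
    cutoff_nm: float = HBOND_CUTOFF_NM,
    min_seq_sep: int = 2,
) -> list[tuple[int, int]]:
    """Base-pair bead contacts within *cutoff_nm*, as (nt_i, nt_j) with i < j.

    A pair of nucleotides forms a hydrogen bond when any base bead of one is
    within the cutoff of any base bead of the other.  Nucleotides closer than
    *min_seq_sep* along the chain are excluded: chain neighbours are bonded
    topologically and would satisfy the distance rule trivially (set
    min_seq_sep=0 to disable).
    """
    base_mask = traj.role_mask(["base"])
    if not base_mask.any():
        raise TrajectoryError("no base beads in trajectory")
    nt = traj.beads.loc[base_mask, "nt_index"].to_numpy()
    coords = traj.positions[frame][base_mask]
    if not np.isfinite(coords).all():
        raise TrajectoryError("missing coordinates in frame")
    d = np.linalg.norm(
        _pairwise_displacements(coords, coords, traj.box, traj.periodic_axis), axis=-1
    )
    sep = np.abs(nt[:, None] - nt[None, :])
    # beads of the same nucleotide never pair with themselves
    hit = (d <= cutoff_nm) & (sep >= max(min_seq_sep, 1))
    pairs = set()
    for a, b in zip(*np.nonzero(hit)):
        i, j = int(nt[a]), int(nt[b])
        if i > j:
            i, j = j, i
        pairs.add((i, j))
    return sorted(pairs)


def surface_distance(
    points: np.ndarray,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    radius_nm: float = CNT_RADIUS_NM,
) -> np.ndarray:
    """Distance from point(s) to the cylinder surface, clamped at 0 inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    radial_vec = rel - np.outer(rel @ d, d)
    radial = np.linalg.norm(radial_vec, axis=-1)
    out = np.maximum(radial - radius_nm, 0.0)
    return out if np.asarray(points).ndim > 1 else float(out[0])


def classify_near_far(
    pairs: Sequence[tuple[int, int]],
    traj: Trajectory,
    frame: int,
    cutoff_nm: float = NEARFAR_CUTOFF_NM,
) -> list[str]:
    """Label each H-bond pair 'near' or 'far' relative to the tube surface.

    A pair is near when the smaller of its two partners' surface distances is
    below the cutoff (0.6 nm = 6 A), otherwise far.  Per-nucleotide surface
    distance is the minimum over that nucleotide's base beads.
    """
    base_mask = traj.role_mask(["base"])
    nt = traj.beads.loc[base_mask, "nt_index"].to_numpy()
    coords = traj.positions[frame][base_mask]
    dists = surface_distance(coords, traj.axis_point, traj.axis_dir, traj.cnt_radius)
    dists = np.atleast_1d(dists)
    per_nt: dict[int, float] = {}
    for n, d in zip(nt, dists):
        per_nt[int(n)] = min(per_nt.get(int(n), np.inf), float(d))
    labels = []
    for i, j in pairs:
        labels.append("near" if min(per_nt[i], per_nt[j]) < cutoff_nm else "far")
    return labels


def hbond_stats(
    traj: Trajectory,
    window_frames: int = ANALYSIS_WINDOW_FRAMES,
    hbond_cutoff_nm: float = HBOND_CUTOFF_NM,
    nearfar_cutoff_nm: float = NEARFAR_CUTOFF_NM,
    min_seq_sep: int = 2,
    n_positions: int = 30,
) -> HBondStats:
    """H-bond statistics over the last *window_frames* frames of *traj*."""
    if traj.n_frames < window_frames:
        raise TrajectoryError(
            f"trajectory has {traj.n_frames} frames, window needs {window_frames}"
        )
    start = traj.n_frames - window_frames
    pairs_per_frame: list[list[tuple[int, int]]] = []
    per_pos = np.zeros(n_positions)
    near = far = 0
    for f in range(start, traj.n_frames):
        pairs = detect_hbonds(traj, f, hbond_cutoff_nm, min_seq_sep)
        pairs_per_frame.append(pairs)
        for i, j in pairs:
            per_pos[i - 1] += 1
            per_pos[j - 1] += 1
        for lab in classify_near_far(pairs, traj, f, nearfar_cutoff_nm):
            if lab == "near":
                near += 1
            else:
                far += 1
    return HBondStats(
        pairs_per_frame=pairs_per_frame,
        per_position_mean=per_pos / window_frames,
        near_count=near,
        far_count=far,
    )


def per_position_hbond_mean(
    traj: Trajectory,
    window_frames: int = ANALYSIS_WINDOW_FRAMES,
    **kwargs,
) -> np.ndarray:
    """Mean H-bond count per nucleotide position over the analysis window."""
    return hbond_stats(traj, window_frames=window_frames, **kwargs).per_position_mean


def _unwrap(positions: np.ndarray, box: Sequence[float], axis: int | None) -> np.ndarray:
    """Undo periodic wrapping along the periodic axis, per bead."""
    if axis is None:
        return positions
    out = positions.copy()
    L = box[axis]
    steps = np.diff(positions[..., axis], axis=0)
    steps -= L * np.round(steps / L)
    out[1:, ..., axis] = positions[0, ..., axis] + np.cumsum(steps, axis=0)
    return out


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Multi-origin MSD of a scalar series via the FFT autocorrelation trick."""
    T = len(x)
    n_fft = 1 << (2 * T - 1).bit_length()
    X = np.fft.rfft(x, n_fft)
    s2 = np.fft.irfft(X * np.conjugate(X), n_fft)[:T].real
    sq = x * x
    # S1(k) = sum_{t} x(t)^2 + x(t+k)^2 over valid origins, by running sums
    ssum = 2.0 * sq.sum()
    s1 = np.empty(T)
    s1[0] = ssum
    for k in range(1, T):
        ssum -= sq[k - 1] + sq[T - k]
        s1[k] = ssum
    counts = T - np.arange(T)
    return s1 / counts - 2.0 * s2 / counts


def msd(
    traj: Trajectory,
    roles: Iterable[str] = ("backbone", "base"),
    multi_origin: bool = True,
    unwrap: bool = True,
) -> MSDCurve:
    """Mean square displacement of the centre of mass of the selected beads.

    MSD(k) = <|r(t+k) - r(t)|^2>, averaged over all time origins t when
    *multi_origin* is set (the default), or referenced to the first frame
    only otherwise.  Beads are weighted equally (a common coarse-grained
    convention: near-uniform bead masses).
    """
    mask = traj.role_mask(roles)
    if not mask.any():
        raise TrajectoryError(f"empty bead selection for roles {tuple(roles)}")
    if traj.n_frames < 2:
        raise TrajectoryError("need at least two frames for MSD")
    pos = traj.positions[:, mask, :]
    if unwrap:
        pos = _unwrap(pos, traj.box, traj.periodic_axis)
    com = pos.mean(axis=1)  # (T, 3)
    T = com.shape[0]
    lags = np.arange(T)
    if multi_origin:
        vals = np.zeros(T)
        for dim in range(3):
            vals += _msd_fft_1d(np.ascontiguousarray(com[:, dim]))
        vals[0] = 0.0
    else:
        vals = np.sum((com - com[0]) ** 2, axis=1)
    return MSDCurve(lags=lags, msd=vals)
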