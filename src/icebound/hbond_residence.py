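"""Hydrogen-bond detection and forward-lifetime water residence times.

Water residence time on a protein surface is estimated as the *forward
lifetime* of protein-water hydrogen bonds: the mean duration of maximal
uninterrupted bonded runs, measured from bond formation to first break.
Runs truncated by either trajectory end are excluded by default (the break
is never observed), and a one-frame break terminates a run — there is no
grace period unless one is configured.

Bonds are detected per frame with a geometric criterion (donor-acceptor
distance, and the hydrogen-donor-acceptor angle when hydrogens are
present; distance-only otherwise).  Aggregation by surface region (e.g.
ice-binding site vs the rest of the surface) pools the completed runs of
every bond whose protein residue position falls in the region.

This module post-processes trajectories or precomputed event tables; it
never runs a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import RegionDefinition

__all__ = [
    "HBondEventTable",
    "ResidenceResult",
    "detect_hbonds",
    "forward_lifetime",
    "region_residence",
    "read_event_table",
    "write_event_table",
]

DEFAULT_D_CUT = 3.5  # A, donor-acceptor distance
DEFAULT_ANGLE_CUT = 30.0  # degrees from linear, hydrogen-donor-acceptor


@dataclass
class HBondEventTable:
    """Per-bond boolean occupancy series on a uniform frame grid.

    Keys are ``(residue_position, water_id)``; every series has the same
    length; ``dt`` is the frame interval in picoseconds.
    """

    dt: float
    series: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = None
        for key, s in list(self.series.items()):
            s = np.asarray(s, dtype=bool)
            self.series[key] = s
            if n is None:
                n = len(s)
            elif len(s) != n:
                raise ValueError(f"series length mismatch at {key}")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.series.values()))) if self.series else 0


@dataclass
class ResidenceResult:
    """Pooled forward lifetimes (ps) and run counts by surface region."""

    lifetimes: dict[str, float]  # region -> mean forward lifetime, ps
    run_counts: dict[str, int]
    bond_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": r,
                "mean_lifetime_ps": self.lifetimes[r],
                "n_runs": self.run_counts[r],
                "n_bonds": self.bond_counts[r],
            }
            for r in self.lifetimes
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_hbonds(
    frames: np.ndarray,
    protein_sites: list[tuple[int, int]],
    water_sites: list[tuple[int, str]],
    dt: float,
    d_cut: float = DEFAULT_D_CUT,
    angle_cut: float = DEFAULT_ANGLE_CUT,
    hydrogen_index: dict[int, int] | None = None,
) -> HBondEventTable:
    """Per-frame protein-water hydrogen-bond occupancy.

    Parameters
    ----------
    frames : (n_frames, n_atoms, 3) array
        Trajectory coordinates in angstrom, shared atom ordering.
    protein_sites : list of (atom_index, residue_position)
        Protein donor/acceptor heavy atoms.
    water_sites : list of (atom_index, water_id)
        Water oxygen atoms.
    dt : frame interval, ps.
    d_cut, angle_cut : geometric criterion.
    hydrogen_index : optional map donor atom index -> hydrogen atom index;
        when given for a donor, the hydrogen-donor-acceptor angle must also
        be within ``angle_cut`` of linear (0 deg = linear here).

    A bond series is recorded for every (residue position, water) pair that
    is bonded in at least one frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n_frames, n_atoms, 3) array")
    p_idx = np.array([i for i, _ in protein_sites])
    w_idx = np.array([i for i, _ in water_sites])
    n_frames = frames.shape[0]
    occ = np.zeros((n_frames, len(p_idx), len(w_idx)), dtype=bool)
    for f in range(n_frames):
        P = frames[f, p_idx]
        W = frames[f, w_idx]
        diff = P[:, None, :] - W[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        ok = dist <= d_cut
        if hydrogen_index:
            for a, (atom_i, _) in enumerate(protein_sites):
                h = hydrogen_index.get(atom_i)
                if h is None:
                    continue
                Hp = frames[f, h]
                Dp = frames[f, atom_i]
                dh = Hp - Dp
                for b in range(len(w_idx)):
                    if not ok[a, b]:
                        continue
                    da = W[b] - Dp
                    cosang = float(
                        dh @ da / (np.linalg.norm(dh) * np.linalg.norm(da) + 1e-12)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang > angle_cut:
                        ok[a, b] = False
        occ[f] = ok
    series: dict[tuple[int, str], np.ndarray] = {}
    for a, (_, respos) in enumerate(protein_sites):
        for b, (_, wid) in enumerate(water_sites):
            s = occ[:, a, b]
            if s.any():
                key = (respos, wid)
                series[key] = series[key] | s if key in series else s.copy()
    return HBondEventTable(dt=dt, series=series)


# ---------------------------------------------------------------------------
# forward lifetime
# ---------------------------------------------------------------------------

def _runs(series: np.ndarray, include_truncated: bool, grace: int = 0) -> list[int]:
    """Lengths (frames) of maximal bonded runs; optionally bridge short breaks."""
    s = np.asarray(series, dtype=bool).copy()
    if grace > 0:
        # bridge interior unbonded gaps of length <= grace
        padded = np.concatenate([[True], s, [True]])
        d = np.diff(padded.astype(int))
        gap_starts = np.where(d == -1)[0]
        gap_ends = np.where(d == 1)[0]
        for a, b in zip(gap_starts, gap_ends):
            if 0 < a and b < len(s) and b - a <= grace:
                s[a:b] = True
    padded = np.concatenate([[False], s, [False]])
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    out = []
    for a, b in zip(starts, ends):
        truncated = a == 0 or b == len(s)
        if truncated and not include_truncated:
            continue
        out.append(b - a)
    return out


def forward_lifetime(
    table: HBondEventTable,
    include_truncated: bool = False,
    grace_frames: int = 0,
) -> tuple[float, dict[tuple[int, str], float], int]:
    """Mean forward lifetime, pooled over all bonds.

    A maximal contiguous bonded run of k frames has lifetime ``k * dt``.
    Returns ``(pooled_mean_ps, per_bond_mean_ps, n_completed_runs)``; bonds
    whose only runs are truncated contribute no completed runs and are
    absent from the per-bond map.
    """
    if not table.series:
        raise ValueError("event table has no bonded series")
    per_bond: dict[tuple[int, str], float] = {}
    all_runs: list[int] = []
    for key, s in table.series.items():
        runs = _runs(s, include_truncated, grace_frames)
        if runs:
            per_bond[key] = float(np.mean(runs) * table.dt)
            all_runs.extend(runs)
    if not all_runs:
        raise ValueError(
            "no completed hydrogen-bond runs (all runs truncated by the "
            "trajectory ends); pass include_truncated=True to count them"
        )
    pooled = float(np.mean(all_runs) * table.dt)
    return pooled, per_bond, len(all_runs)


def region_residence(
    table: HBondEventTable,
    regions: RegionDefinition,
    sequence_length: int | None = None,
    include_truncated: bool = False,
    grace_frames: int = 0,
) -> ResidenceResult:
    """Pooled forward lifetime per named region, plus complement and whole.

    Every bond's residue position is classified into one of the named
    regions or, failing that, into ``"non-<first region>"``; a ``"whole"``
    entry pools everything.  Positions beyond ``sequence_length`` (when
    given) raise.  Regions with bonds but no completed runs are reported
    as NaN; regions with no bonds at all are absent from the result.
    """
    if not table.series:
        raise ValueError("event table has no bonded series")
    first = next(iter(regions.regions))
    complement = f"non-{first}"
    runs_by_region: dict[str, list[int]] = {}
    bonds_by_region: dict[str, int] = {}
    for (respos, _wid), s in table.series.items():
        if respos < 1 or (sequence_length is not None and respos > sequence_length):
            raise ValueError(f"residue position {respos} outside the sequence")
        region = regions.classify(respos) or complement
        for name in (region, "whole"):
            runs = _runs(s, include_truncated, grace_frames)
            runs_by_region.setdefault(name, []).extend(runs)
            bonds_by_region[name] = bonds_by_region.get(name, 0) + 1
    lifetimes = {}
    run_counts = {}
    for name, runs in runs_by_region.items():
        lifetimes[name] = float(np.mean(runs) * table.dt) if runs else float("nan")
        run_counts[name] = len(runs)
    return ResidenceResult(lifetimes, run_counts, bonds_by_region)


# ---------------------------------------------------------------------------
# event-table I/O (CSV: frame, residue_position, water_id, bonded)
# ---------------------------------------------------------------------------

def write_event_table(table: HBondEventTable, path: str | Path) -> None:
    rows = []
    for (respos, wid), s in sorted(table.series.items()):
        for frame, bonded in enumerate(s):
            rows.append((frame, respos, wid, int(bonded)))
    df = pd.DataFrame(rows, columns=["frame", "residue_position", "water_id", "bonded"])
    df.attrs["dt"] = table.dt
    with open(path, "w") as fh:
        fh.write(f"# dt_ps={table.dt}\n")
        df.to_csv(fh, index=False)


def read_event_table(path: str | Path, dt: float | None = None) -> HBondEventTable:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if dt is None and "dt_ps=" in first:
            dt = float(first.split("dt_ps=")[1])
    if dt is None:
        raise ValueError("dt must be given or recorded in the file header")
    df = pd.read_csv(path, skiprows=skip)
    n_frames = int(df["frame"].max()) + 1
    series: dict[tuple[int, str], np.ndarray] = {}
    for (respos, wid), grp in df.groupby(["residue_position", "water_id"]):
        s = np.zeros(n_frames, dtype=bool)
        s[grp["frame"].to_numpy(int)] = grp["bonded"].to_numpy(int).astype(bool)
        series[(int(respos), str(wid))] = s
    return HBondEventTable(dt=dt, series=series)
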