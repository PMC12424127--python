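"""Per-track directed-migration statistics and radial-bin aggregation.

Metric definitions (tip = pipette tip, r(t) = distance of the cell from
the tip, path = sum of frame-to-frame step lengths):

* directed-migration efficiency (chemotactic index):
  (r_first - r_last) / path — net radial approach over total distance
  covered, in [-1, 1]; positive = net approach.
* speed: path / elapsed time, um/min — path, not displacement.
* line speed to the tip: (r_first - r_last) / elapsed, um/min (signed).
* straightness: |p_last - p_first| / path, in [0, 1]; tip-independent.
* MSD(tau): ensemble mean over cells of |p(t_first + tau) - p(t_first)|^2
  — displacement from each track's origin, no sliding-window averaging
  (a time-averaged variant is available behind a flag).

Cells are grouped by their distance from the tip at the first analyzed
frame into half-open 100 um radial bins (default 100-500 um); experiment-
level summaries average per-experiment bin means, with n = experiments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tracking import TrackSet
from .walks import Trajectory

__all__ = [
    "path_length",
    "migration_efficiency",
    "speed",
    "burst_speed",
    "fit_msd_slope",
    "line_speed_to_tip",
    "straightness",
    "track_metrics",
    "msd",
    "radial_bin",
    "flower_transform",
    "aggregate_by_experiment",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (100.0, 200.0, 300.0, 400.0, 500.0)


def _steps(track: Trajectory) -> np.ndarray:
    return np.linalg.norm(np.diff(track.positions, axis=0), axis=1)


def path_length(track: Trajectory) -> float:
    """Total distance covered: sum of frame-to-frame step lengths, um."""
    if len(track) < 2:
        raise ValueError("track needs >= 2 points")
    return float(_steps(track).sum())


def migration_efficiency(
    track: Trajectory,
    tip: tuple[float, float],
    mode: str = "net",
) -> float:
    """Distance traveled toward the gradient center over total distance.

    ``mode='net'`` (default): net radial approach (r_first - r_last)
    divided by path length — bounded in [-1, 1] and exactly equal to
    line_speed_to_tip / speed.  ``mode='positive_steps'`` instead sums
    only the positive radial decrements.
    A stationary track (zero path) has no defined efficiency.
    """
    p = path_length(track)
    if p == 0:
        raise ValueError("stationary track: efficiency undefined")
    r = track.radii(tip)
    if mode == "net":
        toward = r[0] - r[-1]
    elif mode == "positive_steps":
        toward = float(np.clip(-np.diff(r), 0.0, None).sum())
    else:
        raise ValueError(f"unknown efficiency mode {mode!r}")
    return float(toward / p)


def speed(track: Trajectory) -> float:
    """Total path length over elapsed time, um/min."""
    if len(track) < 2:
        raise ValueError("track needs >= 2 points")
    elapsed = track.times[-1] - track.times[0]
    return float(path_length(track) / elapsed * 60.0)


def line_speed_to_tip(track: Trajectory, tip: tuple[float, float]) -> float:
    """Mean velocity toward the gradient center, um/min (signed)."""
    if len(track) < 2:
        raise ValueError("track needs >= 2 points")
    r = track.radii(tip)
    elapsed = track.times[-1] - track.times[0]
    return float((r[0] - r[-1]) / elapsed * 60.0)


def burst_speed(track: Trajectory) -> float:
    """Peak frame-to-frame speed within a track, um/min.

    The maximum single-step displacement divided by the frame interval —
    the 'peak burst' counterpart of the mean speed.
    """
    if len(track) < 2:
        raise ValueError("track needs >= 2 points")
    steps = _steps(track)
    dts = np.diff(track.times)
    return float((steps / dts).max() * 60.0)


def straightness(track: Trajectory) -> float:
    """Net displacement over path length; 1 = perfectly straight."""
    p = path_length(track)
    if p == 0:
        raise ValueError("stationary track: straightness undefined")
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    return net / p


def track_metrics(
    tracks: TrackSet | list[Trajectory],
    tip: tuple[float, float],
    efficiency_mode: str = "net",
) -> pd.DataFrame:
    """Per-track metric table; stationary tracks are excluded with a reason."""
    rows = []
    for tr in tracks:
        base = {"cell_id": tr.cell_id, "population": tr.population,
                "r0_um": float(tr.radii(tip)[0]), "n_frames": len(tr)}
        try:
            p = path_length(tr)
            if p == 0:
                raise ValueError("stationary")
            rows.append(
                base
                | {
                    "efficiency": migration_efficiency(tr, tip, efficiency_mode),
                    "speed_um_min": speed(tr),
                    "line_speed_um_min": line_speed_to_tip(tr, tip),
                    "straightness": straightness(tr),
                    "path_length_um": p,
                    "net_displacement_um": float(
                        np.linalg.norm(tr.positions[-1] - tr.positions[0])
                    ),
                    "excluded": "",
                }
            )
        except ValueError as e:
            rows.append(base | {"excluded": str(e)})
    return pd.DataFrame(rows)


def msd(
    tracks: TrackSet | list[Trajectory],
    max_lag: float | None = None,
    min_cells: int = 5,
    time_averaged: bool = False,
) -> pd.DataFrame:
    """Ensemble mean squared displacement versus time lag.

    All tracks must share one frame interval.  For each lag, tracks long
    enough contribute |p(origin + lag) - p(origin)|^2 (or, with
    ``time_averaged=True``, the within-track mean over all sample pairs
    at that lag).  Lags with fewer than ``min_cells`` contributing cells
    are dropped.  Returns columns (lag_s, msd_um2, sem, n).
    """
    tracks = list(tracks)
    if not tracks:
        return pd.DataFrame(columns=["lag_s", "msd_um2", "sem", "n"])
    dts = {round(float(np.diff(tr.times).mean()), 9) for tr in tracks if len(tr) > 1}
    if len(dts) > 1:
        raise ValueError("tracks must share a uniform frame interval")
    dt = dts.pop()
    max_k = max(len(tr) - 1 for tr in tracks)
    if max_lag is not None:
        max_k = min(max_k, int(np.floor(max_lag / dt + 1e-9)))
    rows = []
    for k in range(1, max_k + 1):
        vals = []
        for tr in tracks:
            if len(tr) <= k:
                continue
            if time_averaged:
                d = tr.positions[k:] - tr.positions[:-k]
                vals.append(float((d**2).sum(axis=1).mean()))
            else:
                d = tr.positions[k] - tr.positions[0]
                vals.append(float((d**2).sum()))
        if len(vals) >= min_cells:
            vals = np.asarray(vals)
            n = vals.size
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append((k * dt, float(vals.mean()), sem, n))
    out = pd.DataFrame(rows, columns=["lag_s", "msd_um2", "sem", "n"])
    if out.empty:
        warnings.warn("no lag has enough contributing tracks", stacklevel=2)
    return out


def fit_msd_slope(curve: pd.DataFrame, n_lags: int = 10) -> float:
    """Slope of a diffusive (linear, zero-intercept) MSD curve, um^2/s.

    Weighted least squares through the origin over the first ``n_lags``
    lags, weighting by 1/sem^2 — for an unbiased walk MSD(tau) =
    4 * D_eff * tau exactly, so the intercept is not a free parameter
    and early, well-estimated lags dominate.
    """
    head = curve.head(n_lags)
    lag = head["lag_s"].to_numpy()
    m = head["msd_um2"].to_numpy()
    sem = head["sem"].to_numpy()
    w = np.where(np.isfinite(sem) & (sem > 0), 1.0 / sem**2, 1.0)
    return float((w * lag * m).sum() / (w * lag**2).sum())


def radial_bin(
    tracks: TrackSet | list[Trajectory],
    tip: tuple[float, float],
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Assign each track to a half-open radial bin [e_i, e_{i+1}).

    Membership is frozen at the first analyzed frame.  Tracks with
    r0 below the first edge or at/above the last are labelled
    "out_of_range" and reported separately, never silently dropped.
    Returns columns (cell_id, r0_um, bin).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    labels = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(edges.size - 1)]
    rows = []
    for tr in tracks:
        r0 = float(tr.radii(tip)[0])
        i = int(np.searchsorted(edges, r0, side="right")) - 1
        bin_label = labels[i] if 0 <= i < len(labels) else "out_of_range"
        rows.append((tr.cell_id, r0, bin_label))
    return pd.DataFrame(rows, columns=["cell_id", "r0_um", "bin"])


def flower_transform(
    tracks: TrackSet | list[Trajectory],
    tip: tuple[float, float],
) -> list[Trajectory]:
    """Translate all tracks so the pipette tip is the origin.

    A rigid translation: pairwise distances and all metrics are
    unchanged; used for 'flower plot' overlays of trajectories.
    """
    tip = np.asarray(tip, dtype=float)
    return [
        Trajectory(
            cell_id=tr.cell_id,
            times=tr.times.copy(),
            positions=tr.positions - tip,
            population=tr.population,
        )
        for tr in tracks
    ]


def aggregate_by_experiment(
    per_cell: pd.DataFrame,
    value_cols: list[str] | None = None,
    experiment_col: str = "experiment",
    bin_col: str = "bin",
) -> pd.DataFrame:
    """Two-level aggregation: per-(experiment, bin) means, then mean and
    s.e.m. across experiment means.

    ``n`` reports the number of independent experiments contributing to a
    bin, not the number of cells, so cell-count imbalance across
    experiments does not weight the summary.  With a single experiment
    the s.e.m. is undefined and reported as NaN.
    Returns long-format columns (bin, metric, mean, sem, n_experiments,
    n_cells).
    """
    if value_cols is None:
        value_cols = [
            c
            for c in per_cell.columns
            if c not in (experiment_col, bin_col)
            and pd.api.types.is_numeric_dtype(per_cell[c])
        ]
    rows = []
    for bin_label, grp in per_cell.groupby(bin_col, sort=True):
        for col in value_cols:
            exp_means = grp.groupby(experiment_col)[col].mean().dropna()
            if exp_means.empty:
                continue
            n = exp_means.size
            sem = float(exp_means.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append(
                {
                    "bin": bin_label,
                    "metric": col,
                    "mean": float(exp_means.mean()),
                    "sem": sem,
                    "n_experiments": n,
                    "n_cells": int(grp[col].notna().sum()),
                }
            )
    return pd.DataFrame(rows)
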