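"""Biased persistent random-walk model of microglial chemotaxis.

Cells take steps at fixed intervals ``dt``.  Step headings follow a von
Mises distribution centred on a drift vector that combines the previous
heading (persistence) with a radial attraction toward the pipette tip
whose weight decays linearly with distance and vanishes beyond the
sensing range (~400 um, the distance beyond which tracked cells move as
an unbiased random walk).  Step lengths are gamma distributed with mean
``mean_step_speed * dt`` — positive support, with the coefficient of
variation controlling the burstiness of frame-to-frame speeds.

With zero chemotactic sensitivity and zero persistence the model reduces
to an isotropic random walk with ensemble MSD(tau) = 4 * D_eff * tau,
D_eff = E[step^2] / (4 dt); in the large-sensitivity limit every step
points at the tip and the walk is ballistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gradient import GradientSource
from .presets import TreatmentPreset
from .seeding import as_seed_sequence

__all__ = ["MotilityParams", "Trajectory", "simulate_trajectories", "tracks_to_frame"]

# von Mises concentration per unit drift magnitude; 2.0 makes the
# directional correlation E[cos dtheta] ~ persistence for small values
# (I1/I0(c) ~ c/2).
_VM_GAIN = 2.0

# cells spawn uniformly in this annulus around the tip (um) unless start
# positions are supplied; keeps the default population inside the imaged
# field while spanning the radial bins
DEFAULT_SPAWN_ANNULUS = (100.0, 400.0)


@dataclass(frozen=True)
class MotilityParams:
    """Motility parameters of one cell population.

    Defaults are the packaged iMG preset, calibrated once so the full
    simulate -> render -> track -> metrics pipeline reports the
    system-level mean speed (~5 um/min) and burst speed (~10 um/min).
    """

    mean_step_speed: float = 5.0  # um/min
    speed_cv: float = 0.45
    persistence: float = 0.3
    chemotactic_sensitivity: float = 1.2  # kappa
    sensing_range: float = 400.0  # um
    dt: float = 15.0  # s per step

    def __post_init__(self) -> None:
        if self.mean_step_speed < 0 or self.speed_cv < 0:
            raise ValueError("speed parameters must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if self.chemotactic_sensitivity < 0:
            raise ValueError("chemotactic_sensitivity must be >= 0")
        if self.sensing_range <= 0 or self.dt <= 0:
            raise ValueError("sensing_range and dt must be > 0")


@dataclass
class Trajectory:
    """Time-stamped 2-D positions of one cell, in micrometres."""

    cell_id: int | str
    times: np.ndarray  # (n,), s, strictly increasing, uniform spacing
    positions: np.ndarray  # (n, 2), um
    population: str = "population_A"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise ValueError("times must be (n,), positions (n, 2)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return self.times.size

    def radii(self, tip: tuple[float, float]) -> np.ndarray:
        """Euclidean distance to the tip at every sample, um."""
        return np.hypot(
            self.positions[:, 0] - tip[0], self.positions[:, 1] - tip[1]
        )


def _bias_weight(r: float, sensing_range: float) -> float:
    # clipped-linear attraction: full at the tip, zero beyond sensing_range
    return max(0.0, 1.0 - r / sensing_range)


def _simulate_one(
    rng: np.random.Generator,
    params: MotilityParams,
    preset: TreatmentPreset,
    tip: np.ndarray,
    start: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    kappa = params.chemotactic_sensitivity * preset.kappa_multiplier
    mean_len = params.mean_step_speed * preset.speed_multiplier * params.dt / 60.0
    cv = params.speed_cv
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    heading = rng.uniform(0.0, 2.0 * np.pi)
    if cv > 0 and mean_len > 0:
        shape = 1.0 / cv**2
        lengths = rng.gamma(shape, mean_len / shape, size=n_steps)
    else:
        lengths = np.full(n_steps, mean_len)
    for i in range(n_steps):
        to_tip = tip - pos[i]
        r = float(np.hypot(*to_tip))
        drift = params.persistence * np.array([np.cos(heading), np.sin(heading)])
        if kappa > 0 and r > 0:
            drift = drift + kappa * _bias_weight(r, params.sensing_range) * to_tip / r
        mag = float(np.hypot(*drift))
        if mag < 1e-12:
            theta = rng.uniform(0.0, 2.0 * np.pi)
        else:
            theta = rng.vonmises(np.arctan2(drift[1], drift[0]), _VM_GAIN * mag)
        heading = theta
        pos[i + 1] = pos[i] + lengths[i] * np.array([np.cos(theta), np.sin(theta)])
    return pos


def spawn_positions(
    n_cells: int,
    tip: np.ndarray,
    spawn_annulus: tuple[float, float],
    min_separation: float,
    seed,
) -> np.ndarray:
    """Uniform-by-area spawn points in an annulus with a minimum spacing.

    With ``min_separation > 0`` points are drawn by rejection (dart
    throwing), emulating a well-separated plating; with 0 the draw is
    plain uniform.  Deterministic given the seed.
    """
    rng = np.random.default_rng(as_seed_sequence(seed))
    r_lo, r_hi = spawn_annulus
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_cells:
        attempts += 1
        if attempts > 10000 * n_cells:
            raise ValueError("cannot place cells at this min_separation")
        r0 = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        p = tip + r0 * np.array([np.cos(phi), np.sin(phi)])
        if min_separation > 0 and pts:
            if np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) < min_separation:
                continue
        pts.append(p)
    return np.asarray(pts)


def simulate_trajectories(
    params: MotilityParams,
    preset: TreatmentPreset,
    source: GradientSource,
    n_cells: int,
    duration: float,
    seed: int,
    start_positions: np.ndarray | None = None,
    population: str = "population_A",
    spawn_annulus: tuple[float, float] = DEFAULT_SPAWN_ANNULUS,
    min_separation: float = 0.0,
) -> list[Trajectory]:
    """Simulate ``n_cells`` biased persistent random walks under a gradient.

    One top-level seed fans out into independent per-cell substreams, so
    increasing ``n_cells`` extends the ensemble without perturbing the
    cells already generated.  If ``start_positions`` is None, each cell
    spawns uniformly (by area) in ``spawn_annulus`` around the tip.

    Returns one :class:`Trajectory` per cell with uniform spacing
    ``params.dt`` covering ``duration`` seconds.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if duration < params.dt:
        raise ValueError("duration must be >= dt")
    n_steps = int(np.floor(duration / params.dt))
    times = np.arange(n_steps + 1) * params.dt
    tip = np.asarray(source.tip_position, dtype=float)
    top = as_seed_sequence(seed)
    if start_positions is None and min_separation > 0:
        # dart-throwing spawn couples cells, so it uses its own substream;
        # the per-cell walk substreams below stay independent of n_cells
        spawn_ss, walk_ss = top.spawn(2)
        start_positions = spawn_positions(
            n_cells, tip, spawn_annulus, min_separation, spawn_ss
        )
        streams = walk_ss.spawn(n_cells)
    else:
        streams = top.spawn(n_cells)
    tracks: list[Trajectory] = []
    for i in range(n_cells):
        rng = np.random.default_rng(streams[i])
        if start_positions is not None:
            start = np.asarray(start_positions[i], dtype=float)
            rng.uniform()  # keep stream alignment with the spawn branch
            rng.uniform()
        else:
            r_lo, r_hi = spawn_annulus
            r0 = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            start = tip + r0 * np.array([np.cos(phi), np.sin(phi)])
        pos = _simulate_one(rng, params, preset, tip, start, n_steps)
        tracks.append(
            Trajectory(cell_id=i, times=times.copy(), positions=pos,
                       population=population)
        )
    return tracks


def tracks_to_frame(tracks: list[Trajectory]) -> pd.DataFrame:
    """Long-format table (cell_id, frame, t_s, x_um, y_um, population)."""
    rows = []
    for tr in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(len(tr)),
                    "t_s": tr.times,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                    "population": tr.population,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["cell_id", "frame", "t_s", "x_um", "y_um", "population"]
        )
    return pd.concat(rows, ignore_index=True)
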