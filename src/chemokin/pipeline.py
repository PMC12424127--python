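"""End-to-end scenario runs: simulate -> render -> track -> metrics.

A scenario is one experimental condition (treatment preset) run for a
configured number of independent experiments.  Each experiment simulates
biased persistent random walks under the pulsed gradient, optionally
renders them to an image stack and recovers tracks through the full
imaging chain (trim/downsample, background subtraction, segmentation,
linking, min-length filter), computes per-track migration metrics and
radially binned summaries, and generates matched per-cell Ca2+ traces
and metrics.  Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from .gradient import GradientSource
from .migration import (
    DEFAULT_BIN_EDGES,
    aggregate_by_experiment,
    msd,
    radial_bin,
    track_metrics,
)
from .presets import get_preset
from .rendering import DEFAULT_IMAGE_SHAPE, DEFAULT_PIXEL_SIZE, render_frames
from .seeding import as_seed_sequence
from .tracking import (
    FrameSeries,
    TrackSet,
    exclude_tracks,
    filter_min_length,
    link_tracks,
    segment_series,
    subtract_background,
    trim_and_downsample,
)
from .traces import CalciumModel, simulate_calcium
from .walks import MotilityParams, Trajectory, simulate_trajectories

__all__ = ["RunConfig", "ScenarioReport", "run_scenario", "compare_conditions"]


def _default_gradient() -> dict:
    return {
        "tip_xy_um": [422.5, 422.5],  # center of the 650 px field at 1.3 um/px
        "pulse_rate_hz": 0.5,
        "pulse_ms": 20.0,
        "diffusion_um2_s": 300.0,
        "pipette_conc_uM": 50.0,
    }


def _default_motility() -> dict:
    return {k: getattr(MotilityParams(), k) for k in (
        "mean_step_speed", "speed_cv", "persistence",
        "chemotactic_sensitivity", "sensing_range", "dt")}


def _default_imaging() -> dict:
    return {
        "image_shape": list(DEFAULT_IMAGE_SHAPE),
        "pixel_um": DEFAULT_PIXEL_SIZE,
        "blob_sigma_px": 3.0,
        "intensity": 600.0,
        "background": 100.0,
        "noise": True,
    }


def _default_tracking() -> dict:
    return {
        "start_after_release_s": 60.0,
        "window_s": 600.0,
        "target_interval_s": 15.0,
        "min_area_px": 9,
        "max_disp_um": None,  # None -> 3 * mean step per frame
        "min_length": 20,
        "exclude_track_ids": [],
    }


def _default_metrics() -> dict:
    return {"bin_edges_um": list(DEFAULT_BIN_EDGES), "efficiency_mode": "net"}


def _default_spawn() -> dict:
    return {"annulus_um": [100.0, 400.0], "min_separation_um": 0.0}


def _default_calcium() -> dict:
    d = {k: getattr(CalciumModel(), k) for k in (
        "baseline_r0", "peak_amp_at_0", "peak_decay_length", "peak_rise_tau",
        "peak_decay_tau", "plateau_amp_at_0", "plateau_rise_tau",
        "plateau_delay_s", "noise_sd", "stimulus_onset")}
    d.update({"duration_s": 160.0, "dt_s": 1.0})
    return d


@dataclass
class RunConfig:
    """Fully serializable configuration of one scenario run."""

    preset: str = "control"
    seed: int = 1
    n_cells: int = 200
    n_experiments: int = 1
    duration_s: float = 660.0  # simulated time from release (trim + window)
    track_from_images: bool = True
    gradient: dict = field(default_factory=_default_gradient)
    spawn: dict = field(default_factory=_default_spawn)
    motility: dict = field(default_factory=_default_motility)
    imaging: dict = field(default_factory=_default_imaging)
    tracking: dict = field(default_factory=_default_tracking)
    metrics: dict = field(default_factory=_default_metrics)
    calcium: dict = field(default_factory=_default_calcium)

    def source(self) -> GradientSource:
        g = self.gradient
        return GradientSource(
            tip_position=tuple(g["tip_xy_um"]),
            pulse_rate=g["pulse_rate_hz"],
            pulse_duration=g["pulse_ms"] / 1000.0,
            diffusion_coefficient=g["diffusion_um2_s"],
            pipette_concentration=g["pipette_conc_uM"],
        )

    def motility_params(self) -> MotilityParams:
        return MotilityParams(**self.motility)

    def calcium_model(self) -> CalciumModel:
        c = {k: v for k, v in self.calcium.items() if k not in ("duration_s", "dt_s")}
        return CalciumModel(**c)

    def max_disp_um(self) -> float:
        md = self.tracking.get("max_disp_um")
        if md is not None:
            return float(md)
        p = self.motility_params()
        return 3.0 * p.mean_step_speed / 60.0 * self.tracking["target_interval_s"]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = cls()
        kwargs = {}
        for k, v in raw.items():
            if not hasattr(base, k):
                raise KeyError(f"unknown config key {k!r}")
            cur = getattr(base, k)
            kwargs[k] = {**cur, **v} if isinstance(cur, dict) else v
        return cls(**kwargs)


@dataclass
class ScenarioReport:
    """Tables produced by one scenario run; every figure is backed by one."""

    config: RunConfig
    per_cell: pd.DataFrame  # migration metrics + bin + experiment
    summary: pd.DataFrame  # per-bin mean +/- sem over experiments
    msd_by_bin: pd.DataFrame  # (bin, lag_s, msd_um2, sem, n)
    calcium_per_cell: pd.DataFrame
    calcium_summary: pd.DataFrame
    calcium_timecourses: pd.DataFrame  # (t_s, bin, mean_drr, n)
    tracks: list[Trajectory] = field(default_factory=list)  # last experiment
    log: list[str] = field(default_factory=list)

    def write(self, out_dir, figures: bool = True) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.per_cell.to_csv(out / "per_cell_metrics.csv", index=False)
        self.summary.to_csv(out / "bin_summary.csv", index=False)
        self.msd_by_bin.to_csv(out / "msd_by_bin.csv", index=False)
        self.calcium_per_cell.to_csv(out / "calcium_per_cell.csv", index=False)
        self.calcium_summary.to_csv(out / "calcium_summary.csv", index=False)
        self.calcium_timecourses.to_csv(out / "calcium_timecourses.csv", index=False)
        (out / "run.log").write_text("\n".join(self.log) + "\n")
        if figures:
            from . import plots

            tip = tuple(self.config.gradient["tip_xy_um"])
            if self.tracks:
                plots.flower_plot(self.tracks, tip, out / "flower.png")
            if not self.msd_by_bin.empty:
                plots.msd_plot(self.msd_by_bin, out / "msd.png")
            if not self.summary.empty:
                plots.metric_by_bin_plot(
                    self.summary, "efficiency", out / "efficiency_by_bin.png"
                )
            if not self.calcium_timecourses.empty:
                plots.calcium_timecourse_plot(
                    self.calcium_timecourses, out / "calcium_timecourses.png"
                )


def _trim_trajectory(
    tr: Trajectory, t_start: float, t_end: float, stride: int
) -> Trajectory | None:
    mask = np.flatnonzero(
        (tr.times >= t_start - 1e-9) & (tr.times <= t_end + 1e-9)
    )
    if mask.size == 0:
        return None
    keep = mask[::stride]
    if keep.size < 2:
        return None
    return Trajectory(
        cell_id=tr.cell_id,
        times=tr.times[keep],
        positions=tr.positions[keep],
        population=tr.population,
    )


def _tracks_from_simulation(config: RunConfig, sim_tracks: list[Trajectory]) -> TrackSet:
    """Fast route: analysis-window tracks taken directly from simulation."""
    tk = config.tracking
    dt = config.motility["dt"]
    stride = int(np.ceil(round(tk["target_interval_s"] / dt, 9)))
    t0 = tk["start_after_release_s"]
    t1 = t0 + tk["window_s"]
    kept = []
    for tr in sim_tracks:
        out = _trim_trajectory(tr, t0, t1, stride)
        if out is not None:
            kept.append(out)
    ts = TrackSet(tracks=kept, linking={"route": "ground_truth"})
    return filter_min_length(ts, tk["min_length"])


def _tracks_from_images(
    config: RunConfig, sim_tracks: list[Trajectory], render_seed
) -> tuple[TrackSet, pd.DataFrame]:
    """Image route: render, trim/downsample, subtract, segment, link."""
    img = config.imaging
    tk = config.tracking
    stack, gt = render_frames(
        sim_tracks,
        image_shape=tuple(img["image_shape"]),
        pixel_size=img["pixel_um"],
        blob_sigma=img["blob_sigma_px"],
        intensities=img["intensity"],
        background=img["background"],
        noise=img["noise"],
        seed=render_seed,
    )
    series = FrameSeries(
        images=stack,
        frame_interval=config.motility["dt"],
        pixel_size=img["pixel_um"],
        t0_offset=0.0,
    )
    series = trim_and_downsample(
        series,
        start_after_release=tk["start_after_release_s"],
        window=tk["window_s"],
        target_interval=tk["target_interval_s"],
    )
    series = subtract_background(series)
    cents = segment_series(series, min_area=tk["min_area_px"])
    trackset = link_tracks(
        cents,
        frame_interval=series.frame_interval,
        max_disp=config.max_disp_um(),
        min_length=tk["min_length"],
        t_first_frame=-series.t0_offset,
    )
    return trackset, gt


def run_scenario(config: RunConfig) -> ScenarioReport:
    """Execute one condition end to end and return its report."""
    preset = get_preset(config.preset)
    source = config.source()
    params = config.motility_params()
    tip = tuple(config.gradient["tip_xy_um"])
    edges = tuple(config.metrics["bin_edges_um"])
    log = [f"preset={config.preset} seed={config.seed} "
           f"n_cells={config.n_cells} n_experiments={config.n_experiments}"]

    all_cells, all_ca, last_tracks = [], [], []
    tracks_by_bin: dict[str, list[Trajectory]] = {}
    ca_trace_sums: dict[str, np.ndarray] = {}
    ca_trace_counts: dict[str, int] = {}
    ca_times = None

    for e, child in enumerate(as_seed_sequence(config.seed).spawn(config.n_experiments)):
        sim_ss, render_ss, ca_ss = child.spawn(3)
        sim_tracks = simulate_trajectories(
            params, preset, source, config.n_cells, config.duration_s, sim_ss,
            spawn_annulus=tuple(config.spawn["annulus_um"]),
            min_separation=config.spawn["min_separation_um"],
        )
        if config.track_from_images:
            trackset, _gt = _tracks_from_images(config, sim_tracks, render_ss)
        else:
            trackset = _tracks_from_simulation(config, sim_tracks)
        trackset = exclude_tracks(
            trackset, config.tracking.get("exclude_track_ids", [])
        )
        log.append(f"experiment {e}: {len(trackset)} tracks after filtering")
        m = track_metrics(trackset, tip, config.metrics["efficiency_mode"])
        bins = radial_bin(trackset, tip, edges)
        df = m.merge(bins[["cell_id", "bin"]], on="cell_id")
        df["experiment"] = e
        all_cells.append(df)
        for tr, b in zip(trackset, bins["bin"]):
            tracks_by_bin.setdefault(b, []).append(tr)
        last_tracks = list(trackset.tracks)

        # matched Ca2+ traces at each simulated cell's starting radius
        model = config.calcium_model()
        cac = config.calcium
        cell_seeds = ca_ss.spawn(len(sim_tracks))
        sim_bins = radial_bin(sim_tracks, tip, edges)
        for tr, (_, brow), cs in zip(
            sim_tracks, sim_bins.iterrows(), cell_seeds
        ):
            r0 = brow["r0_um"]
            trace = simulate_calcium(
                model, preset, r0, cac["duration_s"], cac["dt_s"], cs
            )
            norm = ca.normalize(trace)
            window = norm.default_window()
            amp = ca.amplitude(norm, window)
            integ = ca.integral(norm, window)
            try:
                rt = ca.rise_time(norm, window)
            except ValueError:
                rt = np.nan
            all_ca.append(
                {
                    "cell_id": tr.cell_id,
                    "experiment": e,
                    "r0_um": r0,
                    "bin": brow["bin"],
                    "amplitude": amp,
                    "integral_s": integ,
                    "rise_time_s": rt,
                }
            )
            if ca_times is None:
                ca_times = norm.times
            ca_trace_sums[brow["bin"]] = (
                ca_trace_sums.get(brow["bin"], 0.0) + norm.values
            )
            ca_trace_counts[brow["bin"]] = ca_trace_counts.get(brow["bin"], 0) + 1

    per_cell = pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    analyzed = per_cell[per_cell["excluded"] == ""] if not per_cell.empty else per_cell
    summary = (
        aggregate_by_experiment(
            analyzed,
            value_cols=["efficiency", "speed_um_min", "line_speed_um_min",
                        "straightness", "path_length_um", "net_displacement_um"],
        )
        if not analyzed.empty
        else pd.DataFrame()
    )
    msd_rows = []
    for b, trs in sorted(tracks_by_bin.items()):
        if len(trs) < 5:  # too few cells for an ensemble curve
            continue
        curve = msd(trs)
        if not curve.empty:
            curve.insert(0, "bin", b)
            msd_rows.append(curve)
    msd_by_bin = (
        pd.concat(msd_rows, ignore_index=True)
        if msd_rows
        else pd.DataFrame(columns=["bin", "lag_s", "msd_um2", "sem", "n"])
    )
    ca_df = pd.DataFrame(all_ca)
    ca_summary = (
        aggregate_by_experiment(
            ca_df, value_cols=["amplitude", "integral_s", "rise_time_s"]
        )
        if not ca_df.empty
        else pd.DataFrame()
    )
    tc_rows = []
    for b in sorted(ca_trace_sums):
        mean_trace = ca_trace_sums[b] / ca_trace_counts[b]
        tc_rows.append(
            pd.DataFrame(
                {"t_s": ca_times, "bin": b, "mean_drr": mean_trace,
                 "n": ca_trace_counts[b]}
            )
        )
    timecourses = (
        pd.concat(tc_rows, ignore_index=True)
        if tc_rows
        else pd.DataFrame(columns=["t_s", "bin", "mean_drr", "n"])
    )
    return ScenarioReport(
        config=config,
        per_cell=per_cell,
        summary=summary,
        msd_by_bin=msd_by_bin,
        calcium_per_cell=ca_df,
        calcium_summary=ca_summary,
        calcium_timecourses=timecourses,
        tracks=last_tracks,
        log=log,
    )


def compare_conditions(
    report_a: ScenarioReport,
    report_b: ScenarioReport,
    metrics: tuple[str, ...] = ("efficiency", "speed_um_min",
                                "line_speed_um_min", "straightness"),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin differences (b - a) of experiment-level means, with
    seeded bootstrap confidence intervals.

    Experiments are the resampling unit; when a report holds a single
    experiment, cells are resampled instead.  No p-values are emitted.
    Returns columns (bin, metric, delta, ci_low, ci_high).
    """
    ea = tuple(report_a.config.metrics["bin_edges_um"])
    eb = tuple(report_b.config.metrics["bin_edges_um"])
    if ea != eb:
        raise ValueError("reports use different bin edges")
    rng = np.random.default_rng(as_seed_sequence(seed))

    def _unit_means(report: ScenarioReport, b: str, metric: str) -> np.ndarray:
        df = report.per_cell
        df = df[(df["bin"] == b) & (df["excluded"] == "")]
        if report.config.n_experiments > 1:
            return df.groupby("experiment")[metric].mean().to_numpy()
        return df[metric].to_numpy()

    bins = sorted(
        set(report_a.per_cell["bin"]) & set(report_b.per_cell["bin"])
        - {"out_of_range"}
    )
    rows = []
    for b in bins:
        for metric in metrics:
            ua = _unit_means(report_a, b, metric)
            ub = _unit_means(report_b, b, metric)
            if ua.size == 0 or ub.size == 0:
                continue
            delta = float(ub.mean() - ua.mean())
            boots = np.empty(n_boot)
            for i in range(n_boot):
                ra = ua[rng.integers(0, ua.size, ua.size)]
                rb = ub[rng.integers(0, ub.size, ub.size)]
                boots[i] = rb.mean() - ra.mean()
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {"bin": b, "metric": metric, "delta": delta,
                 "ci_low": float(lo), "ci_high": float(hi)}
            )
    return pd.DataFrame(rows)
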