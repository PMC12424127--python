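"""Ratiometric and single-dye Ca2+ metrics.

Cells express the ratiometric sensor Salsa6f (Ca2+-sensitive GCaMP6f fused
to Ca2+-insensitive TdTomato); the ratio R = G/T cancels motion and
expression artifacts.  Single-dye recordings (Cal-590) use F instead of R.
Traces are normalized to the pre-stimulus baseline, dR/R0 = (R - R0)/R0,
and summarized as:

* amplitude — maximum dR/R0 in the analysis window (proxy of maximum
  cation load); the window defaults to the first 100 s after the
  chemoattractant challenge to avoid confounds from cell movement.
* integral — trapezoidal area of dR/R0 over the window (overall load).
* rise time — 10% -> 90% of peak on the rising phase, interpolated.
* SOCE rate — dF/dt (1/s) over the 10 s after extracellular Ca2+
  re-addition, estimated as a least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RatioTrace",
    "NormalizedTrace",
    "compute_ratio",
    "normalize",
    "amplitude",
    "integral",
    "rise_time",
    "soce_rate",
    "ANALYSIS_WINDOW_S",
    "SOCE_WINDOW_S",
]

#: Ca2+ analysis restricted to the first 100 s after the challenge
ANALYSIS_WINDOW_S = 100.0
#: SOCE rate measured over 10 s after Ca2+ re-addition
SOCE_WINDOW_S = 10.0


@dataclass
class RatioTrace:
    """Paired two-channel (or single-dye) fluorescence time series."""

    times: np.ndarray  # s, strictly increasing
    numerator: np.ndarray  # G (GCaMP6f-like), or F in single-dye mode
    denominator: np.ndarray | None = None  # T (TdTomato-like); None = single dye
    stimulus_onset: float = 0.0
    r0_um: float | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.numerator = np.asarray(self.numerator, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.numerator.shape != self.times.shape:
            raise ValueError("numerator length must match times")
        if self.denominator is not None:
            self.denominator = np.asarray(self.denominator, dtype=float)
            if self.denominator.shape != self.times.shape:
                raise ValueError("denominator length must match times")

    def ratio(self) -> np.ndarray:
        if self.denominator is None:
            return self.numerator
        return compute_ratio(self.numerator, self.denominator)


@dataclass
class NormalizedTrace:
    """dR/R0 (or dF/F0) trace with the baseline used to normalize it."""

    times: np.ndarray
    values: np.ndarray  # dimensionless
    baseline: float  # R0 (or F0)
    stimulus_onset: float = 0.0
    r0_um: float | None = None
    condition: str | None = None

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if not hi > lo:
            raise ValueError("window must be a non-empty interval")
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError("window contains no samples")
        return mask

    def default_window(self, length: float = ANALYSIS_WINDOW_S) -> tuple[float, float]:
        return (self.stimulus_onset, self.stimulus_onset + length)

    def noise_sd(self) -> float:
        """Baseline noise s.d. from pre-onset residuals."""
        pre = self.values[self.times < self.stimulus_onset]
        if pre.size < 3:
            raise ValueError("need >= 3 pre-onset samples to estimate noise")
        return float(np.std(pre - pre.mean(), ddof=1))


def compute_ratio(numerator: np.ndarray, denominator: np.ndarray) -> np.ndarray:
    """Pointwise G/T ratio; any non-positive denominator is an error."""
    g = np.asarray(numerator, dtype=float)
    t = np.asarray(denominator, dtype=float)
    if g.shape != t.shape:
        raise ValueError("channels must have the same length")
    bad = np.flatnonzero(t <= 0)
    if bad.size:
        raise ValueError(
            f"denominator <= 0 at frame {bad[0]} "
            "(background over-subtraction?)"
        )
    return g / t


def normalize(
    trace: RatioTrace,
    baseline_window: tuple[float, float] | None = None,
) -> NormalizedTrace:
    """(R - R0)/R0 with R0 the mean ratio before the stimulus.

    The baseline window defaults to everything before ``stimulus_onset``;
    at least 3 baseline samples are required.
    """
    r = trace.ratio()
    onset = trace.stimulus_onset
    if baseline_window is None:
        baseline_window = (trace.times[0], onset)
    lo, hi = baseline_window
    mask = (trace.times >= lo) & (trace.times < hi)
    if mask.sum() < 3:
        raise ValueError("need >= 3 baseline samples before stimulus onset")
    r0 = float(r[mask].mean())
    if r0 <= 0:
        raise ValueError("baseline R0 must be > 0")
    return NormalizedTrace(
        times=trace.times,
        values=(r - r0) / r0,
        baseline=r0,
        stimulus_onset=onset,
        r0_um=trace.r0_um,
        condition=trace.condition,
    )


def amplitude(
    trace: NormalizedTrace, window: tuple[float, float] | None = None
) -> float:
    """Maximum dR/R0 within the analysis window."""
    if window is None:
        window = trace.default_window()
    mask = trace.window_slice(window)
    return float(trace.values[mask].max())


def integral(
    trace: NormalizedTrace, window: tuple[float, float] | None = None
) -> float:
    """Signed trapezoidal area of dR/R0 over the window (units: s).

    Values at the exact window edges are obtained by linear interpolation
    so the area does not depend on where samples fall relative to the
    window boundaries.
    """
    if window is None:
        window = trace.default_window()
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must be a non-empty interval")
    lo = max(lo, float(trace.times[0]))
    hi = min(hi, float(trace.times[-1]))
    if not hi > lo:
        raise ValueError("window does not overlap the trace")
    inside = (trace.times > lo) & (trace.times < hi)
    t = np.concatenate(([lo], trace.times[inside], [hi]))
    v = np.interp(t, trace.times, trace.values)
    return float(np.trapezoid(v, t))


def rise_time(
    trace: NormalizedTrace,
    window: tuple[float, float] | None = None,
    detection_snr: float = 5.0,
    lo_frac: float = 0.1,
    hi_frac: float = 0.9,
) -> float:
    """10%-to-90% rise time of the peak, in seconds.

    Crossing times are the first upward crossings of each level on the
    rising phase, linearly interpolated between samples.  If the peak does
    not exceed ``detection_snr`` times the baseline noise s.d. the rise
    time is undefined and a ValueError (reason-coded) is raised.
    """
    if window is None:
        window = trace.default_window()
    mask = trace.window_slice(window)
    t = trace.times[mask]
    v = trace.values[mask]
    ipeak = int(np.argmax(v))
    peak = v[ipeak]
    noise = trace.noise_sd()
    if noise > 0 and peak < detection_snr * noise:
        raise ValueError("sub-threshold: peak below detection threshold")
    if peak <= 0:
        raise ValueError("sub-threshold: non-positive peak")

    def first_crossing(level: float) -> float:
        rising_t = t[: ipeak + 1]
        rising_v = v[: ipeak + 1]
        above = np.flatnonzero(rising_v >= level)
        if above.size == 0:
            return float(rising_t[-1])
        i = above[0]
        if i == 0:
            return float(rising_t[0])
        # linear interpolation between samples i-1 and i
        f = (level - rising_v[i - 1]) / (rising_v[i] - rising_v[i - 1])
        return float(rising_t[i - 1] + f * (rising_t[i] - rising_t[i - 1]))

    return first_crossing(hi_frac * peak) - first_crossing(lo_frac * peak)


def soce_rate(
    trace: NormalizedTrace,
    readdition_time: float,
    window_s: float = SOCE_WINDOW_S,
    mode: str = "regression",
) -> float:
    """SOCE rate dF/dt (1/s) over ``window_s`` after Ca2+ re-addition.

    ``mode='regression'`` (default) fits a least-squares slope to all
    samples in the window — robust to noise; ``mode='endpoints'`` uses
    (F_end - F_start)/window_s.
    """
    mask = (trace.times >= readdition_time) & (
        trace.times <= readdition_time + window_s
    )
    if mask.sum() < 3:
        raise ValueError("need >= 3 samples in the re-addition window")
    t = trace.times[mask]
    v = trace.values[mask]
    if mode == "regression":
        return float(stats.linregress(t, v).slope)
    if mode == "endpoints":
        return float((v[-1] - v[0]) / (t[-1] - t[0]))
    raise ValueError(f"unknown mode {mode!r}")
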