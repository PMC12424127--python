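"""Synthetic two-channel Ca2+ traces with ground-truth kinetics.

The ADP-evoked cytosolic Ca2+ response of microglia is biphasic: an early
sharp peak from IP3-mediated ER store release, followed by a sustained
plateau supported by store-operated Ca2+ entry (SOCE).  Both phases shrink
with distance from the pipette tip because less agonist reaches the cell;
this is modelled as an exponential decay of amplitude with the cell's
initial radial distance r0.

The clean dR/R0 signal is

    x(t) = A_peak * exp(-r0 / lambda) * h(t - onset - delay) / h_max
         + A_plat * exp(-r0 / lambda) * (1 - exp(-(t - onset - delay - d_p)/tau_p))

where d_p is a fixed plateau onset delay (SOCE engages only after the
stores have emptied, so the early peak is uncontaminated by influx),

with h(s) = exp(-s/tau_decay) - exp(-s/tau_rise) for s > 0 (0 otherwise),
normalized by its maximum h_max so A_peak is the true peak amplitude of
the first phase.  Treatment presets scale the two phases and delay the
onset.  The trace is emitted as two channels — denominator (TdTomato-like)
constant plus noise, numerator = R * denominator — so the downstream
ratio pipeline is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calcium import RatioTrace
from .presets import TreatmentPreset
from .seeding import as_seed_sequence

__all__ = [
    "CalciumModel",
    "biphasic_response",
    "double_exponential_peak_time",
    "simulate_calcium",
    "simulate_soce_trace",
]


@dataclass(frozen=True)
class CalciumModel:
    """Parameters of the synthetic biphasic Ca2+ response.

    Amplitudes are in dR/R0 units at r = 0 and decay as exp(-r/lambda)
    with ``peak_decay_length``; time constants in seconds.
    """

    baseline_r0: float = 1.0  # resting G/T ratio
    peak_amp_at_0: float = 1.5
    peak_decay_length: float = 250.0  # um
    peak_rise_tau: float = 3.0
    peak_decay_tau: float = 20.0
    plateau_amp_at_0: float = 0.4
    plateau_rise_tau: float = 25.0
    plateau_delay_s: float = 15.0  # SOCE develops after store depletion
    noise_sd: float = 0.02  # on dR/R0 scale
    stimulus_onset: float = 30.0

    def __post_init__(self) -> None:
        if self.baseline_r0 <= 0:
            raise ValueError("baseline_r0 must be > 0")
        if self.peak_rise_tau <= 0 or self.peak_decay_tau <= 0:
            raise ValueError("time constants must be > 0")
        if self.peak_rise_tau >= self.peak_decay_tau:
            raise ValueError("peak_rise_tau must be < peak_decay_tau")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def double_exponential_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the maximum of exp(-t/decay) - exp(-t/rise) after onset."""
    return rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def biphasic_response(
    t: np.ndarray,
    model: CalciumModel,
    preset: TreatmentPreset,
    r: float,
) -> np.ndarray:
    """Clean (noise-free) dR/R0 at times ``t`` for a cell at radius ``r``."""
    s = np.asarray(t, dtype=float) - model.stimulus_onset - preset.peak_delay_s
    s = np.where(s > 0, s, 0.0)
    decay = np.exp(-r / model.peak_decay_length)
    tstar = double_exponential_peak_time(model.peak_rise_tau, model.peak_decay_tau)
    h_max = np.exp(-tstar / model.peak_decay_tau) - np.exp(-tstar / model.peak_rise_tau)
    h = np.exp(-s / model.peak_decay_tau) - np.exp(-s / model.peak_rise_tau)
    peak = model.peak_amp_at_0 * preset.er_peak_scale * decay * h / h_max
    s_p = np.clip(s - model.plateau_delay_s, 0.0, None)
    plateau = (
        model.plateau_amp_at_0
        * preset.soce_plateau_scale
        * decay
        * (1.0 - np.exp(-s_p / model.plateau_rise_tau))
    )
    return np.where(s > 0, peak + plateau, 0.0)


def simulate_calcium(
    model: CalciumModel,
    preset: TreatmentPreset,
    r: float,
    duration: float,
    dt: float,
    seed: int,
    denominator_level: float = 1000.0,
    denominator_noise_cv: float = 0.0,
) -> RatioTrace:
    """Two-channel synthetic trace for one cell at radius ``r`` (um).

    Gaussian noise of s.d. ``model.noise_sd`` (dR/R0 units) is added to
    the ratio; the denominator channel is a constant level with optional
    multiplicative Gaussian noise, and the numerator is ratio times
    denominator, so dividing the channels recovers the noisy ratio.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration <= model.stimulus_onset:
        raise ValueError("duration must exceed stimulus_onset")
    rng = np.random.default_rng(as_seed_sequence(seed))
    t = np.arange(0.0, duration + dt / 2, dt)
    x = biphasic_response(t, model, preset, r)
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=t.size)
    ratio = model.baseline_r0 * (1.0 + x)
    denom = np.full(t.size, denominator_level)
    if denominator_noise_cv > 0:
        denom = denom * (1.0 + rng.normal(0.0, denominator_noise_cv, size=t.size))
    return RatioTrace(
        times=t,
        numerator=ratio * denom,
        denominator=denom,
        stimulus_onset=model.stimulus_onset,
        r0_um=r,
        condition=preset.name,
    )


def simulate_soce_trace(
    model: CalciumModel,
    preset: TreatmentPreset,
    duration: float,
    dt: float,
    seed: int,
    readdition_time: float = 150.0,
    depletion_amp: float = 0.3,
    soce_amp: float = 0.5,
    soce_tau: float = 20.0,
) -> RatioTrace:
    """Single-dye trace of the store-depletion / Ca2+ re-addition protocol.

    In Ca2+-free medium, SERCA block releases ER Ca2+ as a small transient
    (``depletion_amp``, store release — preserved in ORAI1-KO cells);
    re-adding extracellular Ca2+ at ``readdition_time`` drives influx that
    saturates with amplitude ``soce_amp`` and time constant ``soce_tau``
    (initial slope soce_amp/soce_tau, 1/s).  SOCE is scaled by the
    preset's ``soce_plateau_scale`` — zero in the ORAI1-KO preset.
    Returned in single-dye mode (no denominator channel).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration <= readdition_time:
        raise ValueError("duration must exceed readdition_time")
    rng = np.random.default_rng(as_seed_sequence(seed))
    t = np.arange(0.0, duration + dt / 2, dt)
    s_dep = np.clip(t - model.stimulus_onset, 0.0, None)
    tstar = double_exponential_peak_time(model.peak_rise_tau, model.peak_decay_tau)
    h_max = np.exp(-tstar / model.peak_decay_tau) - np.exp(-tstar / model.peak_rise_tau)
    release = (
        depletion_amp
        * preset.er_peak_scale
        * (np.exp(-s_dep / model.peak_decay_tau) - np.exp(-s_dep / model.peak_rise_tau))
        / h_max
    )
    release = np.where(t > model.stimulus_onset, release, 0.0)
    s_re = np.clip(t - readdition_time, 0.0, None)
    influx = (
        soce_amp
        * preset.soce_plateau_scale
        * (1.0 - np.exp(-s_re / soce_tau))
    )
    influx = np.where(t > readdition_time, influx, 0.0)
    x = release + influx
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=t.size)
    f = model.baseline_r0 * (1.0 + x)
    return RatioTrace(
        times=t,
        numerator=f,
        denominator=None,
        stimulus_onset=model.stimulus_onset,
        condition=preset.name,
    )
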