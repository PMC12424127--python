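# Methods

This note documents the models behind `chemokin`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical decisions a user should know before trusting an output.

## Gradient field

The pipette tip sits just above the coverslip and ejects 20 ms puffs at
0.5 Hz. Each puff is far shorter than any analysis timestep, so it is
modelled as an instantaneous release of an amount Q from a point source
in a half-space with a reflecting boundary (the coverslip): the field is
the sum of reflected free-space Green's functions over completed pulses.
A 3-D half-space geometry was chosen over a pure 2-D model because a
continuous 2-D point source has no steady state, whereas the assay's
monitored gradient is stable for tens of minutes; the half-space sum
converges to C(r) = Q·f/(2πDr) (f = pulse rate), the observed stable
profile.

Parameters: D defaults to 300 µm²/s (small-nucleotide order of
magnitude); Q is a free scale because neither the ejected volume nor the
dye diffusivity is measured — all downstream uses are normalized or
threshold-relative, and concentrations are reported in arbitrary units.
Convection from the puff itself is ignored.

Two numerical facts matter. First, at a fixed radius the pulse sum
matches the *continuous-release* closed form C_ss(r)·erfc(r/√(4Dt)) to
better than 0.2 % once ≳100 pulses have elapsed; the residual difference
from C_ss itself is the physical diffusion transient, which decays as
erfc and needs t ≳ 800 r²/D to fall below 2 %. Tests therefore check the
discreteness error against the erfc-corrected form at moderate times and
the approach to C_ss at long times (≥10⁴ pulses). Second, the dye-style
normalization (time-averaged intensity within 50 µm of the tip, 20–30 min
after release) is implemented as an area-weighted disk average; for the
1/r steady profile that reference equals the field value at 25 µm, so the
normalized profile is ~25/r at large r.

## Motility model

Cells execute a biased persistent random walk with timestep dt = 15 s
(the analysis cadence). At each step the heading is drawn from a von
Mises distribution centred on the drift vector

b = p·û_prev + κ·g(r)·û_tip,   g(r) = max(0, 1 − r/R_s),

with concentration 2|b| (the factor 2 makes the directional correlation
≈ p for small p). The clipped-linear gain g encodes the observation that
directed migration is robust up to ~400 µm from the tip (R_s = 400 µm
default) and indistinguishable from a random walk beyond. Attraction
depends on radial distance as a proxy for local concentration rather than
on sampling the field itself — simpler, and sufficient to reproduce the
distance dependence of efficiency. Step lengths are gamma distributed
(positive support; the CV sets burstiness).

Defaults (the packaged iMG preset): mean step speed 5.0 µm/min, CV 0.45,
persistence 0.3, κ = 1.2, dt = 15 s. Mean speed and CV were calibrated
once so that the *full* pipeline — render, track, filter, measure —
reports the system-level mean speed (~5 µm/min) and burst speed
(~10 µm/min, mean of per-track maximum frame-to-frame speeds); the CV is
what places the burst/mean ratio at ~2 for 40-step tracks. κ = 0 yields
an unbiased walk (mean efficiency 0, MSD slope 4·D_eff with
D_eff = E[step²]/(4 dt)); large κ is ballistic (efficiency and
straightness → 1).

Cells spawn uniformly by area in a 100–400 µm annulus around the tip,
which keeps the default population inside the 845 µm field while spanning
the analysis bins. An optional minimum-separation (dart-throwing) spawn
emulates well-separated plating for tracking-accuracy studies; it couples
the spawn draws, so it uses its own substream while per-cell walk
substreams remain independent of n_cells.

## Treatment presets

Each experimental condition is a set of dimensionless scalings:
gradient-coupling multiplier (on κ), speed multiplier, ER-peak and
SOCE-plateau scales, and a peak-onset delay. The magnitudes encode the
*direction* of each reported effect (abolished / reduced / unchanged),
not fitted effect sizes — the source experiments report outcomes only as
figures, so presets must not be read as quantitative claims. Notable
choices: the caffeine-family presets set the coupling multiplier to 0
(directed migration "almost completely" lost is encoded as full loss of
gradient coupling, with the residual effects carried by speed and Ca²⁺
scalings); SERCA-block presets zero both Ca²⁺ phases because the ER is
pre-depleted, although the SOCE machinery itself is intact — they are
therefore never combined with the store-depletion/re-addition protocol.

## Ca²⁺ traces

The clean ΔR/R₀ signal is a normalized double exponential (rise 3 s,
decay 20 s) for the ER-release peak plus a saturating exponential plateau
(τ = 25 s) for SOCE, both scaled by exp(−r₀/250 µm) to encode the
distance dependence of agonist exposure. The plateau starts 15 s after
the peak onset: SOCE engages only after store depletion, which keeps the
early peak uncontaminated by influx — this is what makes the Ca²⁺-free
contract ("peak preserved, plateau lost") exact rather than approximate.
Traces are emitted as two channels (denominator constant + optional
noise, numerator = ratio × denominator) so the ratio pipeline is
exercised end to end; Gaussian noise (σ = 0.02 ΔR/R₀ by default) is added
on the ratio scale. The store-depletion/re-addition protocol produces
single-dye traces: a depletion transient plus, after re-addition, influx
saturating with amplitude 0.5 and τ = 20 s (initial slope 0.025 s⁻¹),
scaled by the preset's SOCE factor.

Metric conventions: amplitude and integral are restricted to the first
100 s after the challenge by default (the assay's guard against ROI
drift on moving cells). Rise time is 10 %→90 % of peak with linear
interpolation, undefined (reason-coded error) below 5× the baseline
noise s.d. The SOCE rate is a least-squares slope over the 10 s window —
more noise-robust than the endpoint difference, which remains available
as `mode="endpoints"`.

## Rendering and tracking

Cells are drawn as isotropic Gaussian blobs (σ = 3 px ≈ 4 µm) on a
constant background with Poisson shot noise, on the assay geometry
(650 × 650 binned px, 1.3 µm/px, 845 µm field). This emulates somata of
dye-loaded cells at 10×; it does not emulate ramified processes, shape
changes, uneven illumination, photobleaching, or focus drift — tracking
accuracies measured here are upper bounds for real data, which the assay
addressed with manual curation (modelled as an explicit, logged
exclusion list whose default is empty).

The chain: trim to [release+60 s, release+660 s]; downsample with the
smallest stride giving ≥15 s; per-frame scalar background as the 5th
percentile (deterministic, unlike rolling-ball); Otsu global threshold,
8-connected components, area ≥ 9 px², intensity-weighted centroids;
greedy globally-nearest-neighbour linking with deterministic tie-breaks
(ascending distance, then detection (y, x), then track (y, x)), no gap
closing — "≥ 20 *consecutive* acquisitions" implies gaps end tracks —
and max displacement 3× the expected step (3.75 µm at defaults). Greedy
rather than optimal assignment is adequate at the assay's plating
density; on a well-separated 50-cell scenario the chain recovers ≥99 %
of ground-truth positions with RMSE < 0.1 px. Dual-population assays
label each track by the channel with the higher track-median intensity
(ratio ≥ 1.2, else "unassigned").

## Migration metrics

"Distance traveled towards the center" is interpreted as the *net*
radial approach r_first − r_last, so efficiency is bounded in [−1, 1]
and the identity efficiency × speed = line-speed-to-tip holds exactly;
the positive-steps alternative is available as
`efficiency_mode="positive_steps"`. Straightness is the net-displacement
ratio (a turning-angle statistic would also fit the name; the
displacement ratio is adopted and documented). MSD uses displacements
from each track's origin without sliding-window time averaging, matching
"distance traveled from their origin"; the time-averaged variant is
behind a flag. Bin membership is frozen at the first analyzed frame
(half-open 100 µm bins, 100–500 µm defaults; out-of-range tracks are
reported separately, never dropped silently). Experiment-level summaries
average per-experiment bin means and report n = experiments, so
cell-count imbalance cannot weight a condition.

The diffusive MSD slope is estimated by weighted least squares through
the origin over the first 10 lags (weights 1/sem²) — the zero intercept
is exact for the model, and from-origin MSD values at different lags are
strongly correlated within cells, which an unweighted full-range fit
handles poorly.

## Scenario runs and problem sizes

A scenario (one condition) is reproducible bit for bit from its config
and a single seed, which fans out into named substreams per experiment
and stage (simulation, shot noise, Ca²⁺ noise, bootstrap). Default
scenario sizes — 200 cells for the imaging-route speed measurements,
500-cell ensembles for preset contracts, 1000 walks for null-model
checks, 4 experiments × 120 cells for condition comparisons — were
chosen so Monte-Carlo error sits well below the effects being asserted
while a full run stays in the seconds-to-minutes range on one core.
Condition comparisons bootstrap experiment-level means (1000 resamples,
seeded; cells are resampled only when a report holds a single
experiment) and emit deltas with CIs, never p-values.

## Known limitations

- The gradient is a shape model: absolute concentrations are arbitrary
  units, and fitting D or Q to dye movies is out of scope.
- Bias depends on radial distance, not sampled concentration, so the
  model cannot represent temporal gradient sensing or adaptation.
- No cell–cell interactions: collisions, contact inhibition and the
  track-merging artifacts they cause in dense fields are absent.
- Ca²⁺ kinetics are phenomenological (no IP₃/SOCE mechanism), adequate
  for metric validation and sign-of-effect contracts only.
- Preset magnitudes are qualitative; passing contract tests shows the
  pipeline preserves each condition's direction of effect, not that the
  generator reproduces real effect sizes.
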