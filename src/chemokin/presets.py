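"""Treatment presets: per-condition scalings of motility and Ca2+ models.

Each preset encodes, qualitatively, how one experimental condition alters
(i) the coupling of cell motion to the ADP gradient (``kappa_multiplier``),
(ii) baseline motility (``speed_multiplier``), and (iii) the two phases of
the ADP-evoked Ca2+ response: the early ER-release peak (``er_peak_scale``)
and the sustained store-operated (SOCE) plateau (``soce_plateau_scale``),
plus a delay of the peak onset (``peak_delay_s``, used for slow-onset
responses under cytosolic Ca2+ buffering).

Magnitudes are qualitative sign-of-effect encodings, not fitted effect
sizes: the source experiments report their per-condition outcomes only as
figures, so presets assert direction (abolished / reduced / unchanged),
never quantitative claims.

Condition summary (directed migration; Ca2+ peak; SOCE/plateau):

====================  ==================  ==========  ================
preset                migration           ER peak     SOCE plateau
====================  ==================  ==========  ================
control               intact              intact      intact
sham                  none (no ADP)       shear blip  none
antagonists           abolished           abolished   abolished
atpgs                 mildly reduced      reduced     mostly lost
ca_free               mildly reduced      intact      abolished
ca_10mM               intact              intact      intact
bapta_20              intact              delayed/–   reduced
bapta_5               intact              delayed/–   mildly reduced
egta                  intact (speed –)    reduced     intact
orai1_ko              intact              intact      abolished
thapsigargin          intact              abolished   abolished*
cpa                   intact              abolished   abolished*
caffeine              abolished           reduced     reduced
thapsigargin_caffeine abolished           abolished   abolished
forskolin             depressed           reduced     reduced
====================  ==================  ==========  ================

(*) SERCA block empties the ER before the ADP challenge, so the
ADP-evoked transient — both phases — is absent; the SOCE machinery
itself is untouched, but these presets are never combined with the
store-depletion/re-addition protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TreatmentPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class TreatmentPreset:
    name: str
    kappa_multiplier: float = 1.0
    speed_multiplier: float = 1.0
    er_peak_scale: float = 1.0
    soce_plateau_scale: float = 1.0
    peak_delay_s: float = 0.0

    def __post_init__(self) -> None:
        for f in ("kappa_multiplier", "speed_multiplier", "er_peak_scale",
                  "soce_plateau_scale"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.peak_delay_s < 0:
            raise ValueError("peak_delay_s must be >= 0")


PRESETS: dict[str, TreatmentPreset] = {
    p.name: p
    for p in [
        # vehicle-treated cells, ADP gradient, 2 mM external Ca2+
        TreatmentPreset("control"),
        # pipette puffs without ADP: no gradient coupling; a small
        # shear-stress Ca2+ blip remains
        TreatmentPreset("sham", kappa_multiplier=0.0,
                        er_peak_scale=0.15, soce_plateau_scale=0.0),
        # P2Y12 + P2Y13 antagonists (PSB 0739 + MRS 2211): directed
        # migration and Ca2+ rises abolished; baseline speed reduced
        TreatmentPreset("antagonists", kappa_multiplier=0.0,
                        speed_multiplier=0.75,
                        er_peak_scale=0.0, soce_plateau_scale=0.0),
        # ATPgS gradient (P2X4/P2X7 route): modest, non-significant drop
        # in efficiency; short-lasting Ca2+ elevations
        TreatmentPreset("atpgs", kappa_multiplier=0.85,
                        er_peak_scale=0.7, soce_plateau_scale=0.25),
        # Ca2+-free bath + EGTA 300 uM: peak preserved, plateau abolished;
        # modest efficiency reduction near the tip
        TreatmentPreset("ca_free", kappa_multiplier=0.8,
                        soce_plateau_scale=0.0),
        # 10 mM external Ca2+: indistinguishable from control
        TreatmentPreset("ca_10mM"),
        # BAPTA-AM 20 uM: migration intact; Ca2+ delayed and reduced
        TreatmentPreset("bapta_20", er_peak_scale=0.4,
                        soce_plateau_scale=0.6, peak_delay_s=10.0),
        # BAPTA-AM 5 uM: milder version of the above
        TreatmentPreset("bapta_5", er_peak_scale=0.6,
                        soce_plateau_scale=0.8, peak_delay_s=5.0),
        # EGTA-AM 20 uM: peak reduced, integral preserved; speed reduced
        TreatmentPreset("egta", speed_multiplier=0.8, er_peak_scale=0.5),
        # CRISPR ORAI1 knockout: SOCE abrogated, store release and
        # migration intact
        TreatmentPreset("orai1_ko", soce_plateau_scale=0.0),
        # SERCA inhibitors, ER pre-depleted: ADP-evoked Ca2+ abrogated,
        # migration intact
        TreatmentPreset("thapsigargin", er_peak_scale=0.0,
                        soce_plateau_scale=0.0),
        TreatmentPreset("cpa", er_peak_scale=0.0, soce_plateau_scale=0.0),
        # caffeine 10 mM: directed migration abrogated (cAMP route),
        # Ca2+ reduced, speed reduced
        TreatmentPreset("caffeine", kappa_multiplier=0.0,
                        speed_multiplier=0.7,
                        er_peak_scale=0.3, soce_plateau_scale=0.5),
        TreatmentPreset("thapsigargin_caffeine", kappa_multiplier=0.0,
                        speed_multiplier=0.7,
                        er_peak_scale=0.0, soce_plateau_scale=0.0),
        # forskolin 10 uM (adenylate-cyclase activation): migration and
        # Ca2+ depressed
        TreatmentPreset("forskolin", kappa_multiplier=0.3,
                        speed_multiplier=0.85,
                        er_peak_scale=0.5, soce_plateau_scale=0.5),
    ]
}


def get_preset(name: str) -> TreatmentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
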