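"""Assay channel definitions shared across the pipeline.

Nine channels: two reporter-gene platforms (ER-bla, a beta-lactamase
ligand-binding-domain one-hybrid readout in HEK293; ER-luc, a full-length
receptor luciferase readout in BG1) each run in agonist and antagonist mode,
one multiplexed viability channel per platform, and a three-wavelength
compound autofluorescence counter-screen matched to the fluorescent (bla)
detection channels.
"""

from __future__ import annotations

from dataclasses import dataclass

MODE_ASSAYS = ("bla_agonist", "bla_antagonist", "luc_agonist", "luc_antagonist")
VIABILITY_ASSAYS = ("bla_viability", "luc_viability")
AUTOFLUOR_ASSAYS = ("autofluor_blue", "autofluor_green", "autofluor_red")
MAIN_ASSAYS = MODE_ASSAYS + VIABILITY_ASSAYS
ALL_ASSAYS = MAIN_ASSAYS + AUTOFLUOR_ASSAYS

#: viability channel multiplexed with each antagonist-mode assay
VIABILITY_FOR = {"bla_antagonist": "bla_viability", "luc_antagonist": "luc_viability"}

#: autofluorescence channels that can contaminate each platform's readout;
#: the luc platform is luminescent and is not subject to autofluorescence.
AUTOFLUOR_CHANNELS_FOR = {"bla": ("blue", "green"), "luc": ()}


@dataclass(frozen=True)
class AssayParams:
    """Raw-signal parameters for one channel.

    kind: 'activation' (signal rises with effect: agonist mode, autofluor
    channels) or 'inhibition' (untreated/stimulated level is high and effect
    pulls the signal down: antagonist mode, viability).
    background: raw signal of the low state (assay background).
    s_b: signal-to-background ratio of the positive-control window.
    control_ac50 / control_hill: the embedded positive-control titration.
    """

    kind: str
    background: float
    s_b: float
    control_ac50: float
    control_hill: float = 1.2

    @property
    def top_signal(self) -> float:
        return self.background * self.s_b


# Raw-signal parameters chosen to emulate typical qHTS assay windows
# (S/B of a few fold for reporter channels, a very large window for the
# ATP-based viability channel) with the embedded-control potencies of
# 17-beta-estradiol (agonist mode), 4-hydroxytamoxifen (antagonist mode)
# and a cytotoxic ammonium surfactant (viability).
ASSAY_PARAMS: dict[str, AssayParams] = {
    "bla_agonist": AssayParams("activation", 100.0, 4.6, 3.14e-10),
    "bla_antagonist": AssayParams("inhibition", 100.0, 3.3, 5.01e-9),
    "bla_viability": AssayParams("inhibition", 100.0, 132.6, 1.0e-5),
    "luc_agonist": AssayParams("activation", 100.0, 2.5, 2.74e-11),
    "luc_antagonist": AssayParams("inhibition", 100.0, 8.0, 7.30e-8),
    "luc_viability": AssayParams("inhibition", 100.0, 6.1, 1.0e-5),
    "autofluor_blue": AssayParams("activation", 100.0, 5.0, 1.0e-6),
    "autofluor_green": AssayParams("activation", 100.0, 5.0, 1.0e-6),
    "autofluor_red": AssayParams("activation", 100.0, 5.0, 1.0e-6),
}


def platform_of(assay_id: str) -> str:
    """'bla', 'luc' or 'autofluor'."""
    return assay_id.split("_", 1)[0]


def mode_of(assay_id: str) -> str:
    """'agonist', 'antagonist', 'viability' or the autofluor wavelength."""
    return assay_id.split("_", 1)[1]
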