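"""Named simulation modes: control, HCM R403Q, and myosin-modulator overlays.

Each mode is an immutable :class:`~sarcomech.contractile.ModeOverlay` acting on
the control parameter set:

* ``control`` - identity overlay.
* ``hcm_r403q`` - hypertrophic-cardiomyopathy myosin mutation: elevated
  reference phosphate and MgADP, reduced forward isomerisation (ap2), and a
  raised DRX:SRX ratio (F1 = F2 = 1.3).
* ``mava_0p5uM`` - 0.5 uM Mavacamten applied on top of the HCM variant
  (myosin ATPase inhibitor): strongly reduced DRX:SRX (F1 = F2 = 0.1),
  redistributed cycle coefficients A-E, and metabolites restored to baseline.
* ``bleb_5uM`` - 5 uM Blebbistatin (ATPase inhibitor, desensitises the
  tension-Ca2+ relation).
* ``om_1uM`` - 1 uM Omecamtiv mecarbil (myosin activator, positive inotrope;
  also activates the thin filament through the Ca2+ binding constants).

A dash in the published modification tables means "leave at baseline"; such
entries are simply absent from the overlay.
"""

from __future__ import annotations

from dataclasses import asdict

from .contractile import ModeOverlay

__all__ = ["MODES", "load_overlay", "overlay_to_dict", "overlay_from_dict"]


MODES: dict[str, ModeOverlay] = {
    "control": ModeOverlay(name="control"),
    "hcm_r403q": ModeOverlay(
        name="hcm_r403q",
        ap2_coef=0.315,
        F1=1.3,
        F2=1.3,
        Pi_ref=18.9,      # mM
        MgADP=72e-3,      # mM
    ),
    # Mavacamten is defined on the HCM variant: the HCM ap2 reduction is
    # retained, F1/F2 are replaced, and Pi_ref/MgADP return to control values.
    "mava_0p5uM": ModeOverlay(
        name="mava_0p5uM",
        A=0.26,
        B=0.4,
        C=5.4,
        D=0.4,
        E=2.39,
        ap1_coef=1.45,
        ap2_coef=0.315,
        ap3_coef=0.28,
        F1=0.1,
        F2=0.1,
        scale=(("kon", 1.048), ("nperm", 0.688)),
        Pi_ref=2.0,
        MgADP=36e-3,
    ),
    "bleb_5uM": ModeOverlay(
        name="bleb_5uM",
        F1=5.015,
        F2=0.1,
        tropreg_coef=0.2,
        ap2_coef=0.012,
        ap3_coef=0.03,
        am2_coef=0.25,
        scale=(("perm50", 1.33),),
    ),
    "om_1uM": ModeOverlay(
        name="om_1uM",
        F1=4.1,
        F2=0.1,
        tropreg_coef=0.2,
        ap2_coef=0.02,
        ap3_coef=0.03,
        am2_coef=0.15,
        scale=(
            ("kon", 1.28),
            ("nperm", 1.182),
            ("perm50", 1.33),
            ("kpn", 0.2),
            ("knp", 1.182),
            ("koffmod", 0.52),
            ("koffL", 1.75),
            ("koffH", 0.6),
            ("hf", 2.0),
        ),
    ),
}


def load_overlay(mode_id: str) -> ModeOverlay:
    """Return the registered overlay for ``mode_id``.

    Raises ``KeyError`` listing the registered ids for unknown modes.
    """
    try:
        return MODES[mode_id]
    except KeyError:
        raise KeyError(
            f"unknown mode {mode_id!r}; registered modes: {sorted(MODES)}"
        ) from None


def overlay_to_dict(ov: ModeOverlay) -> dict:
    d = asdict(ov)
    d["scale"] = [list(pair) for pair in ov.scale]
    return d


def overlay_from_dict(d: dict) -> ModeOverlay:
    d = dict(d)
    d["scale"] = tuple((k, float(v)) for k, v in d.get("scale", ()))
    return ModeOverlay(**d)
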