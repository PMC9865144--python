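"""Rule-based qualitative affinity prediction for SH3 x PRM pairs.

The prediction is categorical, mirroring the mutational evidence the rules
encode: AGS-class SH3 domains bind Px+P motifs with HIGH affinity (Kd band
~0.3-10 uM), canonical SH3/class-II pairings are TYPICAL (~20-200 uM), and
charge-reversing substitutions at the key register positions abolish binding
(NONE).  Each prediction carries the rules that fired, in order:

  R1  acidic residue at register position 5            -> NONE
  R2  acidic residue at position 2, AGS partner        -> NONE
  R3  missing anchor proline (P0 or P3)                -> downgrade one level
  R4  AGS x Px+P                                       -> HIGH ("enhanced" if pos2 is R)
  R5  AGS x class-II (non-positive pos2)               -> TYPICAL
  R6  CANONICAL x (class-II or Px+P)                   -> TYPICAL
  R7  motif class NONE                                 -> NONE

R1/R2 are terminal and checked first; R4-R7 assign the base label; R3 then
downgrades it (HIGH->TYPICAL->NONE).  Class-I motifs, which bind the groove
in the reverse orientation, are assigned TYPICAL under either SH3 class and
annotated as untested by the underlying mutational data; likewise the
pos2-acidic x CANONICAL cell is left TYPICAL with an "untested" flag, since
only the AGS pairing was probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .motifs import ACIDIC, POSITIVE, PRMClass


class Affinity(str, Enum):
    HIGH = "HIGH"
    TYPICAL = "TYPICAL"
    NONE = "NONE"


#: Inclusive Kd bands in uM annotated per label (NONE is unbound).
KD_BANDS_UM: dict[Affinity, tuple[float, float] | None] = {
    Affinity.HIGH: (0.3, 10.0),
    Affinity.TYPICAL: (20.0, 200.0),
    Affinity.NONE: None,
}

_DOWNGRADE = {Affinity.HIGH: Affinity.TYPICAL, Affinity.TYPICAL: Affinity.NONE, Affinity.NONE: Affinity.NONE}


class MotifLike(Protocol):
    """Anything carrying the register facts the rules consume.

    Satisfied by :class:`~sh3prm.motifs.PRMMatch` and
    :class:`~sh3prm.motifs.WindowClassification` (variant mode included).
    """

    prm_class: PRMClass
    pos2_residue: str | None
    pos5_residue: str | None
    p0_present: bool
    p3_present: bool


@dataclass(frozen=True)
class PairPrediction:
    sh3_id: str
    prm_id: str
    sh3_class: str
    prm_class: PRMClass
    affinity: Affinity | None
    kd_band_um: tuple[float, float] | None
    enhanced: bool
    status: str                    # "ok" or "unclassifiable"
    rules_applied: tuple[str, ...]
    rationale: tuple[str, ...]


def predict_pair(sh3, prm: MotifLike, sh3_id: str | None = None, prm_id: str | None = None) -> PairPrediction:
    """Apply the rule table to one SH3 classification x motif descriptor.

    ``sh3`` is an :class:`~sh3prm.sh3.SH3Classification` (or anything with
    ``sh3_class`` and optionally ``domain_id``).  An UNKNOWN SH3 class yields
    an explicit unclassifiable result rather than a default label.
    """
    sh3_id = sh3_id or getattr(sh3, "domain_id", "sh3")
    prm_id = prm_id or getattr(prm, "protein_id", "prm")
    sh3_class = getattr(sh3, "sh3_class", sh3)

    if sh3_class == "UNKNOWN":
        return PairPrediction(
            sh3_id=sh3_id, prm_id=prm_id, sh3_class=sh3_class, prm_class=prm.prm_class,
            affinity=None, kd_band_um=None, enhanced=False, status="unclassifiable",
            rules_applied=(), rationale=("SH3 classification is UNKNOWN; no rule applies",),
        )

    rules: list[str] = []
    rationale: list[str] = []
    pos2 = prm.pos2_residue or ""
    pos5 = prm.pos5_residue or ""
    enhanced = False

    # Terminal charge-reversal rules.
    if pos5 not in POSITIVE and pos5 in ACIDIC:
        rules.append("R1")
        rationale.append(f"R1: acidic residue {pos5} at position 5 abolishes binding")
        label = Affinity.NONE
    elif pos2 in ACIDIC and sh3_class == "AGS":
        rules.append("R2")
        rationale.append(f"R2: acidic residue {pos2} at position 2 repelled by the AGS acidic pocket")
        label = Affinity.NONE
    else:
        # Base label from the class pairing.
        if prm.prm_class is PRMClass.PX_PLUS_P:
            if sh3_class == "AGS":
                rules.append("R4")
                label = Affinity.HIGH
                rationale.append("R4: AGS SH3 x Px+P motif binds with high affinity")
                if pos2 == "R":
                    enhanced = True
                    rationale.append("R4: arginine at position 2 mildly enhances the interaction")
            else:
                rules.append("R6")
                label = Affinity.TYPICAL
                rationale.append("R6: canonical SH3 x Px+P motif reverts to typical affinity")
        elif prm.prm_class is PRMClass.CLASS_II:
            rules.append("R5" if sh3_class == "AGS" else "R6")
            label = Affinity.TYPICAL
            rationale.append(
                ("R5: AGS SH3 x class-II motif (non-positive position 2) is typical"
                 if sh3_class == "AGS"
                 else "R6: canonical SH3 x class-II motif is typical")
            )
            if pos2 in ACIDIC:
                rationale.append("pos2-acidic x canonical SH3 pairing untested; label kept TYPICAL")
        elif prm.prm_class is PRMClass.CLASS_I:
            rules.append("R5" if sh3_class == "AGS" else "R6")
            label = Affinity.TYPICAL
            rationale.append("class-I (reverse-orientation) motif assigned TYPICAL; untested pairing")
        else:
            rules.append("R7")
            label = Affinity.NONE
            rationale.append("R7: no recognizable PRM class")

        # Anchor-proline downgrade.
        if not (prm.p0_present and prm.p3_present):
            missing = "P0" if not prm.p0_present else "P3"
            downgraded = _DOWNGRADE[label]
            rules.append("R3")
            rationale.append(
                f"R3: anchor proline {missing} substituted; {label.value} downgraded to {downgraded.value}"
            )
            label = downgraded

    return PairPrediction(
        sh3_id=sh3_id, prm_id=prm_id, sh3_class=sh3_class, prm_class=prm.prm_class,
        affinity=label, kd_band_um=KD_BANDS_UM[label], enhanced=enhanced,
        status="ok", rules_applied=tuple(rules), rationale=tuple(rationale),
    )


def predict_all_pairs(sh3_set: Sequence, prm_set: Sequence[MotifLike]) -> pd.DataFrame:
    """Full cross-product prediction matrix, one row per SH3 x PRM pair."""
    rows = []
    for sh3 in sh3_set:
        for prm in prm_set:
            p = predict_pair(sh3, prm)
            band = p.kd_band_um or (float("nan"), float("nan"))
            rows.append(
                {
                    "sh3_id": p.sh3_id,
                    "prm_id": p.prm_id,
                    "affinity": p.affinity.value if p.affinity else "",
                    "band_lo_uM": band[0],
                    "band_hi_uM": band[1],
                    "enhanced": p.enhanced,
                    "status": p.status,
                    "rules_applied": ",".join(p.rules_applied),
                }
            )
    cols = ["sh3_id", "prm_id", "affinity", "band_lo_uM", "band_hi_uM", "enhanced", "status", "rules_applied"]
    return pd.DataFrame(rows, columns=cols)
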