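"""Position-registered scanning and classification of proline-rich motifs (PRMs).

SH3 domains read their proline-rich ligands through a positional register in
which the two anchor prolines sit at positions 0 and 3:

    class-II      x(-1) P(0) x(1) x(2) P(3) x(4) +(5)        "xPxxPx+"
    Px+P          x(-1) P(0) x(1) +(2) P(3) x(4) +(5)        "xPx+Px+"
    class-I       +     x    x    P    x    x    P           "+xxPxxP"

``+`` is K or R (histidine is not counted as positive).  The Px+P motif is
the atypical class-II variant with a positive residue *inside* the PxxP core
at register position 2; it is the ligand signature of the SH3 domains of the
ASAP/GRAF/SKAP families (SH3-AGS), which grip that lysine/arginine with an
acidic RT-loop pocket.  Typical class-II motifs instead prefer a hydrophobic
residue at position 2, which is annotated but never used for match/no-match.

Registers are reported as mappings from register position to 1-based string
index; position -2 is included whenever a preceding residue exists.  Class-I
motifs carry no published subscripts, so as a convention of this package
their register is anchored on the two prolines (positions 0 and 3) and the
positive residue is reported at position -3.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sequences import ProteinSequence, as_protein_sequence

POSITIVE = frozenset("KR")
ACIDIC = frozenset("DE")
#: Hydrophobic set used only to annotate register position 2 of class-II motifs.
HYDROPHOBIC = frozenset("AVLIMFWP")

# Overlapping-window patterns via lookahead capture.
_RE_CLASS2 = re.compile(r"(?=(.P..P.[KR]))")
_RE_CLASS1 = re.compile(r"(?=([KR]..P..P))")
_RE_PXPLUSP = re.compile(r"(?=(.P.[KR]P.[KR]))")


class PRMClass(str, Enum):
    """Canonical PRM classes, ordered from most to least specific."""

    PX_PLUS_P = "PX_PLUS_P"
    CLASS_II = "CLASS_II"
    CLASS_I = "CLASS_I"
    NONE = "NONE"


@dataclass(frozen=True)
class PRMRegister:
    """Mapping from register positions to 1-based sequence indices.

    Anchor prolines sit at positions 0 and 3; ``p3_substituted`` marks the
    explicitly-flagged variant registers where the position-3 proline has
    been replaced (e.g. the APC-like P3->S motif).
    """

    positions: dict[int, int]
    p3_substituted: bool = False
    p0_substituted: bool = False

    def __post_init__(self) -> None:
        keys = sorted(self.positions)
        idx = [self.positions[k] for k in keys]
        if any(b - a != kb - ka for (a, b, ka, kb) in zip(idx, idx[1:], keys, keys[1:])):
            raise ValueError("register indices must be strictly increasing and consecutive")
        if 0 not in self.positions or 3 not in self.positions:
            raise ValueError("register must cover anchor positions 0 and 3")

    def validate_against(self, residues: str) -> None:
        """Check the anchor prolines against a sequence (1-based indices)."""
        if not self.p0_substituted and residues[self.positions[0] - 1] != "P":
            raise ValueError("register position 0 is not proline")
        if not self.p3_substituted and residues[self.positions[3] - 1] != "P":
            raise ValueError("register position 3 is not proline")

    def to_json(self) -> str:
        return json.dumps({str(k): v for k, v in sorted(self.positions.items())})


@dataclass(frozen=True)
class PRMMatch:
    """A motif hit with its register, class label and key residues."""

    protein_id: str
    start: int  # 1-based inclusive, core window
    end: int
    register: PRMRegister
    prm_class: PRMClass
    window: str
    pos2_residue: str
    pos5_residue: str
    pos2_hydrophobic: bool
    is_pxplusp: bool = False
    p0_present: bool = True
    p3_present: bool = True

    def biological_positions(self, seq: ProteinSequence) -> dict[int, int]:
        """Register mapped to biological residue numbers via the sequence offset."""
        return {k: seq.biological_number(v) for k, v in self.register.positions.items()}


@dataclass(frozen=True)
class WindowClassification:
    """Outcome of :func:`classify_window` on a single window."""

    prm_class: PRMClass
    pos2_residue: str | None
    pos5_residue: str | None
    pos2_hydrophobic: bool
    p0_present: bool
    p3_present: bool
    variant_label: str | None = None


def _class2_register(start0: int) -> dict[int, int]:
    """Register for a class-II/Px+P window starting at 0-based index ``start0``."""
    start1 = start0 + 1
    reg = {p: start1 + (p + 1) for p in range(-1, 6)}
    if start0 >= 1:
        reg[-2] = start0  # 1-based index of the preceding residue
    return reg


def _class1_register(start0: int) -> dict[int, int]:
    """Class-I convention: prolines anchored at 0 and 3, '+' reported at -3."""
    start1 = start0 + 1
    return {p: start1 + (p + 3) for p in range(-3, 4)}


def _make_match(seq: ProteinSequence, start0: int, cls: PRMClass) -> PRMMatch:
    window = seq.residues[start0 : start0 + 7]
    if cls is PRMClass.CLASS_I:
        register = PRMRegister(_class1_register(start0))
        pos2 = window[5]
        pos5 = ""  # class-I register ends at position 3; no position 5
    else:
        register = PRMRegister(_class2_register(start0))
        pos2 = window[3]
        pos5 = window[6]
    register.validate_against(seq.residues)
    return PRMMatch(
        protein_id=seq.id,
        start=start0 + 1,
        end=start0 + 7,
        register=register,
        prm_class=cls,
        window=window,
        pos2_residue=pos2,
        pos5_residue=pos5,
        pos2_hydrophobic=pos2 in HYDROPHOBIC,
        is_pxplusp=(cls is not PRMClass.CLASS_I and pos2 in POSITIVE),
    )


def _scan(seq: ProteinSequence | str, pattern: re.Pattern, cls: PRMClass) -> list[PRMMatch]:
    seq = as_protein_sequence(seq)
    out: list[PRMMatch] = []
    seen: set[tuple[int, PRMClass]] = set()
    for m in pattern.finditer(seq.residues):
        start0 = m.start()
        if "X" in seq.residues[start0 : start0 + 7]:
            continue  # unknown residue voids this window only
        key = (start0 + 1, cls)
        if key in seen:
            continue
        seen.add(key)
        out.append(_make_match(seq, start0, cls))
    return out


def scan_class2(seq: ProteinSequence | str) -> list[PRMMatch]:
    """All class-II (xPxxPx+) windows; Px+P-compatible hits carry ``is_pxplusp``."""
    return _scan(seq, _RE_CLASS2, PRMClass.CLASS_II)


def scan_class1(seq: ProteinSequence | str) -> list[PRMMatch]:
    """All class-I (+xxPxxP) windows."""
    return _scan(seq, _RE_CLASS1, PRMClass.CLASS_I)


def scan_pxplusp(seq: ProteinSequence | str) -> list[PRMMatch]:
    """All atypical Px+P windows, xPx(K/R)Px(K/R); a subset of class-II hits."""
    return _scan(seq, _RE_PXPLUSP, PRMClass.PX_PLUS_P)


_SCANNERS = {
    PRMClass.CLASS_I: scan_class1,
    PRMClass.CLASS_II: scan_class2,
    PRMClass.PX_PLUS_P: scan_pxplusp,
}


def scan_all(seq: ProteinSequence | str) -> list[PRMMatch]:
    """Concatenated hits of all three scanners (class-I, class-II, Px+P)."""
    seq = as_protein_sequence(seq)
    return scan_class1(seq) + scan_class2(seq) + scan_pxplusp(seq)


def classify_window(window: str, variant_mode: bool = False) -> WindowClassification:
    """Classify a 7-9 residue window into its most specific PRM class.

    Specificity order: Px+P > class-II > class-I > NONE.  For 8- or 9-residue
    windows the leading extra residue is treated as register position -2 and a
    trailing ninth residue is ignored, so the 7-residue core starts at the
    second character.

    With ``variant_mode`` the classifier additionally recognizes windows that
    match a class-II/Px+P pattern except for a substituted anchor proline
    (e.g. the APC-like P3->S motif); these return the class the intact motif
    would have, with ``p0_present``/``p3_present`` cleared and a
    ``variant_label`` set.  Without it such windows are class NONE.
    """
    window = window.upper()
    if not 7 <= len(window) <= 9:
        raise ValueError(f"window must be 7-9 residues, got {len(window)}")
    core = window if len(window) == 7 else window[1:8]

    p0 = core[1] == "P"
    p3 = core[4] == "P"
    pos2, pos5 = core[3], core[6]
    class2 = p0 and p3 and pos5 in POSITIVE
    pxplusp = class2 and pos2 in POSITIVE
    class1 = core[0] in POSITIVE and core[3] == "P" and core[6] == "P"

    if pxplusp:
        cls, label = PRMClass.PX_PLUS_P, None
    elif class2:
        cls, label = PRMClass.CLASS_II, None
    elif class1:
        cls, label = PRMClass.CLASS_I, None
    else:
        cls, label = PRMClass.NONE, None

    p0_present, p3_present = True, True
    if cls is PRMClass.NONE and variant_mode and pos5 in POSITIVE and (p0 or p3) and not (p0 and p3):
        base = "Px+P" if pos2 in POSITIVE else "class-II"
        which = "P3" if p0 else "P0"
        label = f"{which}-substituted {base}-like"
        cls = PRMClass.PX_PLUS_P if pos2 in POSITIVE else PRMClass.CLASS_II
        p0_present, p3_present = p0, p3

    if cls is PRMClass.CLASS_I and not class2:
        pos2 = core[5]  # class-I register: position 2 is the residue before P3
        pos5 = None
    return WindowClassification(
        prm_class=cls,
        pos2_residue=pos2,
        pos5_residue=pos5,
        pos2_hydrophobic=(pos2 or "") in HYDROPHOBIC,
        p0_present=p0_present,
        p3_present=p3_present,
        variant_label=label,
    )


def matches_to_table(matches: Iterable[PRMMatch]) -> pd.DataFrame:
    """Tabulate matches (TSV-ready: one row per hit, register as JSON)."""
    rows = [
        {
            "protein_id": m.protein_id,
            "start": m.start,
            "end": m.end,
            "class": m.prm_class.value,
            "window": m.window,
            "pos2": m.pos2_residue,
            "pos5": m.pos5_residue,
            "pos2_hydrophobic": m.pos2_hydrophobic,
            "is_pxplusp": m.is_pxplusp,
            "register_json": m.register.to_json(),
        }
        for m in matches
    ]
    cols = [
        "protein_id", "start", "end", "class", "window",
        "pos2", "pos5", "pos2_hydrophobic", "is_pxplusp", "register_json",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_matches_tsv(matches: Iterable[PRMMatch], path: str | Path) -> None:
    matches_to_table(matches).to_csv(path, sep="\t", index=False)


def write_matches_jsonl(matches: Iterable[PRMMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in matches_to_table(matches).iterrows():
            fh.write(json.dumps(row.to_dict()) + "\n")
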