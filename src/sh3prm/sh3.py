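"""RT-loop diagnostic classification of SH3 domains (AGS vs canonical).

The SH3 domains of the ASAP, GRAF and SKAP families (collectively "AGS")
carry a Cxx(D/E) sequence in the RT-loop where most SH3 domains present an
aromatic residue at the groove-center site (e.g. F165 in SEM5) and a neutral
residue three positions later (Q168 in SEM5).  In ASAP1 these diagnostic
sites are C1096 and D1099: the small cysteine opens the central pocket for a
long lysine/arginine sidechain from register position 2 of the ligand, and
the aspartate pins its charged tip.  A domain is classified AGS if and only
if its residue mapped to the groove-center site is C, the residue mapped to
the acidic site is D or E, and the two sites are exactly three apart on the
query itself.

Diagnostic sites on a query domain are located by global pairwise alignment
(BLOSUM62, gap open 11 / extend 1, end gaps free) to an annotated reference.
The bundled default reference is a synthetic SH3-like scaffold (not a
database sequence) that places the C/D diagnostic pair at biological numbers
1096/1099 under ASAP1 numbering (domain span 1087-1147) and carries four
groove aromatics; all classification logic is relative to the annotation, so
any user-supplied annotated reference can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

AROMATIC = frozenset("FYWH")
ACIDIC = frozenset("DE")

GAP = None  # marker for a diagnostic site aligned to a gap


@dataclass(frozen=True)
class SH3Domain:
    """An excised SH3 domain sequence with biological numbering offset."""

    id: str
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 40 <= len(self.sequence) <= 90:
            warnings.warn(
                f"{self.id}: length {len(self.sequence)} outside the typical "
                "SH3 span (40-90 residues)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReferenceAnnotation:
    """An annotated reference SH3: diagnostic sites and groove aromatics.

    Indices are 1-based positions in ``sequence``.  The acidic site must sit
    exactly three residues after the groove-center site (the Cxx(D/E)
    spacing).
    """

    sequence: str
    groove_center_index: int
    acidic_index: int
    aromatic_indices: tuple[int, int, int, int]
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if self.acidic_index != self.groove_center_index + 3:
            raise ValueError("acidic site must be groove-center site + 3")
        for idx in (self.groove_center_index, self.acidic_index, *self.aromatic_indices):
            if not 1 <= idx <= len(self.sequence):
                raise ValueError(f"annotation index {idx} outside reference sequence")


# Synthetic SH3-like reference scaffold (61 residues, ASAP1-style numbering
# 1087-1147).  This is a constructed fixture, not a database sequence: the
# RT-loop carries the diagnostic Cxx(D/E) pair at biological numbers
# 1096/1099 (string indices 10/13) and four groove aromatics are annotated.
_SYNTHETIC_AGS_SCAFFOLD = (
    "TFVALYDYE"  # 1087-1095, beta1 + RT-loop start; Y1094 groove aromatic
    "CSRD"       # 1096-1099, diagnostic Cxx(D/E)
    "TETDLSFKKGERLQIVNNTEGD"  # 1100-1121
    "WWLAHSLSTGQT"            # 1122-1133, W1122 groove aromatic
    "GYIPSNYVAPSDSG"          # 1134-1147, Y1135/Y1140 groove aromatics
)

DEFAULT_REFERENCE = ReferenceAnnotation(
    sequence=_SYNTHETIC_AGS_SCAFFOLD,
    groove_center_index=10,  # biological 1096, C
    acidic_index=13,         # biological 1099, D
    aromatic_indices=(8, 36, 49, 54),
    numbering_offset=1086,
)

#: Canonical-control scaffold: same fold, RT-loop diagnostic pair replaced by
#: the SEM5-like F/Q (F165/Q168 analogue).
SEM5_LIKE_SEQUENCE = (
    _SYNTHETIC_AGS_SCAFFOLD[:9] + "F" + _SYNTHETIC_AGS_SCAFFOLD[10:12]
    + "Q" + _SYNTHETIC_AGS_SCAFFOLD[13:]
)

#: Fraction of the reference self-score below which a query is "unalignable".
SCORE_FLOOR_FRACTION = 0.25


@dataclass(frozen=True)
class SiteMapping:
    """Query-side locations of the reference's annotated sites."""

    query_id: str
    query_sequence: str
    groove_center: int | None  # 1-based query index, or None on gap
    acidic: int | None
    aromatics: tuple[int | None, int | None, int | None, int | None]
    score: float
    unalignable: bool


@dataclass(frozen=True)
class AromaticsReport:
    residues: tuple[str, ...]       # query residue at each annotated site ('-' on gap)
    present: tuple[bool, ...]       # aromatic (F/Y/W/H) at each site
    n_present: int
    degenerate_groove: bool         # >= 2 of the 4 sites lost


@dataclass(frozen=True)
class SH3Classification:
    domain_id: str
    sh3_class: str                  # "AGS" | "CANONICAL" | "UNKNOWN"
    groove_center_residue: str | None
    groove_center_index: int | None
    acidic_residue: str | None
    acidic_index: int | None
    aromatics: AromaticsReport | None
    score: float
    diagnostic: str = ""


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # End gaps free: flanking extensions must not be penalized.
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _self_score(sequence: str) -> float:
    mat = substitution_matrices.load("BLOSUM62")
    return float(sum(mat[ch, ch] for ch in sequence))


def map_diagnostic_positions(
    query: SH3Domain, ref: ReferenceAnnotation = DEFAULT_REFERENCE
) -> SiteMapping:
    """Locate the reference's annotated sites on a query by global alignment.

    Returns 1-based query indices for the groove-center site, the acidic
    site and the four groove aromatics; a site aligned to a gap maps to
    ``None``.  A query whose alignment score falls below
    ``SCORE_FLOOR_FRACTION`` of the reference self-score is flagged
    unalignable (classification will be UNKNOWN).
    """
    if not query.sequence or not ref.sequence:
        raise ValueError("query and reference must be non-empty")
    aligner = _aligner()
    alignment = aligner.align(ref.sequence, query.sequence)[0]
    score = float(alignment.score)
    unalignable = score < SCORE_FLOOR_FRACTION * _self_score(ref.sequence)

    def map_index(ref_index1: int) -> int | None:
        r0 = ref_index1 - 1
        for (t_start, t_end), (q_start, q_end) in zip(*alignment.aligned):
            if t_start <= r0 < t_end:
                return q_start + (r0 - t_start) + 1
        return None

    return SiteMapping(
        query_id=query.id,
        query_sequence=query.sequence,
        groove_center=map_index(ref.groove_center_index),
        acidic=map_index(ref.acidic_index),
        aromatics=tuple(map_index(i) for i in ref.aromatic_indices),
        score=score,
        unalignable=unalignable,
    )


def check_conserved_aromatics(mapping: SiteMapping) -> AromaticsReport:
    """Report which of the four annotated groove aromatics the query retains.

    A site is "present" when the mapped query residue is aromatic (F/Y/W/H);
    losing two or more of the four flags the groove as degenerate.
    """
    residues = []
    present = []
    for idx in mapping.aromatics:
        if idx is None:
            residues.append("-")
            present.append(False)
        else:
            res = mapping.query_sequence[idx - 1]
            residues.append(res)
            present.append(res in AROMATIC)
    n = sum(present)
    return AromaticsReport(
        residues=tuple(residues),
        present=tuple(present),
        n_present=n,
        degenerate_groove=(4 - n) >= 2,
    )


def classify_sh3(mapping: SiteMapping) -> SH3Classification:
    """Classify an SH3 domain from its diagnostic-site mapping.

    AGS requires groove-center C, acidic-site D/E, and a query-side spacing
    of exactly 3 (strict Cxx(D/E)); anything else alignable is CANONICAL;
    gaps or an unalignable query give UNKNOWN.
    """
    aromatics = check_conserved_aromatics(mapping)
    if mapping.unalignable:
        return SH3Classification(
            domain_id=mapping.query_id, sh3_class="UNKNOWN",
            groove_center_residue=None, groove_center_index=None,
            acidic_residue=None, acidic_index=None,
            aromatics=aromatics, score=mapping.score, diagnostic="unalignable",
        )
    if mapping.groove_center is None or mapping.acidic is None:
        return SH3Classification(
            domain_id=mapping.query_id, sh3_class="UNKNOWN",
            groove_center_residue=None, groove_center_index=mapping.groove_center,
            acidic_residue=None, acidic_index=mapping.acidic,
            aromatics=aromatics, score=mapping.score,
            diagnostic="diagnostic site aligned to gap",
        )
    groove_res = mapping.query_sequence[mapping.groove_center - 1]
    acidic_res = mapping.query_sequence[mapping.acidic - 1]
    spacing = mapping.acidic - mapping.groove_center
    is_ags = groove_res == "C" and acidic_res in ACIDIC and spacing == 3
    return SH3Classification(
        domain_id=mapping.query_id,
        sh3_class="AGS" if is_ags else "CANONICAL",
        groove_center_residue=groove_res,
        groove_center_index=mapping.groove_center,
        acidic_residue=acidic_res,
        acidic_index=mapping.acidic,
        aromatics=aromatics,
        score=mapping.score,
        diagnostic="" if is_ags else f"groove={groove_res}, acidic={acidic_res}, spacing={spacing}",
    )


def classify_domain(
    domain: SH3Domain, ref: ReferenceAnnotation = DEFAULT_REFERENCE
) -> SH3Classification:
    """One-shot alignment + classification of a single domain."""
    return classify_sh3(map_diagnostic_positions(domain, ref))


def read_reference_tsv(path: str | Path) -> ReferenceAnnotation:
    """Load a user-supplied reference annotation.

    Tab-separated, two lines minimum: a header and one row with columns
    ``sequence``, ``groove_center_index``, ``acidic_index``,
    ``aromatic_indices`` (comma-separated), ``numbering_offset`` (optional).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    row = df.iloc[0]
    return ReferenceAnnotation(
        sequence=str(row["sequence"]).upper(),
        groove_center_index=int(row["groove_center_index"]),
        acidic_index=int(row["acidic_index"]),
        aromatic_indices=tuple(int(x) for x in str(row["aromatic_indices"]).split(",")),
        numbering_offset=int(row.get("numbering_offset", 0) or 0),
    )
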