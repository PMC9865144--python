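"""Synthetic data with known ground truth for every pipeline stage.

Generators for proteomes with planted motifs at known registers, annotation
tables with planted term enrichment, ortholog sets with controlled motif
conservation, idealized polyproline-II peptide coordinates with pseudo-pocket
marker atoms at planted distances, and noisy one-site titration curves.
Every generator is deterministic given a seed; a single global seed fans out
to independent per-generator streams through documented stream ids
(``default_rng([stream_id, seed])``), so each data type is reproducible on
its own.

Ground truth is carried in a :class:`TruthTable` serialized alongside the
outputs.  Planted features are recorded at generation time and, for
proteomes, the final sequences are re-scanned so spontaneous background
matches also enter the truth table (truth = ground truth, not just the
plantings).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    POSITIVE,
    PRMClass,
    PRMRegister,
    scan_all,
    scan_class1,
    scan_class2,
    scan_pxplusp,
)
from .sequences import ProteinSequence, write_fasta

_STREAMS = {
    "proteome": 11,
    "annotations": 12,
    "orthologs": 13,
    "structure": 14,
    "titration": 15,
    "screen": 16,
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Swiss-Prot-like background composition (UniProtKB/Swiss-Prot release
#: statistics, percent frequencies normalized to 1).
SWISSPROT_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Per-generator random stream derived from the global seed."""
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class TruthTable:
    """Ground truth for generated data, keyed by output object.

    ``proteins[pid]`` may carry: ``planted`` (list of {class, start,
    register}), ``matches`` (post-hoc scan of the final sequence),
    ``cytoplasmic``, ``ppii``, ``conserved`` flags, ``localization``,
    ``terms``.  ``structures[name]`` carries planted register / salt bridges
    / aromatics.  ``titrations[name]`` carries the generating parameters.
    ``enrichment`` maps term id -> "enriched" | "null".
    """

    proteins: dict[str, dict] = field(default_factory=dict)
    structures: dict[str, dict] = field(default_factory=dict)
    titrations: dict[str, dict] = field(default_factory=dict)
    enrichment: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "proteins": self.proteins,
                    "structures": self.structures,
                    "titrations": self.titrations,
                    "enrichment": self.enrichment,
                },
                indent=2,
            )
        )


def random_sequence(length: int, rng: np.random.Generator, composition: str = "uniform") -> str:
    """Background sequence from a uniform or Swiss-Prot-like residue table."""
    if composition == "uniform":
        probs = None
    elif composition == "swissprot":
        probs = np.array([SWISSPROT_FREQS[a] for a in AA20])
        probs = probs / probs.sum()
    else:
        raise ValueError(f"unknown composition {composition!r}")
    return "".join(rng.choice(list(AA20), size=length, p=probs))


def gen_random_sequences(
    n: int, length: int, seed: int, composition: str = "uniform"
) -> list[ProteinSequence]:
    """Plain random sequences (no planting), for scanner-vs-oracle checks."""
    rng = stream_rng(seed, "proteome")
    return [
        ProteinSequence(id=f"R{i:04d}", residues=random_sequence(length, rng, composition))
        for i in range(n)
    ]


def _motif_window(cls: str, rng: np.random.Generator) -> str:
    """A 7-residue window guaranteed to match (exactly) the requested class."""
    x = lambda: rng.choice(list(AA20))
    plus = lambda: rng.choice(["K", "R"])
    if cls == "PX_PLUS_P":
        return "".join([x(), "P", x(), plus(), "P", x(), plus()])
    if cls == "CLASS_II":
        nonplus = lambda: rng.choice([a for a in AA20 if a not in POSITIVE])
        return "".join([x(), "P", nonplus(), nonplus(), "P", x(), plus()])
    if cls == "CLASS_I":
        return "".join([plus(), x(), x(), "P", x(), x(), "P"])
    raise ValueError(f"unknown motif class {cls!r}")


def _break_spurious(residues: list[str], match, planted_spans: list[tuple[int, int]]) -> bool:
    """Mutate one residue to void a spontaneous match without touching plantings.

    Prefers the pattern-bearing register slots (anchors and positives); falls
    back to any in-window position outside planted spans.  Returns False if
    the whole window lies inside planted spans.
    """

    def planted(idx1: int) -> bool:
        return any(lo <= idx1 <= hi for lo, hi in planted_spans)

    slots = [0, 3, 5, 2] if match.prm_class is not PRMClass.CLASS_I else [0, 3, -3]
    for slot in slots:
        idx1 = match.register.positions.get(slot)
        if idx1 is not None and not planted(idx1):
            residues[idx1 - 1] = "G"
            return True
    for idx1 in range(match.start, match.end + 1):
        if not planted(idx1):
            residues[idx1 - 1] = "G"
            return True
    return False


def gen_proteome(
    n_proteins: int = 50,
    length: int = 200,
    motif_spec: Mapping[str, int] | None = None,
    seed: int = 0,
    composition: str = "uniform",
    forbid_spontaneous: bool = False,
) -> tuple[list[ProteinSequence], TruthTable]:
    """Generate a proteome with motifs planted at recorded registers.

    ``motif_spec`` gives the number of proteins carrying one planted motif of
    each class, e.g. ``{"PX_PLUS_P": 12, "CLASS_II": 3}``; remaining proteins
    carry no planting.  Windows are placed away from the termini so the full
    -1..5 register (plus -2) is interior.  With ``forbid_spontaneous`` the
    background is locally re-mutated until no Px+P match exists outside the
    planted spans (useful when exact per-class counts are needed); otherwise
    spontaneous matches are simply recorded in the truth table.
    """
    motif_spec = dict(motif_spec or {})
    if length < 10:
        raise ValueError("sequences must be at least 10 residues for an interior motif")
    total = sum(motif_spec.values())
    if total > n_proteins:
        raise ValueError("motif_spec plants more proteins than the proteome holds")

    rng = stream_rng(seed, "proteome")
    labels = [cls for cls, k in motif_spec.items() for _ in range(k)]
    labels += [None] * (n_proteins - total)
    rng.shuffle(labels)

    truth = TruthTable()
    proteome = []
    for i, cls in enumerate(labels):
        pid = f"P{i:04d}"
        residues = list(random_sequence(length, rng, composition))
        planted = []
        planted_spans: list[tuple[int, int]] = []
        if cls is not None:
            start0 = int(rng.integers(1, length - 7))  # keep a -2 residue and a trailing one
            window = _motif_window(cls, rng)
            residues[start0 : start0 + 7] = list(window)
            planted_spans.append((start0 + 1, start0 + 7))
            planted.append({"class": cls, "start": start0 + 1, "window": window})

        if forbid_spontaneous:
            for _ in range(200):
                seq = "".join(residues)
                spurious = [
                    m
                    for m in scan_pxplusp(seq)
                    if (m.start, m.end) not in planted_spans
                ]
                if not spurious:
                    break
                if not _break_spurious(residues, spurious[0], planted_spans):
                    break  # fully inside plantings: keep (it is the planting)
            else:
                raise RuntimeError(f"{pid}: could not remove spontaneous motifs")

        seq = ProteinSequence(id=pid, residues="".join(residues))
        proteome.append(seq)
        matches = scan_all(seq)
        truth.proteins[pid] = {
            "planted": planted,
            "matches": [
                {
                    "class": m.prm_class.value,
                    "start": m.start,
                    "window": m.window,
                    "register": {str(k): v for k, v in m.register.positions.items()},
                }
                for m in matches
            ],
        }
        for m in planted:
            recovered = any(
                t["class"] == m["class"] and t["start"] == m["start"]
                for t in truth.proteins[pid]["matches"]
            )
            if not recovered:  # pragma: no cover - planting is constructive
                raise RuntimeError(f"{pid}: planted motif not recovered by scanner")
    return proteome, truth


def gen_annotations(
    truth: TruthTable,
    seed: int = 0,
    cyto_fraction: float = 0.6,
    enriched_terms: Mapping[str, float] | None = None,
    base_term_prob: float = 0.1,
    n_null_terms: int = 0,
    cytoplasmic_label: str = "cytoplasm",
    other_label: str = "nucleus",
) -> pd.DataFrame:
    """Annotation table (localization, ontology terms, ortholog-set id).

    Localization honours any ``cytoplasmic`` flag already planted in the
    truth table and otherwise samples cytoplasmic with ``cyto_fraction``.
    Each term in ``enriched_terms`` is planted among motif-positive proteins
    with probability ``min(ratio * base_term_prob, 0.95)`` versus
    ``base_term_prob`` in the background (ratio 1 = null); ``n_null_terms``
    extra terms are sampled at the base rate everywhere.  The expected
    enrichment direction is recorded in ``truth.enrichment``.
    """
    if not 0.0 <= cyto_fraction <= 1.0:
        raise ValueError("cyto_fraction must be within [0, 1]")
    if not 0.0 < base_term_prob < 1.0:
        raise ValueError("base_term_prob must be within (0, 1)")
    rng = stream_rng(seed, "annotations")
    enriched_terms = dict(enriched_terms or {})

    rows = []
    for pid, info in truth.proteins.items():
        motif_positive = any(m["class"] == "PX_PLUS_P" for m in info["matches"])
        if "cytoplasmic" in info:
            cyto = bool(info["cytoplasmic"])
        else:
            cyto = bool(rng.random() < cyto_fraction)
            info["cytoplasmic"] = cyto
        terms = []
        for term, ratio in enriched_terms.items():
            if ratio < 0:
                raise ValueError("enrichment ratio must be >= 0")
            p = min(ratio * base_term_prob, 0.95) if motif_positive else base_term_prob
            if rng.random() < p:
                terms.append(term)
            truth.enrichment[term] = "enriched" if ratio > 1 else "null"
        for j in range(n_null_terms):
            term = f"NULL{j:03d}"
            if rng.random() < base_term_prob:
                terms.append(term)
            truth.enrichment[term] = "null"
        info["localization"] = cytoplasmic_label if cyto else other_label
        info["terms"] = terms
        rows.append(
            {
                "protein_id": pid,
                "localization": info["localization"],
                "terms": "|".join(terms),
                "ortholog_set": pid,
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "localization", "terms", "ortholog_set"])


def _motif_positions(info: dict) -> set[int]:
    """1-based indices covered by register positions -1..5 of Px+P matches."""
    out: set[int] = set()
    for m in info["matches"]:
        if m["class"] != "PX_PLUS_P":
            continue
        for pos, idx in m["register"].items():
            if int(pos) >= -1:
                out.add(int(idx))
    return out


def gen_ortholog_sets(
    proteome: Sequence[ProteinSequence],
    truth: TruthTable,
    substitution_rate: float = 0.1,
    conserve_motif: bool = True,
    k: int = 5,
    seed: int = 0,
    motif_mutated_fraction: float = 1.0,
) -> dict[str, list[str]]:
    """Ortholog sequences with i.i.d. substitutions at ``substitution_rate``.

    With ``conserve_motif`` the Px+P register windows (-1..5) are held
    invariant in every ortholog; otherwise a ``motif_mutated_fraction`` of
    the k orthologs receives at least one forced substitution inside each
    motif window.  The intended conservation outcome is recorded per protein.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be within [0, 1]")
    if k < 1:
        raise ValueError("need at least one ortholog per set")
    rng = stream_rng(seed, "orthologs")
    out: dict[str, list[str]] = {}
    for seq in proteome:
        info = truth.proteins[seq.id]
        window = _motif_positions(info)
        n_mutated = math.ceil(motif_mutated_fraction * k) if not conserve_motif else 0
        mutated_orthologs = set(rng.choice(k, size=n_mutated, replace=False)) if n_mutated else set()
        orthologs = []
        for j in range(k):
            residues = list(seq.residues)
            for idx1 in range(1, len(residues) + 1):
                in_window = idx1 in window
                if in_window and conserve_motif:
                    continue
                if in_window and j not in mutated_orthologs:
                    continue
                if rng.random() < substitution_rate:
                    current = residues[idx1 - 1]
                    residues[idx1 - 1] = rng.choice([a for a in AA20 if a != current])
            if j in mutated_orthologs and window:
                intact = all(residues[i - 1] == seq.residues[i - 1] for i in window)
                if intact:
                    idx1 = int(rng.choice(sorted(window)))
                    current = residues[idx1 - 1]
                    residues[idx1 - 1] = rng.choice([a for a in AA20 if a != current])
            orthologs.append("".join(residues))
        info["conserved"] = bool(conserve_motif) if window else None
        out[seq.id] = orthologs
    return out


# ---------------------------------------------------------------------------
# Screen fixture: nested planted counts across the full filter cascade.
# ---------------------------------------------------------------------------


@dataclass
class ScreenFixture:
    """A proteome plus all screening inputs, with per-filter truth flags."""

    proteome: list[ProteinSequence]
    annotations: pd.DataFrame
    dihedrals: dict[str, dict[int, tuple[float, float]]]
    orthologs: dict[str, list[str]]
    truth: TruthTable


PPII_ANGLES = (-75.0, 145.0)
ALPHA_ANGLES = (-60.0, -45.0)


def gen_screen_fixture(
    seed: int = 0,
    n_proteins: int = 50,
    n_motif: int = 12,
    n_cyto: int = 8,
    n_ppii: int = 6,
    n_conserved: int = 5,
    length: int = 200,
) -> ScreenFixture:
    """Planted proteome for end-to-end screen tests.

    Of ``n_proteins`` proteins, ``n_motif`` carry a Px+P motif; ``n_cyto`` of
    those are cytoplasmic; ``n_ppii`` of the cytoplasmic ones have PPII
    dihedrals across the motif register; ``n_conserved`` of those have the
    motif conserved across orthologs.  Motif proteins outside the nested
    chain receive mixed flags so every filter subset has informative truth.
    """
    if not n_proteins >= n_motif >= n_cyto >= n_ppii >= n_conserved >= 0:
        raise ValueError("planted counts must be nested: proteins >= motif >= cyto >= ppii >= conserved")
    rng = stream_rng(seed, "screen")
    proteome, truth = gen_proteome(
        n_proteins=n_proteins,
        length=length,
        motif_spec={"PX_PLUS_P": n_motif},
        seed=seed,
        forbid_spontaneous=True,
    )
    motif_ids = [pid for pid, info in truth.proteins.items() if info["planted"]]
    rng.shuffle(motif_ids)
    cyto_ids = motif_ids[:n_cyto]
    noncyto_ids = motif_ids[n_cyto:]
    ppii_ids = set(cyto_ids[:n_ppii])
    conserved_ids = set(cyto_ids[:n_conserved])
    # Mixed flags off the nested chain: alternate so each filter subset is informative.
    for j, pid in enumerate(noncyto_ids):
        if j % 2 == 0:
            ppii_ids.add(pid)
        if j % 3 == 0:
            conserved_ids.add(pid)
    for pid in cyto_ids[n_ppii:]:
        if len(cyto_ids[n_ppii:]) > 1 and pid == cyto_ids[-1]:
            conserved_ids.add(pid)  # conserved but not PPII

    for pid, info in truth.proteins.items():
        info["cytoplasmic"] = pid in cyto_ids
        info["ppii"] = pid in ppii_ids if info["planted"] else None

    annotations = gen_annotations(truth, seed=seed, cyto_fraction=0.5)

    dihedrals: dict[str, dict[int, tuple[float, float]]] = {}
    for seq in proteome:
        info = truth.proteins[seq.id]
        per_res = {i: ALPHA_ANGLES for i in range(1, len(seq) + 1)}
        if info.get("ppii"):
            for idx in _motif_positions(info):
                per_res[idx] = PPII_ANGLES
        dihedrals[seq.id] = per_res

    orthologs: dict[str, list[str]] = {}
    for seq in proteome:
        conserve = seq.id in conserved_ids or not truth.proteins[seq.id]["planted"]
        orthologs.update(
            gen_ortholog_sets(
                [seq], truth, substitution_rate=0.05,
                conserve_motif=conserve, k=5, seed=seed,
            )
        )
        truth.proteins[seq.id]["conserved"] = (
            (seq.id in conserved_ids) if truth.proteins[seq.id]["planted"] else None
        )
    return ScreenFixture(
        proteome=proteome,
        annotations=annotations,
        dihedrals=dihedrals,
        orthologs=orthologs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Idealized peptide coordinates with a pseudo-pocket.
# ---------------------------------------------------------------------------

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# Ideal backbone geometry.
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: |cd| = bond, angle(b,c,d) = angle, torsion(a,b,c,d) = torsion."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    theta, chi = math.radians(angle_deg), math.radians(torsion_deg)
    d = np.array([-bond * math.cos(theta), bond * math.sin(theta) * math.cos(chi),
                  -bond * math.sin(theta) * math.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(sequence: str, phi: float, psi: float, omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry backbone (N, CA, C + CB except Gly) at uniform (phi, psi)."""
    coords: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c = ca + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, len(sequence)):
        prev = coords[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, omega)
        c_next = _place_atom(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": n_next, "CA": ca_next, "C": c_next})
    for res, aa in zip(coords, sequence):
        if aa == "G":
            continue
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"], 1.53, 110.5, 122.5)
    return coords


def _sidechain_markers(coords: list[dict[str, np.ndarray]], sequence: str) -> None:
    """Add terminal charged-group marker atoms for Lys (NZ) and Arg (NE, NH1)."""
    for res, aa in zip(coords, sequence):
        if "CB" not in res:
            continue
        u = res["CB"] - res["CA"]
        u = u / np.linalg.norm(u)
        if aa == "K":
            res["NZ"] = res["CB"] + 2.8 * u
        elif aa == "R":
            res["NE"] = res["CB"] + 1.8 * u
            res["NH1"] = res["CB"] + 3.2 * u


def gen_ppii_fixture(
    peptide_seq: str,
    register: Mapping[int, int] | PRMRegister,
    conformation: str = "PPII",
    seed: int = 0,
    path: str | Path | None = None,
    name: str = "fixture",
    truth: TruthTable | None = None,
) -> tuple[str, TruthTable]:
    """Build a two-chain PDB fixture: ideal peptide + pseudo-pocket markers.

    Chain A is the peptide at ideal geometry in the requested conformation
    (PPII: phi,psi = -75,145; ALPHA: -60,-45).  Chain B is a minimal marker
    cloud, not a folded domain: two PHE pseudo-ring atoms within 4.0 A of
    each anchor proline's sidechain, and ASP carboxylate atoms within 3.5 A
    of the terminal amine/guanidinium of the positive residues at register
    positions 2 and 5.  Returns the PDB text and a truth table recording the
    planted register, salt bridges and aromatic marker residues.
    """
    peptide_seq = peptide_seq.upper()
    positions = dict(register.positions) if isinstance(register, PRMRegister) else dict(register)
    for anchor in (0, 3):
        idx = positions.get(anchor)
        if idx is None or not 1 <= idx <= len(peptide_seq) or peptide_seq[idx - 1] != "P":
            raise ValueError(f"register position {anchor} must be a proline in the peptide")
    if conformation == "PPII":
        phi, psi = PPII_ANGLES
    elif conformation == "ALPHA":
        phi, psi = ALPHA_ANGLES
    else:
        raise ValueError(f"unknown conformation {conformation!r}")

    coords = build_backbone(peptide_seq, phi, psi)
    _sidechain_markers(coords, peptide_seq)

    centroid = np.mean([res["CA"] for res in coords], axis=0)

    def outward(res: dict[str, np.ndarray], key: str) -> np.ndarray:
        u = res[key] - res["CA"]
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            u = res[key] - centroid
            norm = np.linalg.norm(u)
        return u / norm

    pocket: list[tuple[str, str, np.ndarray]] = []  # (res_name, atom_name, coord)
    for anchor in (0, 3):
        res = coords[positions[anchor] - 1]
        u = outward(res, "CB")
        pocket.append(("PHE", "CZ", res["CB"] + 3.4 * u))
        pocket.append(("PHE", "CZ", res["CB"] + 3.8 * u))

    bridges = []
    for pos, atom in ((2, None), (5, None)):
        idx = positions.get(pos)
        if idx is None:
            continue
        aa = peptide_seq[idx - 1]
        key = "NZ" if aa == "K" else ("NH1" if aa == "R" else None)
        if key is None:
            continue
        res = coords[idx - 1]
        u = outward(res, key)
        pocket.append(("ASP", "OD1", res[key] + 3.0 * u))
        bridges.append((len(pocket), idx))  # pocket res_seq (1-based, below), peptide index

    pdb_text = _fixture_pdb(peptide_seq, coords, pocket)
    if truth is None:
        truth = TruthTable()
    truth.structures[name] = {
        "register": {str(k): v for k, v in sorted(positions.items())},
        "conformation": conformation,
        "phi": phi,
        "psi": psi,
        "aromatic_res_seqs": [i + 1 for i, (rn, _, _) in enumerate(pocket) if rn == "PHE"],
        "salt_bridges": [
            {"acidic_res_seq": b_seq, "basic_peptide_index": p_idx} for b_seq, p_idx in bridges
        ],
        "peptide": peptide_seq,
    }
    if path is not None:
        Path(path).write_text(pdb_text)
    return pdb_text, truth


def _fixture_pdb(sequence: str, coords: list[dict[str, np.ndarray]],
                 pocket: list[tuple[str, str, np.ndarray]]) -> str:
    """Assemble the two-chain fixture as PDB text (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic SH3/PRM fixture"
    model = gemmi.Model("1")
    chain_a = gemmi.Chain("A")
    for i, (aa, res_coords) in enumerate(zip(sequence, coords), start=1):
        residue = gemmi.Residue()
        residue.name = ONE_TO_THREE[aa]
        residue.seqid = gemmi.SeqId(i, " ")
        for atom_name, xyz in res_coords.items():
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            residue.add_atom(atom)
        chain_a.add_residue(residue)
    chain_b = gemmi.Chain("B")
    for i, (res_name, atom_name, xyz) in enumerate(pocket, start=1):
        residue = gemmi.Residue()
        residue.name = res_name
        residue.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = atom_name
        atom.element = gemmi.Element(atom_name[0])
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        residue.add_atom(atom)
        chain_b.add_residue(residue)
    model.add_chain(chain_a)
    model.add_chain(chain_b)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def gen_titration(
    seed: int = 0,
    n_sites: float = 1.0,
    kd: float = 1e-6,
    dh: float = -10.0,
    noise_fraction: float = 0.01,
    protocol=None,
    name: str = "titration",
    truth: TruthTable | None = None,
):
    """Simulate a noisy titration curve, recording the generating parameters.

    ``noise_fraction`` scales Gaussian heat noise to the first-injection
    heat (1% by default).
    """
    from .itc import TitrationProtocol, relative_noise_sd, simulate_titration

    protocol = protocol or TitrationProtocol()
    sd = relative_noise_sd(protocol, n_sites, kd, dh, noise_fraction) if noise_fraction else 0.0
    rng = stream_rng(seed, "titration")
    curve = simulate_titration(protocol, n_sites, kd, dh, noise_sd=sd, seed=rng)
    if truth is None:
        truth = TruthTable()
    truth.titrations[name] = {
        "n_sites": n_sites, "kd_m": kd, "dh": dh,
        "noise_sd": sd, "seed": seed,
    }
    return curve, truth
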