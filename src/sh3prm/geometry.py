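"""SH3/peptide complex geometry: contacts, salt bridges, PPII dihedrals, register.

Operates on PDB-format coordinates (parsed with gemmi).  Conventions:

* contacts: heavy-atom pairs across two chains within 4.5 A (configurable);
* salt bridges: Lys NZ / Arg NE,NH1,NH2 within 4.0 A of Asp OD1,OD2 /
  Glu OE1,OE2 (His excluded -- protonation unknown);
* polyproline-II: backbone dihedrals within +/-30 deg (angular distance) of
  (phi, psi) = (-75, +145), the canonical PPII region;
* structure-derived register: the two peptide prolines with the most
  heavy-atom contacts to the annotated groove aromatics are taken as the
  anchor prolines P0/P3 and cross-checked against the sequence-derived
  register, which wins on mismatch (with a warning).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .motifs import PRMRegister, scan_class2
from .sequences import ProteinSequence

CONTACT_CUTOFF = 4.5
SALT_BRIDGE_CUTOFF = 4.0
PPII_PHI = -75.0
PPII_PSI = 145.0
PPII_TOL = 30.0

BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
AROMATIC_RESNAMES = {"PHE", "TYR", "TRP", "HIS"}
ACIDIC_RESNAMES = {"ASP", "GLU"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    res_name: str
    res_seq: int
    icode: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain_id, self.res_name, self.res_seq, self.icode)


@dataclass(frozen=True)
class ContactPair:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: tuple[str, str, int, str]
    acidic_residue: tuple[str, str, int, str]
    distance: float  # minimal N-O distance over the atom pairs


@dataclass(frozen=True)
class ResidueDihedral:
    res_seq: int
    icode: str
    res_name: str
    phi: float | None  # degrees, (-180, 180]; None at termini / missing atoms
    psi: float | None


def _validate_pdb_text(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}: malformed ATOM record at line {lineno} (truncated)")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed ATOM record at line {lineno} (bad coordinates)"
                ) from None


def read_structure(path: str | Path) -> dict[str, list[AtomRecord]]:
    """Parse a PDB file into per-chain heavy-atom lists.

    Hydrogens are dropped; alternate locations resolve to the highest
    occupancy (first seen wins ties); insertion codes are preserved.
    Malformed ATOM records raise with the offending line number.
    """
    import gemmi

    _validate_pdb_text(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    chains: dict[str, list[AtomRecord]] = {}
    n_atoms = 0
    for model in st:
        for chain in model:
            records = chains.setdefault(chain.name, [])
            for residue in chain:
                # altloc resolution per atom name
                best: dict[str, tuple[float, int, "gemmi.Atom"]] = {}
                for order, atom in enumerate(residue):
                    if atom.element.is_hydrogen:
                        continue
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev[0]:
                        best[atom.name] = (atom.occ, order, atom)
                for _, _, atom in sorted(best.values(), key=lambda t: t[1]):
                    records.append(
                        AtomRecord(
                            chain_id=chain.name,
                            res_name=residue.name,
                            res_seq=residue.seqid.num,
                            icode=residue.seqid.icode.strip(),
                            atom_name=atom.name,
                            element=atom.element.name,
                            x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        )
                    )
                    n_atoms += 1
        break  # first model only
    if n_atoms == 0:
        raise ValueError(f"{path}: no atoms found")
    return chains


def residues_in_order(atoms: Sequence[AtomRecord]) -> list[tuple[tuple[str, str, int, str], list[AtomRecord]]]:
    """Group a chain's atoms by residue, preserving file order."""
    out: list[tuple[tuple[str, str, int, str], list[AtomRecord]]] = []
    index: dict[tuple, int] = {}
    for atom in atoms:
        key = atom.residue_key
        if key not in index:
            index[key] = len(out)
            out.append((key, []))
        out[index[key]][1].append(atom)
    return out


def chain_sequence(atoms: Sequence[AtomRecord]) -> str:
    """One-letter sequence of a chain in residue order ('X' for non-standard)."""
    return "".join(THREE_TO_ONE.get(key[1], "X") for key, _ in residues_in_order(atoms))


def compute_contacts(
    chain_a: Sequence[AtomRecord],
    chain_b: Sequence[AtomRecord],
    cutoff: float = CONTACT_CUTOFF,
) -> list[ContactPair]:
    """All cross-chain heavy-atom pairs within ``cutoff`` (exact Euclidean)."""
    if not chain_a or not chain_b:
        raise ValueError("both chains must be non-empty")
    ids_a = {a.chain_id for a in chain_a}
    ids_b = {b.chain_id for b in chain_b}
    if ids_a & ids_b:
        raise ValueError(
            f"contact analysis needs two distinct chains, got {sorted(ids_a & ids_b)} on both sides"
        )
    coords_a = np.array([a.coord for a in chain_a])
    coords_b = np.array([b.coord for b in chain_b])
    tree_b = cKDTree(coords_b)
    pairs = cKDTree(coords_a).query_ball_tree(tree_b, r=cutoff)
    out = []
    for i, neighbours in enumerate(pairs):
        for j in sorted(neighbours):
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            if d <= cutoff:
                out.append(ContactPair(chain_a[i], chain_b[j], d))
    return out


def detect_salt_bridges(
    contacts: Iterable[ContactPair], cutoff: float = SALT_BRIDGE_CUTOFF
) -> list[SaltBridge]:
    """Salt bridges among contact pairs: basic-N to acidic-O within ``cutoff``."""
    best: dict[tuple, float] = {}
    for c in contacts:
        for basic, acidic in ((c.atom_a, c.atom_b), (c.atom_b, c.atom_a)):
            if (
                (basic.res_name, basic.atom_name) in BASIC_ATOMS
                and (acidic.res_name, acidic.atom_name) in ACIDIC_ATOMS
                and c.distance <= cutoff
            ):
                key = (basic.residue_key, acidic.residue_key)
                if key not in best or c.distance < best[key]:
                    best[key] = c.distance
    return [
        SaltBridge(basic_residue=k[0], acidic_residue=k[1], distance=d)
        for k, d in sorted(best.items(), key=lambda kv: kv[0])
    ]


def dihedral_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Torsion angle in degrees, range (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))
    return 180.0 if angle <= -180.0 else angle


def compute_dihedrals(atoms: Sequence[AtomRecord]) -> list[ResidueDihedral]:
    """Backbone phi/psi for each residue of one chain.

    Terminal residues and residues missing any backbone atom get None for the
    affected angle; no error is raised for incomplete residues.
    """
    residues = residues_in_order(atoms)
    backbone = []
    for key, res_atoms in residues:
        names = {a.atom_name: a.coord for a in res_atoms}
        backbone.append((key, names.get("N"), names.get("CA"), names.get("C")))
    out = []
    for i, (key, n, ca, c) in enumerate(backbone):
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if i > 0 and backbone[i - 1][3] is not None:
                phi = dihedral_angle(backbone[i - 1][3], n, ca, c)
            if i + 1 < len(backbone) and backbone[i + 1][1] is not None:
                psi = dihedral_angle(n, ca, c, backbone[i + 1][1])
        out.append(ResidueDihedral(res_seq=key[2], icode=key[3], res_name=key[1], phi=phi, psi=psi))
    return out


def angular_distance(a: float, b: float) -> float:
    """Shortest distance between two angles in degrees."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def is_ppii(
    series: Sequence[ResidueDihedral] | Sequence[tuple[float | None, float | None]],
    tol: float = PPII_TOL,
) -> list[bool]:
    """Per-residue PPII flags: both angles defined and within ``tol`` of (-75, 145)."""
    flags = []
    for item in series:
        phi, psi = (item.phi, item.psi) if isinstance(item, ResidueDihedral) else item
        flags.append(
            phi is not None
            and psi is not None
            and angular_distance(phi, PPII_PHI) <= tol
            and angular_distance(psi, PPII_PSI) <= tol
        )
    return flags


def assign_register_from_structure(
    sh3_atoms: Sequence[AtomRecord],
    peptide_atoms: Sequence[AtomRecord],
    aromatic_res_seqs: Sequence[int] | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> PRMRegister:
    """Derive the PRM register from groove-contact geometry.

    P0 and P3 are taken as the two peptide prolines with the largest
    heavy-atom contact counts to the annotated groove aromatics
    (``aromatic_res_seqs``; default: every aromatic residue of the SH3
    chain).  The result is cross-checked against the sequence-derived
    register; on mismatch a warning is issued and the sequence register is
    returned.  Register indices are 1-based positions along the peptide
    chain.
    """
    if aromatic_res_seqs is None:
        groove = [a for a in sh3_atoms if a.res_name in AROMATIC_RESNAMES]
    else:
        wanted = set(aromatic_res_seqs)
        groove = [a for a in sh3_atoms if a.res_seq in wanted]
    if not groove:
        raise ValueError("register unassignable: no groove aromatics annotated or present")

    residues = residues_in_order(peptide_atoms)
    groove_tree = cKDTree(np.array([a.coord for a in groove]))
    pro_counts: list[tuple[int, int]] = []  # (chain position 1-based, contact count)
    for pos, (key, res_atoms) in enumerate(residues, start=1):
        if key[1] != "PRO":
            continue
        coords = np.array([a.coord for a in res_atoms])
        count = int(sum(len(nb) for nb in groove_tree.query_ball_point(coords, r=cutoff)))
        if count > 0:
            pro_counts.append((pos, count))
    if not pro_counts:
        raise ValueError("register unassignable: no peptide proline contacts the groove")

    pro_counts.sort(key=lambda t: (-t[1], t[0]))
    top = sorted(p for p, _ in pro_counts[:2])
    structural = (top[0], top[-1])

    seq = chain_sequence(peptide_atoms)
    matches = scan_class2(ProteinSequence(id="peptide", residues=seq))
    seq_register = None
    for m in matches:
        if m.register.positions[0] == structural[0]:
            seq_register = m.register
            break
    if seq_register is None and matches:
        seq_register = matches[0].register

    if seq_register is not None:
        seq_anchors = (seq_register.positions[0], seq_register.positions[3])
        if len(structural) < 2 or seq_anchors != structural:
            warnings.warn(
                f"structure-derived anchors {structural} disagree with sequence register "
                f"{seq_anchors}; sequence register wins",
                stacklevel=2,
            )
        return seq_register

    # No sequence motif: fall back to the structural anchors if they are 3 apart.
    p0, p3 = structural
    if p3 - p0 != 3:
        raise ValueError(
            "register unassignable: groove-contacting prolines are not 3 residues apart "
            "and the peptide sequence carries no class-II motif"
        )
    warnings.warn(
        "peptide sequence carries no class-II motif; register anchors disagree with any "
        "sequence-derived register and are taken from the structure alone",
        stacklevel=2,
    )
    positions = {k: p0 + k for k in range(-1, 6) if 1 <= p0 + k <= len(residues)}
    return PRMRegister(positions)


@dataclass
class InterfaceReport:
    """Structure-level summary of one SH3/peptide complex."""

    contacts: list[ContactPair]
    salt_bridges: list[SaltBridge]
    pocket_summary: dict[int, dict[str, int]]
    structure_register: PRMRegister | None
    register_error: str | None
    ppii_flags: dict[int, bool]  # peptide res_seq -> PPII
    peptide_sequence: str

    def to_dict(self) -> dict:
        return {
            "n_contacts": len(self.contacts),
            "contacts": [
                {
                    "chain_a": c.atom_a.chain_id, "res_a": c.atom_a.res_seq,
                    "name_a": f"{c.atom_a.res_name}:{c.atom_a.atom_name}",
                    "chain_b": c.atom_b.chain_id, "res_b": c.atom_b.res_seq,
                    "name_b": f"{c.atom_b.res_name}:{c.atom_b.atom_name}",
                    "distance": round(c.distance, 3),
                }
                for c in self.contacts
            ],
            "salt_bridges": [
                {
                    "basic": list(b.basic_residue),
                    "acidic": list(b.acidic_residue),
                    "distance": round(b.distance, 3),
                }
                for b in self.salt_bridges
            ],
            "pocket_summary": {str(k): v for k, v in self.pocket_summary.items()},
            "structure_register": (
                {str(k): v for k, v in self.structure_register.positions.items()}
                if self.structure_register
                else None
            ),
            "register_error": self.register_error,
            "ppii_flags": {str(k): v for k, v in self.ppii_flags.items()},
            "peptide_sequence": self.peptide_sequence,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def analyze_complex(
    path: str | Path,
    sh3_chain: str,
    peptide_chain: str,
    aromatic_res_seqs: Sequence[int] | None = None,
    contact_cutoff: float = CONTACT_CUTOFF,
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
    ppii_tol: float = PPII_TOL,
) -> InterfaceReport:
    """Full interface analysis of a two-chain complex in a PDB file."""
    chains = read_structure(path)
    if len(chains) < 2:
        raise ValueError(
            f"complex analysis needs at least two chains; {path} has {sorted(chains)}"
        )
    for name in (sh3_chain, peptide_chain):
        if name not in chains:
            raise ValueError(f"chain {name!r} not in structure (has {sorted(chains)})")
    sh3_atoms = chains[sh3_chain]
    pep_atoms = chains[peptide_chain]

    contacts = compute_contacts(sh3_atoms, pep_atoms, cutoff=contact_cutoff)
    bridges = detect_salt_bridges(contacts, cutoff=salt_bridge_cutoff)

    dihedrals = compute_dihedrals(pep_atoms)
    flags = is_ppii(dihedrals, tol=ppii_tol)
    ppii_flags = {d.res_seq: f for d, f in zip(dihedrals, flags)}

    register = None
    register_error = None
    try:
        register = assign_register_from_structure(
            sh3_atoms, pep_atoms, aromatic_res_seqs=aromatic_res_seqs, cutoff=contact_cutoff
        )
    except ValueError as exc:
        register_error = str(exc)

    pocket: dict[int, dict[str, int]] = {}
    if register is not None:
        residues = residues_in_order(pep_atoms)
        pos_by_chain_index = {v: k for k, v in register.positions.items()}
        for c in contacts:
            # chain position of the peptide atom in this contact
            for idx, (key, _) in enumerate(residues, start=1):
                if key == c.atom_b.residue_key:
                    reg_pos = pos_by_chain_index.get(idx)
                    break
            else:
                reg_pos = None
            if reg_pos is None:
                continue
            slot = pocket.setdefault(reg_pos, {"groove": 0, "acidic": 0})
            if c.atom_a.res_name in AROMATIC_RESNAMES:
                slot["groove"] += 1
            if c.atom_a.res_name in ACIDIC_RESNAMES:
                slot["acidic"] += 1

    return InterfaceReport(
        contacts=contacts,
        salt_bridges=bridges,
        pocket_summary=pocket,
        structure_register=register,
        register_error=register_error,
        ppii_flags=ppii_flags,
        peptide_sequence=chain_sequence(pep_atoms),
    )
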