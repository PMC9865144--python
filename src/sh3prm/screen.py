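"""Proteome-wide Px+P candidate screen, enrichment statistics and network summary.

The screen mirrors the published filter cascade: scan for the xPx(K/R)Px(K/R)
pattern, then keep candidates that are (1) cytoplasmic, (2) in polyproline-II
conformation across the motif register, and (3) sequence-conserved across
orthologs.  The motif scan defines the candidate unit and always runs; the
three downstream filters are individually switchable.  Missing annotation,
dihedral or ortholog data fails the corresponding filter by default
(fail-closed), switchable to fail-open.

Term enrichment is an exact hypergeometric upper tail with Benjamini-
Hochberg adjustment across tested terms; a term passes at the conventional
thresholds p < 0.01, count >= 3 and enrichment factor > 1.5.  The enrichment
background is the screened universe (the input proteome), not an external
database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .geometry import is_ppii
from .motifs import PRMMatch, scan_pxplusp
from .sequences import ProteinSequence

FILTERS = ("motif", "localization", "ppii", "conservation")


@dataclass(frozen=True)
class ScreenConfig:
    """Filter switches and parameters for :func:`run_screen`.

    ``enabled`` lists active filters (subset of :data:`FILTERS`).  The motif
    scan always runs -- it defines what a candidate is -- so the ``motif``
    entry is accepted for symmetry but does not change the candidate set.
    """

    enabled: frozenset = frozenset(FILTERS)
    cytoplasmic_labels: frozenset = frozenset({"cytoplasm", "cytosol"})
    conservation_threshold: float = 0.8
    ppii_tol: float = 30.0
    fail_open: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.enabled) - set(FILTERS)
        if unknown:
            raise ValueError(f"unknown filters: {sorted(unknown)}")
        object.__setattr__(self, "enabled", frozenset(self.enabled))
        object.__setattr__(
            self, "cytoplasmic_labels", frozenset(s.lower() for s in self.cytoplasmic_labels)
        )


@dataclass
class CandidateRecord:
    """One motif-bearing protein with per-filter audit flags."""

    protein_id: str
    matches: list[PRMMatch]
    motif_pass: bool
    localization_pass: bool | None     # None = filter disabled
    ppii_pass: bool | None
    conservation_pass: bool | None
    per_match_ppii: list[bool]
    per_match_conservation: list[bool]
    final_pass: bool
    eliminated_at: str | None          # first enabled stage that failed


def _match_window_indices(match: PRMMatch) -> list[int]:
    """1-based indices of register positions -1..5."""
    return [idx for pos, idx in sorted(match.register.positions.items()) if pos >= -1]


def _localization_sets(annotations: pd.DataFrame | Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    if isinstance(annotations, pd.DataFrame):
        out = {}
        for _, row in annotations.iterrows():
            labels = str(row["localization"]).split("|")
            out[str(row["protein_id"])] = {s.strip().lower() for s in labels if s.strip()}
        return out
    return {pid: {str(s).lower() for s in labels} for pid, labels in annotations.items()}


def run_screen(
    proteome: Sequence[ProteinSequence],
    annotations: pd.DataFrame | Mapping[str, Iterable[str]] | None = None,
    dihedrals: Mapping[str, Mapping[int, tuple[float, float]]] | pd.DataFrame | None = None,
    orthologs: Mapping[str, Sequence[str]] | None = None,
    config: ScreenConfig | None = None,
) -> list[CandidateRecord]:
    """Run the Px+P filter cascade over a proteome.

    ``dihedrals`` maps protein id -> {1-based residue -> (phi, psi)} (or a
    DataFrame with columns protein_id, residue, phi, psi); ``orthologs`` maps
    protein id -> equal-length ortholog sequences.  Returns one record per
    motif-bearing protein with full per-stage audit flags.
    """
    config = config or ScreenConfig()
    enabled = config.enabled
    loc_sets = _localization_sets(annotations) if annotations is not None else {}
    if isinstance(dihedrals, pd.DataFrame):
        dmap: dict[str, dict[int, tuple[float, float]]] = {}
        for _, row in dihedrals.iterrows():
            dmap.setdefault(str(row["protein_id"]), {})[int(row["residue"])] = (
                float(row["phi"]), float(row["psi"])
            )
        dihedrals = dmap

    records: list[CandidateRecord] = []
    for seq in proteome:
        matches = scan_pxplusp(seq)
        if not matches:
            continue
        record = _screen_protein(seq, matches, loc_sets, dihedrals, orthologs, config)
        records.append(record)
    return records


def _screen_protein(seq, matches, loc_sets, dihedrals, orthologs, config) -> CandidateRecord:
    enabled = config.enabled
    fail_open = config.fail_open

    loc = loc_sets.get(seq.id)
    if loc is None:
        loc_pass = fail_open
    else:
        loc_pass = bool(loc & config.cytoplasmic_labels)

    per_res = dihedrals.get(seq.id) if dihedrals else None
    per_match_ppii = []
    for m in matches:
        idxs = _match_window_indices(m)
        if per_res is None or any(i not in per_res for i in idxs):
            per_match_ppii.append(fail_open)
        else:
            flags = is_ppii([per_res[i] for i in idxs], tol=config.ppii_tol)
            per_match_ppii.append(all(flags))

    orths = orthologs.get(seq.id) if orthologs else None
    per_match_cons = []
    for m in matches:
        idxs = _match_window_indices(m)
        if not orths:
            per_match_cons.append(fail_open)
            continue
        intact = 0
        usable = 0
        for orth in orths:
            if len(orth) != len(seq.residues):
                continue  # unalignable ortholog: skipped (counts against the fraction)
            usable += 1
            if all(orth[i - 1] == seq.residues[i - 1] for i in idxs):
                intact += 1
        if usable == 0:
            per_match_cons.append(fail_open)
        else:
            per_match_cons.append(intact / len(orths) >= config.conservation_threshold)

    # A match survives if it passes every enabled match-level filter.
    def match_ok(i: int) -> bool:
        if "ppii" in enabled and not per_match_ppii[i]:
            return False
        if "conservation" in enabled and not per_match_cons[i]:
            return False
        return True

    motif_pass = True  # candidacy established by construction
    stage_pass = {
        "motif": motif_pass,
        "localization": loc_pass if "localization" in enabled else None,
        "ppii": (any(per_match_ppii)) if "ppii" in enabled else None,
        "conservation": None,
    }
    final = ("localization" not in enabled or loc_pass) and any(
        match_ok(i) for i in range(len(matches))
    )
    if "conservation" in enabled:
        survivors_pre = [
            i for i in range(len(matches))
            if "ppii" not in enabled or per_match_ppii[i]
        ]
        stage_pass["conservation"] = any(per_match_cons[i] for i in survivors_pre)

    eliminated_at = None
    if not final:
        if "localization" in enabled and not loc_pass:
            eliminated_at = "localization"
        elif "ppii" in enabled and not any(per_match_ppii):
            eliminated_at = "ppii"
        else:
            eliminated_at = "conservation"

    return CandidateRecord(
        protein_id=seq.id,
        matches=matches,
        motif_pass=motif_pass,
        localization_pass=stage_pass["localization"],
        ppii_pass=stage_pass["ppii"],
        conservation_pass=stage_pass["conservation"],
        per_match_ppii=per_match_ppii,
        per_match_conservation=per_match_cons,
        final_pass=final,
        eliminated_at=eliminated_at,
    )


def screen_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Tabulate candidate records with per-stage flags (TSV-ready)."""
    rows = [
        {
            "protein_id": r.protein_id,
            "n_matches": len(r.matches),
            "motif": r.motif_pass,
            "localization": r.localization_pass,
            "ppii": r.ppii_pass,
            "conservation": r.conservation_pass,
            "final": r.final_pass,
            "eliminated_at": r.eliminated_at or "",
        }
        for r in records
    ]
    cols = ["protein_id", "n_matches", "motif", "localization", "ppii", "conservation", "final", "eliminated_at"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int        # selected proteins with the term
    n: int        # selected proteins
    K: int        # universe proteins with the term
    N: int        # universe size
    p_value: float
    q_value: float
    enrichment_factor: float
    passes_thresholds: bool


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Term-selection thresholds: p < 0.01, count >= 3, factor > 1.5."""

    max_p: float = 0.01
    min_count: int = 3
    min_factor: float = 1.5


def hypergeom_enrich(
    selected_ids: Iterable[str],
    universe_ids: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    thresholds: EnrichmentThresholds | None = None,
) -> list[EnrichmentResult]:
    """Exact hypergeometric term enrichment of a selected set within a universe.

    ``term_map`` maps term id -> protein ids carrying the term.  P-values are
    upper-tail (P[X >= k]); q-values are Benjamini-Hochberg across the tested
    terms; terms absent from the universe (K = 0) are skipped.  Pass/fail
    uses the raw-p threshold together with the count and factor thresholds.
    """
    thresholds = thresholds or EnrichmentThresholds()
    selected = set(selected_ids)
    universe = set(universe_ids)
    if not selected <= universe:
        raise ValueError(f"selected ids outside universe: {sorted(selected - universe)[:5]}")
    n, N = len(selected), len(universe)

    rows = []
    for term, members in term_map.items():
        members = set(members) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        factor = (k / n) / (K / N) if n > 0 else 0.0
        rows.append((term, k, K, p, factor))
    if not rows:
        return []
    qs = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = []
    for (term, k, K, p, factor), q in zip(rows, qs):
        passes = (
            p < thresholds.max_p
            and k >= thresholds.min_count
            and factor > thresholds.min_factor
        )
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, N=N,
                p_value=p, q_value=float(q),
                enrichment_factor=factor, passes_thresholds=passes,
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p_value": r.p_value, "q_value": r.q_value,
                "enrichment_factor": r.enrichment_factor,
                "passes_thresholds": r.passes_thresholds,
            }
            for r in results
        ],
        columns=["term", "k", "n", "K", "N", "p_value", "q_value", "enrichment_factor", "passes_thresholds"],
    )


# ---------------------------------------------------------------------------
# Interaction-network summary
# ---------------------------------------------------------------------------


def build_network(
    edge_table: Iterable[tuple[str, str]] | pd.DataFrame,
    node_classes: Mapping[str, str],
) -> dict:
    """Summarize a user-supplied interaction network.

    ``node_classes`` maps every node to its class (e.g. "AGS" vs "PRM");
    edges referencing unknown nodes raise with the offending ids.  Returns
    connected components, per-node degree and the count of cross-class
    (AGS-PRM) edges.
    """
    if isinstance(edge_table, pd.DataFrame):
        edges = [(str(a), str(b)) for a, b in edge_table.iloc[:, :2].itertuples(index=False)]
    else:
        edges = [(str(a), str(b)) for a, b in edge_table]
    unknown = sorted({v for e in edges for v in e if v not in node_classes})
    if unknown:
        raise ValueError(f"edges reference unknown nodes: {unknown}")

    g = nx.Graph()
    g.add_nodes_from(node_classes)
    g.add_edges_from(edges)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    cross = sum(1 for a, b in g.edges if node_classes[a] != node_classes[b])
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_components": len(components),
        "components": components,
        "degree": {n: int(d) for n, d in g.degree},
        "cross_class_edges": cross,
    }
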