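"""Screen cascade, hypergeometric enrichment and network-summary tests."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from sh3prm.screen import (
    FILTERS,
    EnrichmentThresholds,
    ScreenConfig,
    build_network,
    hypergeom_enrich,
    run_screen,
    screen_table,
)
from sh3prm.motifs import scan_pxplusp
from sh3prm import synthetic


def expected_passes(truth, subset) -> int:
    n = 0
    for info in truth.proteins.values():
        if not info["planted"]:
            continue
        ok = True
        if "localization" in subset:
            ok &= bool(info["cytoplasmic"])
        if "ppii" in subset:
            ok &= bool(info["ppii"])
        if "conservation" in subset:
            ok &= bool(info["conserved"])
        n += ok
    return n


class TestScreenCascade:
    def test_planted_counts_recovered_for_every_filter_subset(self, screen_fixture):
        fx = screen_fixture
        for r in range(len(FILTERS) + 1):
            for subset in combinations(FILTERS, r):
                cfg = ScreenConfig(enabled=frozenset(subset))
                recs = run_screen(fx.proteome, fx.annotations, fx.dihedrals, fx.orthologs, cfg)
                got = sum(x.final_pass for x in recs)
                assert got == expected_passes(fx.truth, subset), subset

    def test_full_cascade_yields_planted_survivor_count(self, screen_fixture):
        fx = screen_fixture
        recs = run_screen(fx.proteome, fx.annotations, fx.dihedrals, fx.orthologs)
        assert sum(r.final_pass for r in recs) == 5

    def test_filter_monotonicity(self, screen_fixture):
        """Enabling an additional filter never increases the pass count."""
        fx = screen_fixture

        def passes(subset):
            cfg = ScreenConfig(enabled=frozenset(subset))
            return sum(
                r.final_pass
                for r in run_screen(fx.proteome, fx.annotations, fx.dihedrals, fx.orthologs, cfg)
            )

        for r in range(len(FILTERS)):
            for subset in combinations(FILTERS, r):
                base = passes(subset)
                for extra in set(FILTERS) - set(subset):
                    assert passes(set(subset) | {extra}) <= base

    def test_all_filters_disabled_reduces_to_scanner(self, screen_fixture):
        fx = screen_fixture
        recs = run_screen(fx.proteome, config=ScreenConfig(enabled=frozenset()))
        scanner_hits = {s.id for s in fx.proteome if scan_pxplusp(s)}
        assert {r.protein_id for r in recs if r.final_pass} == scanner_hits

    def test_stage_audit_partitions_candidates(self, screen_fixture):
        fx = screen_fixture
        recs = run_screen(fx.proteome, fx.annotations, fx.dihedrals, fx.orthologs)
        n_final = sum(r.final_pass for r in recs)
        n_eliminated = sum(1 for r in recs if r.eliminated_at is not None)
        assert n_final + n_eliminated == len(recs)
        assert all((r.eliminated_at is None) == r.final_pass for r in recs)

    def test_empty_proteome_gives_empty_output(self):
        assert run_screen([]) == []

    def test_missing_data_fails_closed_by_default(self, screen_fixture):
        fx = screen_fixture
        recs = run_screen(fx.proteome, fx.annotations, dihedrals=None, orthologs=None)
        assert all(not r.final_pass for r in recs)

    def test_fail_open_passes_missing_data(self, screen_fixture):
        fx = screen_fixture
        cfg = ScreenConfig(fail_open=True)
        recs = run_screen(fx.proteome, fx.annotations, dihedrals=None, orthologs=None, config=cfg)
        cyto = sum(bool(fx.truth.proteins[r.protein_id]["cytoplasmic"]) for r in recs)
        assert sum(r.final_pass for r in recs) == cyto

    def test_screen_table_columns(self, screen_fixture):
        fx = screen_fixture
        df = screen_table(run_screen(fx.proteome, fx.annotations, fx.dihedrals, fx.orthologs))
        assert list(df.columns)[:2] == ["protein_id", "n_matches"]
        assert df["final"].sum() == 5

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown filters"):
            ScreenConfig(enabled=frozenset({"motif", "phase"}))


def exact_upper_tail(N, K, n, k) -> float:
    """Independent enumeration of P[X >= k] for a hypergeometric draw."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1)) / total


class TestHypergeomEnrich:
    def test_worked_example(self):
        universe = [f"u{i}" for i in range(100)]
        selected = universe[:10]
        term_map = {"T": universe[:5] + universe[50:55]}  # K=10, k=5
        (r,) = hypergeom_enrich(selected, universe, term_map)
        assert r.k == 5 and r.K == 10 and r.n == 10 and r.N == 100
        assert r.enrichment_factor == pytest.approx(5.0)
        assert r.p_value == pytest.approx(exact_upper_tail(100, 10, 10, 5), rel=1e-9)
        assert r.passes_thresholds

    def test_exact_enumeration_grid(self):
        """p matches brute-force tail sums across an exhaustive small grid."""
        universe = [f"u{i}" for i in range(60)]
        for N in (10, 25, 40, 60):
            u = universe[:N]
            for K in (1, 3, N // 2, N):
                for n in (1, 5, N // 3 or 1):
                    for k in range(0, min(n, K) + 1):
                        # construct sets realizing (N, K, n, k)
                        if k > n or K - k > N - n:
                            continue
                        term = u[:k] + u[n : n + (K - k)]
                        if len(term) != K:
                            continue
                        (r,) = hypergeom_enrich(u[:n], u, {"T": term})
                        assert r.k == k
                        assert r.p_value == pytest.approx(
                            exact_upper_tail(N, K, n, k), rel=1e-9, abs=1e-12
                        ), (N, K, n, k)

    def test_degenerate_all_selected_all_term(self):
        u = [f"u{i}" for i in range(8)]
        (r,) = hypergeom_enrich(u, u, {"T": u})
        assert r.p_value == pytest.approx(1.0)
        assert r.enrichment_factor == pytest.approx(1.0)
        assert not r.passes_thresholds

    def test_minimum_count_threshold_blocks_small_k(self):
        # k = 2 with tiny p and large factor still fails on count >= 3.
        universe = [f"u{i}" for i in range(1000)]
        selected = universe[:2]
        (r,) = hypergeom_enrich(selected, universe, {"T": universe[:2]})
        assert r.p_value < 0.01 and r.enrichment_factor > 1.5
        assert not r.passes_thresholds

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            hypergeom_enrich(["a"], ["b"], {"T": ["b"]})

    def test_zero_membership_terms_skipped(self):
        u = [f"u{i}" for i in range(10)]
        assert hypergeom_enrich(u[:3], u, {"T": []}) == []

    def test_bh_q_values_monotone_in_p_rank(self):
        rng = np.random.default_rng(4)
        u = [f"u{i}" for i in range(200)]
        term_map = {
            f"T{j}": list(rng.choice(u, size=rng.integers(5, 60), replace=False))
            for j in range(25)
        }
        res = hypergeom_enrich(u[:30], u, term_map)
        ordered = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestEnrichmentSimulations:
    def test_planted_term_flagged_in_most_replicates(self):
        proteome, truth = synthetic.gen_proteome(
            n_proteins=200, length=150, motif_spec={"PX_PLUS_P": 30}, seed=3
        )
        universe = [s.id for s in proteome]
        selected = [
            pid for pid, i in truth.proteins.items()
            if any(m["class"] == "PX_PLUS_P" for m in i["matches"])
        ]
        hits = 0
        null_pass = null_total = 0
        for rep in range(100):
            ann = synthetic.gen_annotations(
                truth, seed=1000 + rep, enriched_terms={"T_ENR": 5.0}, n_null_terms=5
            )
            term_map: dict[str, set] = {}
            for _, row in ann.iterrows():
                for t in str(row["terms"]).split("|"):
                    if t:
                        term_map.setdefault(t, set()).add(row["protein_id"])
            for r in hypergeom_enrich(selected, universe, term_map):
                if r.term == "T_ENR":
                    hits += r.passes_thresholds
                else:
                    null_total += 1
                    null_pass += r.passes_thresholds
        assert hits >= 95
        assert null_pass / null_total <= 0.02


class TestNetwork:
    def test_three_ags_two_prms_each(self):
        node_classes = {f"ags{i}": "AGS" for i in range(3)}
        node_classes.update({f"prm{i}": "PRM" for i in range(6)})
        edges = [(f"ags{i}", f"prm{2 * i + j}") for i in range(3) for j in range(2)]
        summary = build_network(edges, node_classes)
        assert summary["cross_class_edges"] == 6
        assert summary["n_components"] == 3

    def test_shared_targets_merge_components(self):
        node_classes = {"a1": "AGS", "a2": "AGS", "p1": "PRM"}
        summary = build_network([("a1", "p1"), ("a2", "p1")], node_classes)
        assert summary["n_components"] == 1
        assert summary["degree"]["p1"] == 2

    def test_empty_edge_list_gives_singletons(self):
        node_classes = {f"n{i}": "AGS" for i in range(5)}
        summary = build_network([], node_classes)
        assert summary["n_components"] == 5
        assert all(len(c) == 1 for c in summary["components"])

    def test_component_count_matches_union_find_oracle(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{i}" for i in range(40)]
        node_classes = {n: ("AGS" if i % 2 else "PRM") for i, n in enumerate(nodes)}
        edges = [
            tuple(rng.choice(nodes, size=2, replace=False)) for _ in range(30)
        ]
        summary = build_network(edges, node_classes)

        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        assert summary["n_components"] == len({find(n) for n in nodes})

    def test_unknown_nodes_rejected_with_offenders(self):
        with pytest.raises(ValueError, match="ghost"):
            build_network([("a", "ghost")], {"a": "AGS"})
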