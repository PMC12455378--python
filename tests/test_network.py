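"""Patient-sharing graph construction, modularity, Louvain, summaries."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salpnet.config import SyntheticConfig
from salpnet.network import (
    build_networks,
    build_sharing_links,
    cap_patient_links,
    louvain_partition,
    modularity,
    project_physician_graph,
    summarize_networks,
)
from salpnet.synthetic import generate_roster, simulate_sharing_claims


def claims_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "enrollee_id",
            "physician_id",
            "specialty",
            "service_date",
            "setting",
            "code_system",
            "code",
            "hrr_id",
        ],
    )


def visit(e, p, date, specialty="obgyn", hrr="HRR00"):
    return (e, p, specialty, date, "outpatient", "CPT", "99213", hrr)


class TestLinks:
    def test_interaction_days_count_distinct_dates(self):
        claims = claims_frame(
            [
                visit("E1", "P1", "2018-01-01"),
                visit("E1", "P1", "2018-01-01"),
                visit("E1", "P1", "2018-03-01"),
            ]
        )
        links = build_sharing_links(claims)
        assert links.iloc[0]["interaction_days"] == 2

    def test_other_specialty_never_links(self):
        claims = claims_frame([visit("E1", "P1", "2018-01-01", specialty="other")])
        assert build_sharing_links(claims).empty

    def test_empty_claims_empty_links(self):
        assert build_sharing_links(claims_frame([])).empty


class TestCap:
    def _links(self, n_phys, days=None):
        days = days or {}
        return pd.DataFrame(
            {
                "enrollee_id": "E1",
                "physician_id": [f"P{i}" for i in range(n_phys)],
                "interaction_days": [days.get(i, n_phys - i) for i in range(n_phys)],
            }
        )

    def test_ten_physicians_top_eight_kept(self):
        capped = cap_patient_links(self._links(10), cap=8)
        assert len(capped) == 8
        assert set(capped["physician_id"]) == {f"P{i}" for i in range(8)}

    def test_at_cap_unchanged(self):
        capped = cap_patient_links(self._links(8), cap=8)
        assert len(capped) == 8

    def test_all_tied_lowest_ids_kept(self):
        links = self._links(9, days={i: 3 for i in range(9)})
        capped = cap_patient_links(links, cap=8)
        assert set(capped["physician_id"]) == {f"P{i}" for i in range(8)}

    def test_cap_below_one_rejected(self):
        with pytest.raises(ValueError):
            cap_patient_links(self._links(3), cap=0)


class TestProjection:
    def _capped(self, pairs):
        return pd.DataFrame(
            [
                {"enrollee_id": e, "physician_id": p, "interaction_days": 1}
                for e, p in pairs
            ]
        )

    def test_shared_two_patients_edge_weight_two(self):
        pairs = [(f"E{i}", p) for i in range(4) for p in ("A", "B")]
        hrr = {"A": "H1", "B": "H1"}
        G = project_physician_graph(self._capped(pairs), hrr)["H1"]
        assert G["A"]["B"]["weight"] == 4

    def test_single_shared_patient_no_edge(self):
        pairs = [("E1", "A"), ("E1", "B")] + [
            (f"E{i}", p) for i in range(2, 6) for p in ("A", "B")
        ]
        # A,B share E1..E5 -> edge; C shares only E1 with them and has 4 own patients
        pairs += [("E1", "C"), ("F1", "C"), ("F2", "C"), ("F3", "C")]
        hrr = {"A": "H1", "B": "H1", "C": "H1"}
        G = project_physician_graph(self._capped(pairs), hrr)["H1"]
        assert G.has_edge("A", "B")
        assert not G.has_edge("A", "C") and not G.has_edge("B", "C")

    def test_three_patient_physician_not_a_node(self):
        pairs = [(f"E{i}", "A") for i in range(3)]
        pairs += [(f"E{i}", "B") for i in range(4)]
        hrr = {"A": "H1", "B": "H1"}
        G = project_physician_graph(self._capped(pairs), hrr)["H1"]
        assert "A" not in G and "B" in G

    def test_graphs_split_by_hrr(self):
        pairs = [(f"E{i}", p) for i in range(4) for p in ("A", "B")]
        hrr = {"A": "H1", "B": "H2"}
        graphs = project_physician_graph(self._capped(pairs), hrr)
        assert set(graphs) == {"H1", "H2"}
        assert graphs["H1"].number_of_edges() == 0


def two_triangles():
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return G


class TestModularity:
    def test_two_disjoint_triangles_half(self):
        part = {0: "a", 1: "a", 2: "a", 3: "b", 4: "b", 5: "b"}
        assert abs(modularity(two_triangles(), part) - 0.5) < 1e-12

    def test_complete_graph_one_community_zero(self):
        G = nx.complete_graph(5)
        assert abs(modularity(G, {n: 0 for n in G})) < 1e-12

    def test_triangle_singletons_minus_third(self):
        G = nx.complete_graph(3)
        assert abs(modularity(G, {n: n for n in G}) + 1.0 / 3.0) < 1e-12

    def test_agrees_with_networkx_on_weighted_random_graph(self):
        rng = np.random.default_rng(4)
        G = nx.gnm_random_graph(12, 30, seed=2)
        for _, _, d in G.edges(data=True):
            d["weight"] = float(rng.integers(1, 6))
        part = {n: n % 3 for n in G}
        groups = [{n for n in G if n % 3 == i} for i in range(3)]
        mine = modularity(G, part)
        ref = nx.community.modularity(G, groups, weight="weight")
        assert abs(mine - ref) < 1e-12

    def test_uncovered_node_rejected(self):
        with pytest.raises(ValueError):
            modularity(two_triangles(), {0: "a"})

    def test_edgeless_zero_with_warning(self):
        G = nx.empty_graph(3)
        with pytest.warns(UserWarning):
            assert modularity(G, {n: n for n in G}) == 0.0


class TestLouvain:
    @pytest.mark.parametrize("seed", [1, 7, 99])
    def test_two_triangles_recovered(self, seed):
        part = louvain_partition(two_triangles(), seed=seed)
        assert {frozenset(n for n in part if part[n] == c) for c in set(part.values())} == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        }

    def test_edgeless_graph_all_singletons(self):
        G = nx.empty_graph(6)
        part = louvain_partition(G, seed=1)
        assert len(set(part.values())) == 6

    def test_barbell_k5s_recovered(self):
        G = nx.barbell_graph(5, 0)
        part = louvain_partition(G, seed=1)
        groups = {
            frozenset(n for n in part if part[n] == c) for c in set(part.values())
        }
        assert groups == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_partition(nx.Graph(), seed=1)

    def test_partition_quality_vs_brute_force_small_graphs(self):
        """Louvain reaches >= 95% of exhaustive-max modularity (spot sample)."""
        for nx_seed in (10, 20, 30):
            G = nx.connected_watts_strogatz_graph(7, 3, 0.4, seed=nx_seed)
            best = max(
                nx.community.modularity(G, p) for p in _partitions(list(G.nodes()))
            )
            q = modularity(G, louvain_partition(G, seed=1), weighted=False)
            assert q >= 0.95 * best - 1e-12

    def test_relabeling_nodes_preserves_grouping(self):
        G = two_triangles()
        part = louvain_partition(G, seed=5)
        mapping = {n: f"X{9 - n}" for n in G}
        H = nx.relabel_nodes(G, mapping)
        part_h = louvain_partition(H, seed=5)
        groups = lambda p: {
            frozenset(k for k in p if p[k] == c) for c in set(p.values())
        }
        assert groups(part_h) == {
            frozenset(mapping[n] for n in g) for g in groups(part)
        }


def _partitions(nodes):
    if not nodes:
        yield []
        return
    first = nodes[0]
    for rest in _partitions(nodes[1:]):
        for i, block in enumerate(rest):
            yield rest[:i] + [block | {first}] + rest[i + 1 :]
        yield [{first}] + rest


class TestSummaries:
    def test_density_examples(self):
        G = nx.Graph(hrr_id="H1")
        G.add_edges_from([(0, 1), (1, 2), (0, 2)])  # triangle
        G.add_edges_from([(3, 4), (4, 5), (5, 6)])  # 4-node path
        G.add_node(7)  # singleton
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 1, 7: 2}
        t1 = pd.DataFrame({"surgeon_id": [0, 1, 3, 4]})
        summary = summarize_networks({"H1": part}, {"H1": G}, t1).set_index("network_id")
        assert summary.loc["H1-N000", "density"] == 1.0
        assert summary.loc["H1-N001", "density"] == 0.5
        assert np.isnan(summary.loc["H1-N002", "density"])
        assert summary.loc["H1-N000", "n_sterilizing_physicians"] == 2

    def test_sterilization_volume_summed(self):
        G = nx.complete_graph(3)
        part = {n: 0 for n in G}
        t1 = pd.DataFrame({"surgeon_id": [0, 0, 0, 1, 1]})
        summary = summarize_networks({"H": part}, {"H": G}, t1)
        assert summary.iloc[0]["n_eligible_sterilizations"] == 5


class TestThresholdProperties:
    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_claim_sets_respect_all_rules(self, seed):
        """No graph from random claims breaks the cap/node/edge thresholds."""
        rng = np.random.default_rng(seed)
        n_pat = int(rng.integers(5, 40))
        n_doc = int(rng.integers(3, 15))
        rows = []
        for i in range(n_pat):
            for _ in range(int(rng.integers(0, 12))):
                rows.append(
                    visit(
                        f"E{i}",
                        f"P{rng.integers(n_doc)}",
                        f"2018-0{rng.integers(1, 10)}-0{rng.integers(1, 10)}",
                        hrr=f"H{rng.integers(2)}",
                    )
                )
        claims = claims_frame(rows)
        links = build_sharing_links(claims)
        capped = cap_patient_links(links, cap=8)
        if capped.empty:
            return
        assert capped.groupby("enrollee_id").size().max() <= 8
        from salpnet.network import physician_hrr

        graphs = project_physician_graph(capped, physician_hrr(claims))
        pat_of = capped.groupby("physician_id")["enrollee_id"].agg(set)
        for G in graphs.values():
            for a, b, d in G.edges(data=True):
                assert d["weight"] >= 2
                assert len(pat_of[a] & pat_of[b]) == d["weight"]
            for n in G.nodes:
                assert len(pat_of[n]) >= 4


class TestPlantedRecovery:
    def test_block_model_communities_recovered(self):
        cfg = SyntheticConfig(
            n_hrrs=2, communities_per_hrr=3, p_within=0.9, p_between=0.05, seed=99
        )
        roster = generate_roster(cfg)
        claims, _, _ = simulate_sharing_claims(cfg, roster)
        net = build_networks(claims, cfg.t1_span, seed=1)
        from sklearn.metrics import adjusted_rand_score

        truth = roster.set_index("physician_id")["community_id"]
        mem = net.membership
        ari = adjusted_rand_score(
            truth.loc[mem["physician_id"]].to_numpy(), mem["network_id"].to_numpy()
        )
        assert ari >= 0.9
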