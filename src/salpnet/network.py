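"""Physician patient-sharing networks: links, projection, communities.

From baseline-era claims of the patient-sharing sample we build, per
hospital referral region (HRR):

1. patient-physician links, weighted by interaction-days (distinct service
   dates), restricted to the included specialties (OB/GYN, urology,
   primary care),
2. a per-patient cap keeping each patient's top-``cap`` physicians by
   interaction-days (ties broken by ascending physician id),
3. a physician co-patient projection: nodes are physicians billing at
   least ``min_patients`` distinct patients, edges join pairs sharing at
   least ``min_shared`` patients, with the shared-patient count as weight,
4. a Louvain modularity partition into non-overlapping communities
   ("networks"), detected within each HRR and never across.

Capping is applied before the node/edge thresholds.  Modularity uses edge
weights by default (an unweighted mode is available behind a flag).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkSummary",
    "build_sharing_links",
    "cap_patient_links",
    "project_physician_graph",
    "modularity",
    "louvain_partition",
    "summarize_networks",
    "build_networks",
]

INCLUDED_SPECIALTIES = {"obgyn", "urology", "primary_care"}


def build_sharing_links(
    claims: pd.DataFrame,
    t1_window=None,
    sample_enrollees: set[str] | None = None,
) -> pd.DataFrame:
    """Patient-physician links with interaction-day weights.

    One row per (enrollee, physician) pair having at least one claim from
    an included specialty; ``interaction_days`` counts distinct service
    dates.  Optionally restricts to a date window and to the
    patient-sharing sample members.
    """
    df = claims[claims["specialty"].isin(INCLUDED_SPECIALTIES)]
    if t1_window is not None:
        d = pd.to_datetime(df["service_date"]).dt.date
        df = df.loc[(d >= t1_window[0]) & (d < t1_window[1])]
    if sample_enrollees is not None:
        df = df[df["enrollee_id"].isin(sample_enrollees)]
    if df.empty:
        return pd.DataFrame(columns=["enrollee_id", "physician_id", "interaction_days"])
    links = (
        df.groupby(["enrollee_id", "physician_id"])["service_date"]
        .nunique()
        .rename("interaction_days")
        .reset_index()
    )
    return links


def cap_patient_links(links: pd.DataFrame, cap: int = 8) -> pd.DataFrame:
    """Keep each patient's top-``cap`` physicians by interaction-days.

    Ties are broken by ascending physician id, so the result is unique.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    ordered = links.sort_values(
        ["enrollee_id", "interaction_days", "physician_id"],
        ascending=[True, False, True],
    )
    return (
        ordered.groupby("enrollee_id", sort=True)
        .head(cap)
        .reset_index(drop=True)
    )


def physician_hrr(claims: pd.DataFrame) -> pd.Series:
    """Physician -> HRR by plurality of claim lines; ties to lowest HRR id."""
    counts = (
        claims.groupby(["physician_id", "hrr_id"])
        .size()
        .rename("n")
        .reset_index()
        .sort_values(["physician_id", "n", "hrr_id"], ascending=[True, False, True])
    )
    multi = counts.groupby("physician_id")["hrr_id"].nunique()
    n_multi = int((multi > 1).sum())
    if n_multi:
        warnings.warn(f"{n_multi} physicians bill in multiple HRRs; plurality rule applied")
    return counts.groupby("physician_id")["hrr_id"].first()


def project_physician_graph(
    capped_links: pd.DataFrame,
    hrr_of: pd.Series | dict,
    min_patients: int = 4,
    min_shared: int = 2,
) -> dict[str, nx.Graph]:
    """Weighted physician co-patient graph per HRR.

    Nodes: physicians with >= ``min_patients`` distinct patients after
    capping.  Edge (A, B) iff they share >= ``min_shared`` patients;
    weight = shared-patient count.  Built independently per HRR.
    """
    hrr_of = dict(hrr_of)
    links = capped_links.copy()
    links["hrr_id"] = links["physician_id"].map(hrr_of)
    graphs: dict[str, nx.Graph] = {}
    for hrr, sub in links.groupby("hrr_id"):
        pat_count = sub.groupby("physician_id")["enrollee_id"].nunique()
        nodes = set(pat_count[pat_count >= min_patients].index)
        sub = sub[sub["physician_id"].isin(nodes)]
        G = nx.Graph(hrr_id=hrr)
        G.add_nodes_from(sorted(nodes))
        patients_of = sub.groupby("physician_id")["enrollee_id"].agg(set).to_dict()
        # invert: only physician pairs co-billing some patient can have an edge
        by_patient: dict[str, list[str]] = {}
        for doc, pats in patients_of.items():
            for p in pats:
                by_patient.setdefault(p, []).append(doc)
        weights: dict[tuple[str, str], int] = {}
        for docs in by_patient.values():
            for a, b in itertools.combinations(sorted(docs), 2):
                weights[(a, b)] = weights.get((a, b), 0) + 1
        for (a, b), w in sorted(weights.items()):
            if w >= min_shared:
                G.add_edge(a, b, weight=w)
        # contract assertions
        assert all(d["weight"] >= min_shared for _, _, d in G.edges(data=True))
        assert all(len(patients_of.get(n, ())) >= min_patients for n in G.nodes)
        graphs[hrr] = G
    return graphs


def modularity(
    graph: nx.Graph, partition: dict[str, object], weighted: bool = True
) -> float:
    """Newman modularity Q of a node -> community partition.

    Q = sum_c [ W_c/W - (S_c / 2W)^2 ] with W the total edge weight, W_c
    the intra-community weight and S_c the community's weighted degree
    sum.  Empty or edgeless graphs return 0 by convention.
    """
    missing = set(graph.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    if graph.number_of_edges() == 0:
        warnings.warn("modularity of an edgeless graph is 0 by convention")
        return 0.0
    wkey = "weight" if weighted else None
    W = graph.size(weight=wkey)
    intra: dict = {}
    degree: dict = {}
    for node, deg in graph.degree(weight=wkey):
        degree[partition[node]] = degree.get(partition[node], 0.0) + deg
    for a, b, d in graph.edges(data=True):
        if partition[a] == partition[b]:
            w = d.get("weight", 1.0) if weighted else 1.0
            intra[partition[a]] = intra.get(partition[a], 0.0) + w
    q = 0.0
    for c in degree:
        q += intra.get(c, 0.0) / W - (degree[c] / (2.0 * W)) ** 2
    return q


def louvain_partition(
    graph: nx.Graph,
    seed: int = 1,
    resolution: float = 1.0,
    weighted: bool = True,
) -> dict[str, int]:
    """Louvain community assignment (node -> community index).

    Two-phase modularity optimization with the node sweep order shuffled
    by ``seed``; communities are non-overlapping and exhaustive.  Labels
    are arbitrary but deterministic for a given seed: communities are
    numbered by their smallest member node.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    comms = nx.community.louvain_communities(
        graph,
        weight="weight" if weighted else None,
        resolution=resolution,
        seed=seed,
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: str(c[0]))
    return {node: i for i, members in enumerate(comms) for node in members}


@dataclass
class NetworkSummary:
    hrr_id: str
    network_id: str
    n_physicians: int
    n_sterilizing_physicians: int
    n_eligible_sterilizations: int
    density: float  # NaN when the community has < 2 nodes

    @staticmethod
    def frame(rows: list["NetworkSummary"]) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in rows])


def summarize_networks(
    partitions: dict[str, dict],
    graphs: dict[str, nx.Graph],
    t1_sterilizations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-community size, sterilizing-surgeon count, volume, and density.

    Density is realized edges over possible edges within the community's
    induced subgraph; undefined (NaN) for singleton communities.
    ``t1_sterilizations`` needs columns surgeon_id (one row per eligible
    baseline sterilization).
    """
    vol = t1_sterilizations.groupby("surgeon_id").size()
    rows = []
    for hrr, part in sorted(partitions.items()):
        G = graphs[hrr]
        members: dict[int, list] = {}
        for node, c in part.items():
            members.setdefault(c, []).append(node)
        for c, nodes in sorted(members.items()):
            sub = G.subgraph(nodes)
            n = len(nodes)
            dens = (
                2.0 * sub.number_of_edges() / (n * (n - 1)) if n >= 2 else float("nan")
            )
            sterilizers = [p for p in nodes if p in vol.index]
            rows.append(
                NetworkSummary(
                    hrr_id=hrr,
                    network_id=f"{hrr}-N{c:03d}",
                    n_physicians=n,
                    n_sterilizing_physicians=len(sterilizers),
                    n_eligible_sterilizations=int(vol.loc[sterilizers].sum()),
                    density=dens,
                )
            )
    return NetworkSummary.frame(rows)


@dataclass
class NetworkBuild:
    links: pd.DataFrame
    capped: pd.DataFrame
    graphs: dict[str, nx.Graph]
    partitions: dict[str, dict]
    membership: pd.DataFrame  # physician_id, hrr_id, network_id
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_networks(
    claims: pd.DataFrame,
    t1_window,
    sample_enrollees: set[str] | None = None,
    cap: int = 8,
    min_patients: int = 4,
    min_shared: int = 2,
    seed: int = 1,
    resolution: float = 1.0,
    weighted: bool = True,
) -> NetworkBuild:
    """Links -> cap -> projection -> Louvain, end to end."""
    links = build_sharing_links(claims, t1_window, sample_enrollees)
    capped = cap_patient_links(links, cap=cap)
    hrr_of = physician_hrr(claims)
    graphs = project_physician_graph(capped, hrr_of, min_patients, min_shared)
    partitions = {}
    member_rows = []
    for hrr, G in sorted(graphs.items()):
        if G.number_of_nodes() == 0:
            partitions[hrr] = {}
            continue
        part = louvain_partition(G, seed=seed, resolution=resolution, weighted=weighted)
        partitions[hrr] = part
        for node, c in sorted(part.items()):
            member_rows.append(
                {"physician_id": node, "hrr_id": hrr, "network_id": f"{hrr}-N{c:03d}"}
            )
    membership = pd.DataFrame(member_rows, columns=["physician_id", "hrr_id", "network_id"])
    return NetworkBuild(
        links=links, capped=capped, graphs=graphs, partitions=partitions, membership=membership
    )


def export_graphs(build: NetworkBuild, outdir) -> dict[str, object]:
    """Edge-list CSV and GraphML export for visualization."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_rows = []
    paths = {}
    for hrr, G in sorted(build.graphs.items()):
        for a, b, d in G.edges(data=True):
            edge_rows.append(
                {"physician_a": a, "physician_b": b, "weight": d["weight"], "hrr_id": hrr}
            )
        gml = outdir / f"network_{hrr}.graphml"
        nx.write_graphml(G, gml)
        paths[f"graphml_{hrr}"] = gml
    edges = pd.DataFrame(edge_rows, columns=["physician_a", "physician_b", "weight", "hrr_id"])
    paths["edges"] = outdir / "edges.csv"
    edges.to_csv(paths["edges"], index=False)
    paths["membership"] = outdir / "membership.csv"
    build.membership.to_csv(paths["membership"], index=False)
    return paths
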