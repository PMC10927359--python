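"""Phosphosignaling network assembly from kinase-substrate interactions.

The background graph is directed kinase -> substrate-kinase phosphorylation,
read from a PhosphoSitePlus Kinase_Substrate_Dataset flat file, restricted
to one organism and to substrates that are themselves protein kinases, and
deduplicated across phosphosites. A neuron's local network is the union of
ALL shortest directed paths between every ORDERED pair of its member
kinases; kinases that appear only inside such paths are "inferred"
intermediates. Neurons whose members admit no path at all (a single kinase
without autophosphorylation, or mutually unreachable members) yield no
network.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources as _resources

import networkx as nx
import pandas as pd

logger = logging.getLogger("treking.netgen")

PSP_KINASE_COL = "GENE"
PSP_SUBSTRATE_COL = "SUB_GENE"
PSP_KIN_ORG_COL = "KIN_ORGANISM"
PSP_SUB_ORG_COL = "SUB_ORGANISM"


def packaged_kinome() -> list[str]:
    """Editable starter list of human protein-kinase gene symbols.

    Used only for the kinase-kinase substrate filter; replace with a full
    kinome list (~518 genes) for production analyses.
    """
    text = (_resources.files("treking") / "resources" / "human_kinome.txt").read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


@dataclass
class BackgroundNetwork:
    """Directed, deduplicated kinase -> kinase phosphorylation graph."""

    graph: nx.DiGraph
    organism: str = "human"
    provenance: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class LocalNetwork:
    """Union of shortest paths between a neuron's member kinases.

    Node roles: "predicted" for neuron members, "inferred" for kinases that
    lie strictly inside an included path.
    """

    graph: nx.DiGraph
    members: set[str]
    neuron_ids: list = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    unreachable_pairs: int = 0
    functionality: dict[str, list[int]] = field(default_factory=dict)
    sign: int | None = None

    @property
    def inferred(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("role") == "inferred"}


# ---------------------------------------------------------------------------
# Background-network loading (PhosphoSitePlus flat-file dialect)
# ---------------------------------------------------------------------------

def load_kinase_substrate(
    path,
    organism: str = "human",
    kinome: list[str] | None = None,
) -> BackgroundNetwork:
    """Load the kinase-substrate table and build the kinase-kinase graph.

    The flat file has preamble lines before a tab-separated header with
    kinase/substrate gene columns and organism columns (gzip accepted).
    Rows are kept when both organisms match ``organism`` and the substrate
    gene is in the kinome list; one edge per (kinase, substrate) regardless
    of how many phosphosites support it. Autophosphorylation rows become
    self-loops.
    """
    kinome = packaged_kinome() if kinome is None else list(kinome)
    kinome_set = set(kinome)

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = fh.read().splitlines()
    # skip preamble: the header is the first line containing the kinase column
    header_i = next(
        (i for i, ln in enumerate(lines)
         if PSP_KINASE_COL in ln.split("\t") and PSP_SUBSTRATE_COL in ln.split("\t")),
        None,
    )
    if header_i is None:
        raise ValueError(
            f"not a kinase-substrate flat file: no header with "
            f"{PSP_KINASE_COL!r} and {PSP_SUBSTRATE_COL!r} columns")
    header = lines[header_i].split("\t")
    for col in (PSP_KINASE_COL, PSP_SUBSTRATE_COL, PSP_KIN_ORG_COL, PSP_SUB_ORG_COL):
        if col not in header:
            raise ValueError(f"kinase-substrate file missing column {col!r}")
    rows = list(csv.DictReader(lines[header_i:], delimiter="\t"))

    n_total = len(rows)
    org = organism.lower()
    G = nx.DiGraph()
    kept = 0
    for r in rows:
        if (r[PSP_KIN_ORG_COL] or "").lower() != org:
            continue
        if (r[PSP_SUB_ORG_COL] or "").lower() != org:
            continue
        k, s = r[PSP_KINASE_COL], r[PSP_SUBSTRATE_COL]
        if s not in kinome_set:
            continue
        kept += 1
        G.add_edge(k, s)
    if G.number_of_edges() == 0:
        logger.warning("empty kinase-kinase network after organism/kinome filters")
    return BackgroundNetwork(
        graph=G, organism=organism,
        provenance={
            "source": str(path), "rows_total": n_total,
            "rows_kept": kept, "edges": G.number_of_edges(),
        },
    )


def write_background(net: BackgroundNetwork, path) -> None:
    """Write the graph back out in the flat-file dialect (one site per edge)."""
    with open(path, "w") as fh:
        fh.write("Kinase-substrate interactions\n\n")
        fh.write("\t".join([PSP_KINASE_COL, PSP_KIN_ORG_COL,
                            PSP_SUBSTRATE_COL, PSP_SUB_ORG_COL]) + "\n")
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\t{net.organism}\t{v}\t{net.organism}\n")


def apply_synonyms(members: set[str], synonyms: dict[str, str]) -> set[str]:
    """Map panel kinase names into the background namespace."""
    return {synonyms.get(m, m) for m in members}


def read_synonym_table(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"panel_name", "network_name"} <= set(df.columns):
        raise ValueError("synonym CSV needs panel_name and network_name columns")
    return dict(zip(df["panel_name"], df["network_name"]))


# ---------------------------------------------------------------------------
# Local networks
# ---------------------------------------------------------------------------

def build_local_network(
    members: set[str],
    background: BackgroundNetwork,
    neuron_ids: list | None = None,
    mode: str = "all_shortest_paths",
) -> LocalNetwork | None:
    """Union of shortest paths between every ordered member pair.

    For each ordered pair (a, b), a != b, with b reachable from a, every
    shortest directed path is included (mode="single_shortest_path" keeps
    one arbitrary path per pair). A singleton member contributes its
    self-loop if it autophosphorylates. Returns None when the combined edge
    set is empty — a single kinase without self-phosphorylation or multiple
    unconnected kinases yield no network.
    """
    if not members:
        raise ValueError("members must be nonempty")
    G = background.graph
    mapped = sorted(m for m in members if m in G)
    unmapped = sorted(m for m in members if m not in G)
    if unmapped:
        logger.info("members not in background network, skipped: %s",
                    ", ".join(unmapped))

    L = nx.DiGraph()
    unreachable = 0
    for a in mapped:
        for b in mapped:
            if a == b:
                continue
            try:
                if mode == "all_shortest_paths":
                    paths = nx.all_shortest_paths(G, a, b)
                else:
                    paths = [nx.shortest_path(G, a, b)]
                for p in paths:
                    L.add_edges_from(zip(p, p[1:]))
            except nx.NetworkXNoPath:
                unreachable += 1
    # a singleton member forms a network only through autophosphorylation
    if len(mapped) == 1 and G.has_edge(mapped[0], mapped[0]):
        L.add_edge(mapped[0], mapped[0])
    if L.number_of_edges() == 0:
        return None
    member_set = set(members)
    for n in L.nodes:
        L.nodes[n]["role"] = "predicted" if n in member_set else "inferred"
    return LocalNetwork(
        graph=L, members=member_set, neuron_ids=neuron_ids or [],
        unmapped=unmapped, unreachable_pairs=unreachable,
    )


def composite_network(
    neuron_ids: list,
    assignment,
    background: BackgroundNetwork,
    mode: str = "all_shortest_paths",
) -> LocalNetwork | None:
    """Pool several neurons' members and build one local network."""
    pooled: set[str] = set()
    for nid in neuron_ids:
        pooled.update(assignment.members.get(tuple(nid), []))
    if not pooled:
        raise ValueError("all requested neurons are empty")
    return build_local_network(pooled, background, neuron_ids=list(neuron_ids),
                               mode=mode)


def annotate_functionality(
    L: LocalNetwork, matrix, phase: tuple[int, int] | None = None
) -> LocalNetwork:
    """Copy per-node functionality rows (optionally a phase slice) onto L."""
    calls = matrix.calls
    if phase is not None:
        calls = calls.iloc[:, phase[0]: phase[1] + 1]
    for n in L.graph.nodes:
        if n in calls.index:
            row = [int(v) for v in calls.loc[n]]
            L.functionality[n] = row
            L.graph.nodes[n]["functionality"] = _node_class(row)
    signs = {s for r in L.functionality.values() for s in r if s != 0}
    L.sign = (0 if signs == {-1, 1} else (1 if signs == {1} else
              (-1 if signs == {-1} else None)))
    return L


def _node_class(row: list[int]) -> str:
    has_neg, has_pos = -1 in row, 1 in row
    if has_neg and has_pos:
        return "both"
    if has_neg:
        return "weakening"
    if has_pos:
        return "strengthening"
    return "unclassified"


def network_stats(L: LocalNetwork) -> dict[str, int]:
    """Size and diameter-style statistics of a local network.

    max_path_nodes counts KINASES on the longest shortest path over ordered
    reachable node pairs: a direct edge scores 2, a lone self-loop node 1.
    """
    if L is None or L.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    G = L.graph
    best = 1  # a single (self-loop) node scores 1 by convention
    lengths = dict(nx.all_pairs_shortest_path_length(G))
    for a, targets in lengths.items():
        for b, hops in targets.items():
            if a != b:
                best = max(best, hops + 1)
    return {
        "max_path_nodes": best,
        "nodes": G.number_of_nodes(),
        "edges": G.number_of_edges(),
        "inferred": len(L.inferred),
    }


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(L: LocalNetwork, path, fmt: str = "graphml") -> None:
    """Serialize a local network with role/functionality node attributes.

    Formats: "sif" (relation "phosphorylates"), "graphml", "csv"
    (edge list + <path>.nodes.csv attribute sidecar).
    """
    G = L.graph
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(G.edges):
                fh.write(f"{u}\tphosphorylates\t{v}\n")
    elif fmt == "graphml":
        H = nx.DiGraph()
        for n in sorted(G.nodes):
            d = G.nodes[n]
            H.add_node(n, role=d.get("role", ""),
                       functionality=d.get("functionality", ""))
        H.add_edges_from(sorted(G.edges))
        nx.write_graphml(H, path)
    elif fmt == "csv":
        pd.DataFrame(sorted(G.edges), columns=["kinase", "substrate"]).to_csv(
            path, index=False)
        side = pd.DataFrame(
            [(n, G.nodes[n].get("role", ""), G.nodes[n].get("functionality", ""))
             for n in sorted(G.nodes)],
            columns=["node", "role", "functionality"],
        )
        side.to_csv(str(path) + ".nodes.csv", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path, fmt: str = "graphml") -> nx.DiGraph:
    if fmt == "sif":
        G = nx.DiGraph()
        with open(path) as fh:
            for line in fh:
                parts = line.split("\t")
                if len(parts) == 3:
                    G.add_edge(parts[0].strip(), parts[2].strip())
        return G
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        G = nx.DiGraph()
        G.add_edges_from(df.itertuples(index=False, name=None))
        try:
            side = pd.read_csv(str(path) + ".nodes.csv").fillna("")
            for _, r in side.iterrows():
                if r["node"] in G:
                    G.nodes[r["node"]]["role"] = r["role"]
                    G.nodes[r["node"]]["functionality"] = r["functionality"]
        except FileNotFoundError:
            pass
        return G
    raise ValueError(f"unknown import format {fmt!r}")


# ---------------------------------------------------------------------------
# Background overlay
# ---------------------------------------------------------------------------

def overlay_background(
    background: BackgroundNetwork,
    matrices: dict[str, "pd.DataFrame | object"],
    networks: list[LocalNetwork],
    phase: tuple[int, int],
) -> nx.DiGraph:
    """Annotate the background graph with phase-restricted functionality.

    Node class (weakening / strengthening / both) comes from the matrices'
    entries inside the phase; edge class from the signs of the neuron
    networks an edge appears in (an edge present in both a weakening and a
    strengthening network is "both"). Unannotated background nodes and edges
    stay as context.
    """
    H = background.graph.copy()
    n_windows = None
    for m in matrices.values():
        n_windows = m.calls.shape[1]
        if phase[0] < 0 or phase[1] >= n_windows or phase[0] > phase[1]:
            raise ValueError(f"phase {phase} outside the window grid")
    for n in H.nodes:
        signs: set[int] = set()
        for m in matrices.values():
            if n in m.calls.index:
                block = m.calls.loc[n].iloc[phase[0]: phase[1] + 1]
                signs.update(int(v) for v in block if v != 0)
        H.nodes[n]["functionality"] = _node_class(
            sorted(signs) if signs else [])
    edge_signs: dict[tuple[str, str], set[int]] = {}
    for L in networks:
        if L is None or L.sign is None:
            continue
        for e in L.graph.edges:
            edge_signs.setdefault(e, set()).add(L.sign)
    for e, signs in edge_signs.items():
        if H.has_edge(*e):
            if signs == {1}:
                cls = "strengthening"
            elif signs == {-1}:
                cls = "weakening"
            else:
                cls = "both"
            H.edges[e]["functionality"] = cls
    return H
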