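"""Dynamical cross-correlation matrices and correlation-network communities.

Each Cα atom is a communicating node; the normalized covariance of 3D
displacement vectors gives the dynamical cross-correlation matrix (DCCM),
c_ij ∈ [−1, 1].  Residue pairs whose |c_ij| reaches a cutoff (default 0.7)
are wired into a network, which the Girvan–Newman procedure — iterative
removal of the highest-betweenness edge — decomposes into communities; the
partition maximizing Newman–Girvan modularity Q = Σ_k (e_kk − a_k²) along the
removal trace is reported.  Reporting filters drop communities smaller than a
minimum size (default 10 Cα atoms), and a connectivity report states whether
two transmembrane segments communicate through the reported community
structure.

Betweenness uses unweighted shortest paths (edges are present/absent after
the cutoff); ties are broken deterministically by lexicographic edge id so a
rerun reproduces the trace exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .fit_fluct import superpose_frames
from .io_model import Topology, Trajectory
from .essential_dynamics import _stride_mask

__all__ = [
    "DCCM",
    "DynamicNetwork",
    "dccm",
    "build_network",
    "edge_betweenness",
    "girvan_newman",
    "filter_communities",
    "connectivity_report",
    "modularity",
]


@dataclass
class DCCM:
    """N×N normalized Cα cross-correlation matrix (dimensionless)."""

    c: np.ndarray  # (N, N), symmetric, unit diagonal, entries in [-1, 1]
    atom_indices: np.ndarray  # topology atom indices of the nodes
    resids: np.ndarray | None = None
    segments: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.c.shape[0]


@dataclass
class DynamicNetwork:
    """Correlation network with its Girvan–Newman decomposition."""

    graph: nx.Graph  # original (pre-removal) network
    communities: list[set]  # partition of ALL nodes, max-Q on the trace
    modularity_trace: list[float]  # Q after each edge removal (index 0 = no removal)
    final_q: float  # maximal Q along the trace
    min_size: int = 1  # reporting threshold applied (filter_communities)

    @property
    def reported_communities(self) -> list[set]:
        return [c for c in self.communities if len(c) >= self.min_size]

    def inter_community_edges(self) -> list[tuple[int, int, tuple]]:
        """Edges of the original graph crossing reported communities.

        Returns ``(community_a, community_b, (node_u, node_v))`` with
        community indices into :attr:`reported_communities`.
        """
        rep = self.reported_communities
        node_to_comm = {}
        for k, comm in enumerate(rep):
            for n in comm:
                node_to_comm[n] = k
        out = []
        for u, v in self.graph.edges():
            ku, kv = node_to_comm.get(u), node_to_comm.get(v)
            if ku is None or kv is None or ku == kv:
                continue
            out.append((min(ku, kv), max(ku, kv), (u, v)))
        return out


def dccm(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    stride_ps: float | None = 100.0,
    fit_selection: np.ndarray | None = None,
) -> DCCM:
    """Dynamical cross-correlation matrix of Cα displacement vectors.

    c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) with Δr the 3D displacement from
    the atom's time mean, frames superposed to frame 0 and resampled at
    ``stride_ps`` (default 100 ps).  A zero-variance atom is an error naming
    the atom.
    """
    sel = (
        np.arange(trajectory.n_atoms)
        if selection is None
        else np.asarray(selection, int)
    )
    fit = sel if fit_selection is None else np.asarray(fit_selection, int)
    keep = _stride_mask(trajectory.times, stride_ps)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 frames retained after striding")
    fitted = superpose_frames(
        trajectory.coordinates[keep], trajectory.coordinates[0], fit
    )
    x = fitted[:, sel, :]
    dev = x - x.mean(axis=0)
    inner = np.einsum("fia,fja->ij", dev, dev) / dev.shape[0]
    var = np.diag(inner).copy()
    zero = np.nonzero(var <= 1e-12)[0]  # Å² floor: frozen atoms have no direction
    if zero.size:
        labels = sel[zero].tolist()
        raise ValueError(f"zero-variance atoms in DCCM: atom indices {labels}")
    c = inner / np.sqrt(np.outer(var, var))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    top = trajectory.topology
    return DCCM(
        c=c,
        atom_indices=sel,
        resids=top.resids[sel] if top is not None else None,
        segments=top.segments[sel] if top is not None else None,
    )


def build_network(
    matrix: DCCM,
    cutoff: float = 0.7,
    min_seq_separation: int = 2,
    contact_mask: np.ndarray | None = None,
) -> nx.Graph:
    """Wire residues whose |c_ij| ≥ cutoff into an undirected weighted graph.

    Nodes are DCCM row indices carrying ``resid``/``segment`` attributes;
    edges require a sequence separation of at least ``min_seq_separation``
    residues (suppresses trivial backbone-neighbor correlations).  Passing a
    boolean ``contact_mask`` additionally intersects edges with a physical
    contact map.  The absolute value is used so strongly anti-correlated
    pairs also connect.  An empty graph is legal.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    n = matrix.n_nodes
    g = nx.Graph()
    for i in range(n):
        g.add_node(
            i,
            resid=int(matrix.resids[i]) if matrix.resids is not None else i,
            segment=str(matrix.segments[i]) if matrix.segments is not None else "OTHER",
        )
    resids = (
        matrix.resids if matrix.resids is not None else np.arange(n)
    )
    absc = np.abs(matrix.c)
    for i in range(n):
        for j in range(i + 1, n):
            if absc[i, j] < cutoff:
                continue
            if abs(int(resids[i]) - int(resids[j])) < min_seq_separation:
                continue
            if contact_mask is not None and not contact_mask[i, j]:
                continue
            g.add_edge(i, j, weight=float(absc[i, j]))
    return g


def edge_betweenness(graph: nx.Graph) -> dict[tuple, float]:
    """Unweighted edge betweenness: shortest paths crossing each edge.

    Counts each unordered node pair once (Brandes accumulation); keys are
    sorted edge tuples.
    """
    raw = nx.edge_betweenness_centrality(graph, normalized=False)
    return {tuple(sorted(e)): b for e, b in raw.items()}


def modularity(graph: nx.Graph, communities: list[set]) -> float:
    """Newman–Girvan modularity Q = Σ_k (e_kk − a_k²) of a partition.

    ``graph`` supplies the edge set (the ORIGINAL network, not the
    edge-removed working copy).  An edgeless graph has Q defined as 0.
    """
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    node_to_comm = {}
    for k, comm in enumerate(communities):
        for n in comm:
            node_to_comm[n] = k
    e_kk = np.zeros(len(communities))
    deg = np.zeros(len(communities))
    for u, v in graph.edges():
        if node_to_comm[u] == node_to_comm[v]:
            e_kk[node_to_comm[u]] += 1.0
    for n, d in graph.degree():
        deg[node_to_comm[n]] += d
    return float(np.sum(e_kk / m - (deg / (2.0 * m)) ** 2))


def _components(graph: nx.Graph) -> list[set]:
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: sorted(c)[0])


def girvan_newman(graph: nx.Graph) -> DynamicNetwork:
    """Full Girvan–Newman decomposition with a modularity trace.

    Iteratively removes the maximum-betweenness edge (lexicographic edge-id
    tie-break), records Q of the connected-component partition after every
    removal, and returns the earliest partition attaining the maximal Q.
    """
    work = graph.copy()
    best_partition = _components(work)
    trace = [modularity(graph, best_partition)]
    best_q = trace[0]
    while work.number_of_edges() > 0:
        bt = edge_betweenness(work)
        max_b = max(bt.values())
        edge = min(e for e, b in bt.items() if b >= max_b - 1e-9)
        work.remove_edge(*edge)
        partition = _components(work)
        q = modularity(graph, partition)
        trace.append(q)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = partition
    return DynamicNetwork(
        graph=graph.copy(),
        communities=best_partition,
        modularity_trace=trace,
        final_q=best_q,
    )


def filter_communities(network: DynamicNetwork, min_size: int = 10) -> DynamicNetwork:
    """Reporting view keeping communities of at least ``min_size`` nodes.

    The partition itself is unchanged; only the reporting threshold moves.
    If nothing survives, a warning is emitted (empty report, not an error).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    view = DynamicNetwork(
        graph=network.graph,
        communities=network.communities,
        modularity_trace=network.modularity_trace,
        final_q=network.final_q,
        min_size=min_size,
    )
    if not view.reported_communities:
        warnings.warn(f"no communities of size >= {min_size} to report")
    return view


def _dominant_segments(graph: nx.Graph, community: set) -> set[str]:
    """Segment label(s) holding the plurality of a community's members."""
    counts: dict[str, int] = {}
    for n in community:
        seg = graph.nodes[n].get("segment", "OTHER")
        counts[seg] = counts.get(seg, 0) + 1
    top = max(counts.values())
    return {s for s, c in counts.items() if c == top}


def connectivity_report(
    network: DynamicNetwork,
    segment_a: str,
    segment_b: str,
) -> tuple[bool, list[tuple[int, int]]]:
    """Do two segments communicate through the reported community structure?

    True iff an inter-community edge links a community dominated (plurality,
    ties inclusive) by ``segment_a`` to one dominated by ``segment_b``, or a
    single reported community is dominated by both (joint membership).  For
    ``segment_a == segment_b``: true iff the segment dominates at least one
    reported community.  Returns the verdict and the supporting residue
    pairs.
    """
    g = network.graph
    known = {g.nodes[n].get("segment", "OTHER") for n in g.nodes}
    for seg in (segment_a, segment_b):
        if seg not in known:
            raise ValueError(f"segment {seg!r} has no nodes in the network")
    rep = network.reported_communities
    dom = [_dominant_segments(g, c) for c in rep]
    support: list[tuple[int, int]] = []
    connected = False
    if segment_a == segment_b:
        for k, d in enumerate(dom):
            if segment_a in d:
                connected = True
                support.extend(
                    (g.nodes[n]["resid"], g.nodes[n]["resid"]) for n in sorted(rep[k])[:1]
                )
        return connected, support
    # joint membership inside one reported community
    for k, d in enumerate(dom):
        if segment_a in d and segment_b in d:
            members_a = [n for n in rep[k] if g.nodes[n].get("segment") == segment_a]
            members_b = [n for n in rep[k] if g.nodes[n].get("segment") == segment_b]
            if members_a and members_b:
                connected = True
                support.extend(
                    (g.nodes[a]["resid"], g.nodes[b]["resid"])
                    for a in sorted(members_a)[:3]
                    for b in sorted(members_b)[:3]
                )
    # inter-community edges between a-dominated and b-dominated communities
    for ka, kb, (u, v) in network.inter_community_edges():
        if (segment_a in dom[ka] and segment_b in dom[kb]) or (
            segment_b in dom[ka] and segment_a in dom[kb]
        ):
            connected = True
            support.append((g.nodes[u]["resid"], g.nodes[v]["resid"]))
    return connected, support
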