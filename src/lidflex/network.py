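"""Contact persistence, pocket residues, and the dynamical network layer.

A residue pair is "in contact" in a frame when its minimum inter-atom
distance (heavy-atom or C-alpha level) is at or below a cutoff; the
persistence is the fraction of frames in contact. The dynamical network
puts one node per residue and an edge between non-covalent-neighbor pairs
in persistent contact, weighted w_ij = -log|C_ij| with C the DCCM entry:
highly correlated pairs get short (strong) edges, so shortest paths trace
the dominant communication routes. Communities come from Girvan-Newman
edge removal (weighted edge betweenness, deterministic lexicographic
tie-break), keeping the partition of maximal Newman weighted modularity on
the original graph; inter-community flow sums the full-graph edge
betweenness over edges crossing two communities.

Defaults pin the conventional "default settings" of residue-network
analysis in molecular viewers: 4.5 A heavy-atom contact, 75 % persistence,
covalent neighbors excluded, -log|C| weights. All are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .correlation import CorrelationMatrix
from .io import Ensemble, RegionDefinition, SelectionMask, Structure

__all__ = [
    "ContactPersistenceMap",
    "DynamicalNetwork",
    "contact_persistence",
    "pocket_residues",
    "build_network",
    "girvan_newman_communities",
    "intercommunity_flow",
    "edge_betweenness",
]

# |C| is clamped into [EPS, 1 - EPS] before taking -log, keeping weights
# finite and strictly positive
CLAMP_EPS = 1e-6


@dataclass
class ContactPersistenceMap:
    """(residue i, residue j) -> fraction of frames in contact."""

    fractions: dict              # {(i, j) with i < j: float}
    cutoff: float
    atom_level: str

    def __post_init__(self):
        for (i, j), v in self.fractions.items():
            if i == j:
                raise ValueError("self-pairs are excluded from contact maps")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {v} for pair ({i},{j}) not in [0,1]")

    def __getitem__(self, pair):
        i, j = sorted(pair)
        return self.fractions.get((i, j), 0.0)


@dataclass
class DynamicalNetwork:
    """Residue graph with -log|C| edge weights on persistent contacts."""

    graph: nx.Graph                      # nodes = residue ids
    residue_ids: np.ndarray
    persistence_cutoff: float
    distance_cutoff: float
    partition: dict | None = None        # residue id -> community label
    modularity: float | None = None
    flow: dict | None = None             # (comm a, comm b) -> flow

    def communities(self) -> list:
        if self.partition is None:
            raise ValueError("no community partition computed yet")
        groups = {}
        for node, c in self.partition.items():
            groups.setdefault(c, []).append(node)
        return [sorted(groups[c]) for c in sorted(groups)]


def _residue_atom_groups(structure: Structure, residues, atom_level: str):
    """Atom-index arrays per residue at the requested atom level."""
    groups = []
    for r in residues:
        sel = structure.res_ids == r
        if atom_level == "ca":
            sel &= structure.atom_names == "CA"
        elif atom_level == "heavy":
            sel &= structure.elements != "H"
        else:
            raise ValueError(f"atom_level must be 'heavy' or 'ca', got {atom_level!r}")
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            raise ValueError(f"residue {r} has no atoms at level {atom_level!r}")
        groups.append(idx)
    return groups


def contact_persistence(ensemble: Ensemble, region_a: RegionDefinition,
                        region_b: RegionDefinition, cutoff: float = 4.5,
                        atom_level: str = "heavy") -> ContactPersistenceMap:
    """Fraction of frames each inter-region residue pair is in contact."""
    top = ensemble.topology
    region_a.validate(top)
    region_b.validate(top)
    ga = _residue_atom_groups(top, region_a.residues, atom_level)
    gb = _residue_atom_groups(top, region_b.residues, atom_level)
    counts = {}
    for f in range(ensemble.n_frames):
        xyz = ensemble.frames[f]
        for ra, ia in zip(region_a.residues, ga):
            for rb, ib in zip(region_b.residues, gb):
                if ra == rb:
                    continue
                dmin = cdist(xyz[ia], xyz[ib]).min()
                key = tuple(sorted((ra, rb)))
                if dmin <= cutoff:
                    counts[key] = counts.get(key, 0) + 1
                else:
                    counts.setdefault(key, 0)
    fr = {k: v / ensemble.n_frames for k, v in counts.items()}
    return ContactPersistenceMap(fractions=fr, cutoff=cutoff,
                                 atom_level=atom_level)


def pocket_residues(structure: Structure, ligand_mask: SelectionMask,
                    radius: float = 5.0, name: str = "pocket") -> RegionDefinition:
    """Residues with any heavy atom within ``radius`` A of any ligand heavy atom."""
    if len(ligand_mask) == 0:
        raise ValueError("ligand mask is empty")
    lig = [i for i in ligand_mask.indices if structure.elements[i] != "H"]
    heavy = np.flatnonzero(structure.elements != "H")
    prot = np.array([i for i in heavy if i not in set(lig)])
    d = cdist(structure.coords[prot], structure.coords[lig])
    near = prot[np.flatnonzero((d <= radius).any(axis=1))]
    residues = sorted(set(int(structure.res_ids[i]) for i in near))
    if not residues:
        raise ValueError(f"no residues within {radius} A of the ligand")
    return RegionDefinition(name=name, residues=tuple(residues))


def build_network(ensemble: Ensemble, correlation: CorrelationMatrix,
                  persistence_cutoff: float = 0.75,
                  distance_cutoff: float = 4.5,
                  atom_level: str = "heavy") -> DynamicalNetwork:
    """Correlation-weighted residue graph on persistent-contact pairs.

    An edge joins residues i, j when they are not covalent neighbors
    (|i - j| > 1 within a chain) and in contact in at least
    ``persistence_cutoff`` of frames; its weight is -log|C_ij| with |C|
    clamped to [1e-6, 1 - 1e-6].
    """
    top = ensemble.topology
    resids = correlation.residue_ids
    region = RegionDefinition("network-nodes", tuple(int(r) for r in resids))
    region.validate(top)
    groups = _residue_atom_groups(top, region.residues, atom_level)
    n = len(resids)
    counts = np.zeros((n, n), dtype=int)
    if all(len(g) == 1 for g in groups):
        idx = np.array([g[0] for g in groups])
        for f in range(ensemble.n_frames):
            xyz = ensemble.frames[f][idx]
            counts += cdist(xyz, xyz) <= distance_cutoff
    else:
        for f in range(ensemble.n_frames):
            xyz = ensemble.frames[f]
            for a in range(n):
                for b in range(a + 1, n):
                    if cdist(xyz[groups[a]], xyz[groups[b]]).min() <= distance_cutoff:
                        counts[a, b] += 1
                        counts[b, a] += 1
    persistence = counts / ensemble.n_frames

    g = nx.Graph()
    g.add_nodes_from(int(r) for r in resids)
    chains = {int(r): top.chain_ids[groups[k][0]] for k, r in enumerate(resids)}
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = int(resids[a]), int(resids[b])
            if chains[ra] == chains[rb] and abs(ra - rb) == 1:
                continue  # covalent neighbors excluded
            if persistence[a, b] < persistence_cutoff:
                continue
            absc = np.clip(abs(correlation.values[a, b]), CLAMP_EPS, 1 - CLAMP_EPS)
            # 'weight' is a distance (-log|C|) for shortest paths/betweenness;
            # 'strength' is |C| itself, the coupling magnitude modularity uses
            g.add_edge(ra, rb, weight=float(-np.log(absc)),
                       strength=float(absc),
                       correlation=float(correlation.values[a, b]),
                       persistence=float(persistence[a, b]))
    return DynamicalNetwork(graph=g, residue_ids=resids,
                            persistence_cutoff=persistence_cutoff,
                            distance_cutoff=distance_cutoff)


def edge_betweenness(graph: nx.Graph) -> dict:
    """Weighted shortest-path edge betweenness (unnormalized pair counts)."""
    eb = nx.edge_betweenness_centrality(graph, normalized=False, weight="weight")
    return {tuple(sorted(e)): v for e, v in eb.items()}


def _partition_from_components(graph: nx.Graph) -> dict:
    part = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for label, comp in enumerate(comps):
        for node in comp:
            part[node] = label
    return part


def _weighted_modularity(original: nx.Graph, partition: dict) -> float:
    """Newman modularity on the original graph.

    Uses the 'strength' edge attribute (|C|, coupling magnitude) where
    present, falling back to 1 per edge: the path-length weight -log|C|
    is a distance and would invert the meaning of modularity.
    """
    comms = {}
    for node, c in partition.items():
        comms.setdefault(c, set()).add(node)
    return nx.community.modularity(original, list(comms.values()),
                                   weight="strength")


def _gn_partition_sequence(graph: nx.Graph):
    """Yield (partition, n_communities) along the Girvan-Newman removal.

    The dendrogram of max-betweenness edge removals (weighted, shortest
    path) is computed in C via igraph; partitions are yielded from the
    initial component split down to singletons.
    """
    import igraph

    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edges = sorted((idx[u], idx[v]) if idx[u] < idx[v] else (idx[v], idx[u])
                   for u, v in graph.edges)
    g = igraph.Graph(n=len(nodes), edges=edges)
    weights = [graph[nodes[u]][nodes[v]].get("weight", 1.0)
               for u, v in edges]
    dendrogram = g.community_edge_betweenness(weights=weights,
                                              directed=False)
    base = len(list(nx.connected_components(graph)))
    for ncomm in range(base, len(nodes) + 1):
        clustering = dendrogram.as_clustering(ncomm)
        part = {}
        for label, members in enumerate(clustering):
            for m in members:
                part[nodes[m]] = label
        yield part, ncomm


def girvan_newman_communities(network: DynamicalNetwork,
                              k: int | None = None) -> DynamicalNetwork:
    """Girvan-Newman partition by iterative max-betweenness edge removal.

    Returns the partition of maximal modularity (on the coupling-strength
    weights) over the removal sequence, or the first partition with exactly
    ``k`` communities when ``k`` is given. The input network is returned
    with ``partition`` and ``modularity`` set.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        part = _partition_from_components(g)
        if k is not None and len(set(part.values())) != k:
            raise ValueError(
                f"could not cut the graph into exactly {k} communities")
        network.partition, network.modularity = part, 0.0
        return network
    best_part, best_mod = None, -np.inf
    for part, ncomm in _gn_partition_sequence(g):
        if k is not None:
            if ncomm == k:
                network.partition = part
                network.modularity = _weighted_modularity(g, part)
                return network
            continue
        mod = _weighted_modularity(g, part)
        if mod > best_mod + 1e-12:
            best_mod, best_part = mod, part
    if k is not None:
        raise ValueError(f"could not cut the graph into exactly {k} communities")
    network.partition = best_part
    network.modularity = best_mod
    return network


def intercommunity_flow(network: DynamicalNetwork,
                        partition: dict | None = None,
                        normalized: bool = False) -> dict:
    """Symmetric community-pair flow table.

    flow(A, B) = sum of full-graph edge betweenness over edges with one
    endpoint in A and the other in B. With ``normalized=True`` flows are
    divided by the total betweenness over all edges.
    """
    part = partition if partition is not None else network.partition
    if part is None:
        raise ValueError("no partition given or computed")
    missing = [n for n in network.graph.nodes if n not in part]
    if missing:
        raise ValueError(f"partition misses nodes {missing[:5]}")
    eb = edge_betweenness(network.graph)
    flow = {}
    for (u, v), b in eb.items():
        cu, cv = part[u], part[v]
        if cu == cv:
            continue
        key = tuple(sorted((cu, cv)))
        flow[key] = flow.get(key, 0.0) + b
    if normalized:
        total = sum(eb.values())
        if total > 0:
            flow = {kk: v / total for kk, v in flow.items()}
    network.flow = flow
    return flow
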