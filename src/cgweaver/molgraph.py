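"""Core molecular graph model and graph algorithms.

A molecule is an undirected graph whose nodes are particles (atoms or
coarse-grained beads) and whose edges follow bonded connectivity.  Bonded
*interactions* (the force-field terms) are stored alongside the graph: the
edge set and the interaction set may legitimately differ — elastic-network
bonds, for instance, are interactions that deliberately do not become edges
so that they cannot change molecule partitioning or graph distances.

The attribute-aware subgraph matcher implemented here is the workhorse of
residue identification, modification detection and link application.  It is
a VF2-style recursive matcher that enumerates *monomorphisms*: injective
node correspondences under which every pattern edge maps onto a target edge
and a user-supplied node predicate holds.  Enumeration order is
deterministic (sorted by node id) so that every downstream stage is
reproducible.
"""
from __future__ import annotations

import dataclasses
from typing import Any, Callable, Hashable, Iterator, Mapping, Optional, Sequence

import networkx as nx

NodeMatch = Callable[[Mapping[str, Any], Mapping[str, Any]], bool]

#: particle-count constraints per interaction kind; None = variable (min count)
INTERACTION_ARITY: dict[str, tuple[int, Optional[int]]] = {
    "bond": (2, 2),
    "angle": (3, 3),
    "dihedral": (4, 4),
    "improper": (4, 4),
    "constraint": (2, 2),
    "pair": (2, 2),
    "exclusion": (2, None),
    "virtual_site_n": (2, None),
    "position_restraint": (1, 1),
}


@dataclasses.dataclass(frozen=True)
class Interaction:
    """One bonded term: kind, ordered particle references, verbatim parameters.

    Parameters are opaque strings passed through to the topology writer;
    the engine never interprets them numerically except where an operation
    explicitly says so (elastic-network generation).
    """

    kind: str
    particles: tuple
    parameters: tuple = ()
    meta: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_ARITY:
            raise ValueError(f"unknown interaction kind: {self.kind!r}")
        lo, hi = INTERACTION_ARITY[self.kind]
        n = len(self.particles)
        if n < lo or (hi is not None and n > hi):
            raise ValueError(
                f"{self.kind} interaction needs "
                f"{lo}{'' if hi == lo else '+'} particles, got {n}"
            )
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "parameters", tuple(str(p) for p in self.parameters))
        object.__setattr__(self, "meta", dict(self.meta))

    def replace(self, **kwargs: Any) -> "Interaction":
        return dataclasses.replace(self, **kwargs)


class MoleculeGraph(nx.Graph):
    """Undirected particle graph plus interactions, citations and provenance.

    Node attributes follow the ``ParticleAttrs`` convention: ``atom_name``,
    ``resname`` and ``resid`` are always present; ``chain``, ``element``,
    ``charge``, ``mass``, ``position`` (length-3 numpy array in nm, or
    absent), ``particle_type`` and ``secstruct`` are optional.
    """

    def __init__(self, *args: Any, **kwargs: Any) -> None:
        super().__init__(*args, **kwargs)
        self.interactions: dict[str, list[Interaction]] = {}
        self.citations: set[str] = set()
        self.forcefield_name: str = ""

    # -- interactions -------------------------------------------------
    def add_interaction(self, interaction: Interaction) -> None:
        for p in interaction.particles:
            if p not in self:
                raise KeyError(
                    f"interaction references unknown particle {p!r}"
                )
        self.interactions.setdefault(interaction.kind, []).append(interaction)

    def remove_interaction(self, kind: str, particles: Sequence) -> bool:
        """Remove the first interaction of *kind* on *particles* (either order
        for symmetric kinds).  Returns True if one was removed."""
        terms = self.interactions.get(kind, [])
        keys = {tuple(particles), tuple(reversed(tuple(particles)))}
        for i, term in enumerate(terms):
            if term.particles in keys:
                del terms[i]
                return True
        return False

    def all_interactions(self) -> Iterator[Interaction]:
        for kind in sorted(self.interactions):
            yield from self.interactions[kind]

    def copy_with_interactions(self) -> "MoleculeGraph":
        new = MoleculeGraph()
        new.add_nodes_from((n, dict(a)) for n, a in self.nodes(data=True))
        new.add_edges_from(self.edges(data=True))
        new.interactions = {k: list(v) for k, v in self.interactions.items()}
        new.citations = set(self.citations)
        new.forcefield_name = self.forcefield_name
        return new


@dataclasses.dataclass
class SystemOfMolecules:
    """Ordered collection of molecules sharing one force field."""

    molecules: list[MoleculeGraph] = dataclasses.field(default_factory=list)
    forcefield_name: str = ""

    def __iter__(self) -> Iterator[MoleculeGraph]:
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def n_particles(self) -> int:
        return sum(len(m) for m in self.molecules)


# ---------------------------------------------------------------------------
# residue helpers

def residue_key(attrs: Mapping[str, Any]) -> tuple:
    """Composite key identifying the residue a particle belongs to."""
    return (attrs.get("chain", ""), attrs["resid"], attrs.get("icode", ""))


def residue_groups(molecule: nx.Graph) -> dict[tuple, list]:
    """Group node ids by residue, preserving deterministic order.

    Residues are ordered by (chain, resid, icode); nodes within a residue by
    node id.
    """
    groups: dict[tuple, list] = {}
    for node in sorted(molecule.nodes):
        groups.setdefault(residue_key(molecule.nodes[node]), []).append(node)
    return dict(sorted(groups.items()))


# ---------------------------------------------------------------------------
# operations

def connected_components(graph: nx.Graph) -> list[MoleculeGraph]:
    """Partition a global particle graph into molecules.

    Every maximal connected component becomes one :class:`MoleculeGraph`
    with particle ids renumbered contiguously from 0; the original id is
    retained per node under the ``orig_id`` attribute and as the graph-level
    ``orig_ids`` map.  Components are ordered by their smallest original
    node id so partitioning is stable under re-runs.
    """
    molecules: list[MoleculeGraph] = []
    components = sorted(nx.connected_components(graph), key=min)
    for comp in components:
        old_ids = sorted(comp)
        renum = {old: new for new, old in enumerate(old_ids)}
        mol = MoleculeGraph()
        for old in old_ids:
            attrs = dict(graph.nodes[old])
            attrs["orig_id"] = old
            mol.add_node(renum[old], **attrs)
        for u, v, data in graph.edges(data=True):
            if u in renum and v in renum:
                mol.add_edge(renum[u], renum[v], **data)
        mol.graph["orig_ids"] = {new: old for old, new in renum.items()}
        if isinstance(graph, MoleculeGraph):
            mol.forcefield_name = graph.forcefield_name
        molecules.append(mol)
    return molecules


def graph_distance(
    molecule: nx.Graph,
    a: Hashable,
    b: Hashable,
    via: Optional[Callable[[Hashable, Hashable], bool]] = None,
) -> float:
    """Shortest-path length between two particles.

    ``via`` optionally restricts which edges count (a predicate over the
    two endpoint ids); by default all bonded edges count.  Returns
    ``math.inf`` when the nodes are disconnected under that selector.
    """
    for node in (a, b):
        if node not in molecule:
            raise KeyError(f"unknown particle id: {node!r}")
    view = molecule if via is None else nx.subgraph_view(molecule, filter_edge=via)
    try:
        return nx.shortest_path_length(view, a, b)
    except nx.NetworkXNoPath:
        return float("inf")


def default_node_match(p_attrs: Mapping[str, Any], t_attrs: Mapping[str, Any]) -> bool:
    """Element equality when both elements are known, else atom-name equality.

    Atom names in deposited structures are unreliable; elements are not.
    """
    pe = p_attrs.get("element") or ""
    te = t_attrs.get("element") or ""
    if pe and te:
        return pe.upper() == te.upper()
    return p_attrs.get("atom_name") == t_attrs.get("atom_name")


def subgraph_isomorphisms(
    pattern: nx.Graph,
    target: nx.Graph,
    node_match: NodeMatch = default_node_match,
) -> Iterator[dict]:
    """Enumerate all monomorphisms of *pattern* into *target*.

    Yields dicts mapping pattern node -> target node such that the mapping
    is injective, every pattern edge maps onto a target edge, and
    ``node_match(pattern_attrs, target_attrs)`` holds for every pair.
    Pattern non-edges are unconstrained (monomorphism, not induced
    isomorphism) — a link pattern must be allowed to match inside a ring.

    Enumeration is deterministic: pattern nodes are processed in an order
    fixed by (candidate rarity, degree, node id) and target candidates are
    tried in sorted order.
    """
    if len(pattern) == 0:
        yield {}
        return
    if len(pattern) > len(target):
        return

    tnodes = sorted(target.nodes)
    # Precompute per-pattern-node candidate lists (attribute filter only).
    candidates: dict[Hashable, list] = {}
    for p in pattern.nodes:
        pa = pattern.nodes[p]
        candidates[p] = [
            t
            for t in tnodes
            if node_match(pa, target.nodes[t]) and target.degree(t) >= pattern.degree(p)
        ]
        if not candidates[p]:
            return

    # Static order: rare candidates and high degree first; prefer nodes
    # adjacent to already-ordered ones to keep partial maps connected.
    remaining = set(pattern.nodes)
    order: list = []
    while remaining:
        frontier = (
            {n for o in order for n in pattern.adj[o] if n in remaining} or remaining
        )
        nxt = min(
            frontier,
            key=lambda n: (len(candidates[n]), -pattern.degree(n), repr(n)),
        )
        order.append(nxt)
        remaining.discard(nxt)

    mapping: dict = {}
    used: set = set()

    def backtrack(i: int) -> Iterator[dict]:
        if i == len(order):
            yield dict(mapping)
            return
        p = order[i]
        mapped_neighbours = [q for q in pattern.adj[p] if q in mapping]
        for t in candidates[p]:
            if t in used:
                continue
            if any(not target.has_edge(mapping[q], t) for q in mapped_neighbours):
                continue
            mapping[p] = t
            used.add(t)
            yield from backtrack(i + 1)
            del mapping[p]
            used.discard(t)

    yield from backtrack(0)


def maximum_common_correspondence(
    pattern: nx.Graph,
    target: nx.Graph,
    node_match: NodeMatch = default_node_match,
    name_key: str = "atom_name",
) -> dict:
    """Maximum common *induced* subgraph correspondence pattern -> target.

    Among all maximum-cardinality correspondences under which matched pairs
    preserve adjacency in both directions, the one maximizing exact
    ``name_key`` agreement is returned, ties broken by lexicographically
    smallest assignment — residue repair must be reproducible even for
    symmetric rings.

    Branch-and-bound (McGregor style); intended for residue-sized graphs
    (tens of nodes), not whole molecules.
    """
    pnodes = sorted(pattern.nodes, key=lambda n: (-pattern.degree(n), repr(n)))
    tnodes = sorted(target.nodes)
    cand = {
        p: [t for t in tnodes if node_match(pattern.nodes[p], target.nodes[t])]
        for p in pnodes
    }

    best: dict = {}
    best_score = (-1, -1)

    def name_agrees(p: Hashable, t: Hashable) -> bool:
        return pattern.nodes[p].get(name_key) == target.nodes[t].get(name_key)

    def backtrack(i: int, mapping: dict, used: set, names: int) -> None:
        nonlocal best, best_score
        score = (len(mapping), names)
        if score > best_score:
            best_score = score
            best = dict(mapping)
        rest = len(pnodes) - i
        # optimistic bound: every remaining pattern node matches by name
        if (len(mapping) + rest, names + rest) <= best_score:
            return
        if i == len(pnodes):
            return
        p = pnodes[i]
        for t in cand[p]:
            if t in used:
                continue
            ok = True
            for q, tq in mapping.items():
                if pattern.has_edge(p, q) != target.has_edge(t, tq):
                    ok = False
                    break
            if ok:
                mapping[p] = t
                used.add(t)
                backtrack(i + 1, mapping, used, names + name_agrees(p, t))
                del mapping[p]
                used.discard(t)
        # option: leave p unmatched
        backtrack(i + 1, mapping, used, names)

    backtrack(0, {}, set(), 0)
    return best
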