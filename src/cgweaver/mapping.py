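"""Resolution transformation: cover a repaired molecule with fragment
mappings and emit the target-resolution molecule.

Placement is greedy largest-scope-first: mappings spanning several
residues are placed before single-residue ones so they are not shadowed.
Bead positions are the weighted mean of their source atoms' positions;
when some sources lack coordinates the position is estimated from the rest
(with a warning), and when all of them are absent the bead is emitted
coordinate-free — the topology is still generated, only the coordinate is
not.  Virtual sites are constructed afterwards from their constructing
particles, in dependency order.
"""
from __future__ import annotations

import dataclasses
from typing import Any, Iterable, Optional

import numpy as np

from .ffdata import ForceField, FragmentMapping
from .ledger import WarningLedger
from .molgraph import MoleculeGraph, residue_groups


class MappingError(ValueError):
    pass


@dataclasses.dataclass
class Placement:
    mapping: FragmentMapping
    residues: list[tuple]  # residue keys covered, in scope order
    #: source node -> {(scope_idx, bead name): weight}
    atom_weights: dict[Any, dict[tuple[int, str], float]]


@dataclasses.dataclass
class MappingCover:
    placements: list[Placement] = dataclasses.field(default_factory=list)
    uncovered_atoms: set = dataclasses.field(default_factory=set)


def identity_mappings(forcefield: ForceField) -> list[FragmentMapping]:
    """Same-resolution mappings: every block atom maps onto itself.

    Running the pipeline with these reproduces the input graph at the
    output — the pathway used for generating atomistic topologies.
    """
    out = []
    for name, block in forcefield.blocks.items():
        m = FragmentMapping(name=name, from_resnames=(name,), to_resnames=(name,))
        for atom in block.graph.nodes:
            m.weights[(1, atom)] = {(1, atom): 1.0}
        out.append(m)
    return out


def build_cover(
    molecule: MoleculeGraph,
    mappings: Iterable[FragmentMapping],
    ledger: Optional[WarningLedger] = None,
) -> MappingCover:
    """Assign every residue of the molecule to a mapping placement.

    Multi-residue mappings are matched against runs of bonded residues with
    consecutive residue numbers whose names spell the mapping's scope.
    Residues with no applicable mapping are excluded with a warning.
    Hydrogens and modification-added atoms carry their own weights (zero
    and modification-declared respectively) and never count as uncovered.
    """
    groups = residue_groups(molecule)
    keys = list(groups)
    resname_of = {key: molecule.nodes[groups[key][0]]["resname"] for key in keys}
    covered: set[tuple] = set()
    cover = MappingCover()
    ordered = sorted(
        enumerate(mappings), key=lambda kv: (-len(kv[1].from_resnames), kv[0])
    )
    for _, mapping in ordered:
        span = len(mapping.from_resnames)
        for start in range(len(keys) - span + 1):
            window = keys[start:start + span]
            if any(k in covered for k in window):
                continue
            if tuple(resname_of[k] for k in window) != mapping.from_resnames:
                continue
            if span > 1 and not _window_connected(molecule, groups, window):
                continue
            placement = _place(molecule, groups, window, mapping)
            cover.placements.append(placement)
            covered.update(window)
    # emit beads in residue order along the molecule, not mapping order
    cover.placements.sort(key=lambda p: p.residues[0])
    for key in keys:
        if key in covered:
            continue
        if ledger is not None:
            ledger.warn(
                "unrecognized-residue",
                f"no mapping applies to residue {resname_of[key]} {key[0]}{key[1]}; "
                "residue excluded from output",
                chain=key[0], resid=key[1], resname=resname_of[key],
            )
        cover.uncovered_atoms.update(groups[key])
    # atoms inside covered residues that receive no weight anywhere
    weighted = {
        node for p in cover.placements for node in p.atom_weights
    }
    for key in covered:
        for node in groups[key]:
            attrs = molecule.nodes[node]
            if node in weighted or attrs.get("mapped_bead"):
                continue
            if (attrs.get("element") or "").upper() == "H":
                continue  # hydrogens carry zero mapping weight by design
            cover.uncovered_atoms.add(node)
            if ledger is not None and attrs.get("unexpected"):
                continue  # already warned as unexpected during repair
            if ledger is not None:
                ledger.warn(
                    "unexpected-atoms",
                    f"atom {attrs['atom_name']} of residue "
                    f"{attrs['resname']} {key[0]}{key[1]} is not covered by the mapping",
                    chain=key[0], resid=key[1], atom=attrs["atom_name"],
                )
    return cover


def _window_connected(molecule, groups, window) -> bool:
    """Consecutive scope residues must be bonded and contiguously numbered."""
    for a, b in zip(window, window[1:]):
        if a[0] != b[0] or b[1] - a[1] != 1:
            return False
        nodes_a, nodes_b = set(groups[a]), set(groups[b])
        if not any(m in nodes_b for n in nodes_a for m in molecule.adj[n]):
            return False
    return True


def _place(molecule, groups, window, mapping: FragmentMapping) -> Placement:
    atom_weights: dict[Any, dict[tuple[int, str], float]] = {}
    for scope_idx, key in enumerate(window, start=1):
        by_name = {molecule.nodes[n]["atom_name"]: n for n in groups[key]}
        for (residx, atom), targets in mapping.weights.items():
            if residx != scope_idx:
                continue
            node = by_name.get(atom)
            if node is None:
                continue  # atom absent even after repair (e.g. stripped H)
            atom_weights[node] = dict(targets)
        # modification-added atoms folded into a declared bead
        for n in groups[key]:
            bead = molecule.nodes[n].get("mapped_bead")
            if bead is not None and n not in atom_weights:
                atom_weights[n] = {(scope_idx, bead): 1.0}
    return Placement(mapping=mapping, residues=list(window), atom_weights=atom_weights)


def map_to_target(
    molecule: MoleculeGraph,
    cover: MappingCover,
    target_ff: ForceField,
    ledger: Optional[WarningLedger] = None,
    weights_mode: str = "file",
) -> MoleculeGraph:
    """Emit the target-resolution molecule for a validated cover.

    One node per target particle; bead position = Σ w·r / Σ w over source
    atoms with known positions; bead edges wherever a mapped source bond
    crosses two beads; intra-fragment interactions instantiated from the
    target blocks; residue attributes inherited from the dominant source
    residue (largest total weight, ties to the lowest residue number).
    """
    if weights_mode not in ("file", "mass", "uniform"):
        raise MappingError(f"unknown weights mode {weights_mode!r}")
    out = MoleculeGraph()
    out.forcefield_name = target_ff.name
    # residue -> applied modification names, collected once
    residue_mods: dict[tuple, list[str]] = {}
    for node in molecule.nodes:
        a = molecule.nodes[node]
        key = (a.get("chain", ""), a["resid"], a.get("icode", ""))
        for m in a.get("modifications", []):
            mods = residue_mods.setdefault(key, [])
            if m not in mods:
                mods.append(m)
    molecule.graph["_residue_mods"] = residue_mods
    bead_id = 0
    bead_of: dict[tuple[int, int, str], int] = {}  # (placement idx, scope idx, bead)
    node_to_beads: dict[Any, list[tuple[int, float]]] = {}

    for p_idx, placement in enumerate(cover.placements):
        mapping = placement.mapping
        # per-bead source lists
        sources: dict[tuple[int, str], list[tuple[Any, float]]] = {}
        for node, targets in placement.atom_weights.items():
            w_atom = molecule.nodes[node].get("mass") or 1.0
            for (j, bead), w in targets.items():
                if weights_mode == "mass":
                    w = w * float(w_atom)
                elif weights_mode == "uniform":
                    w = 1.0 if w > 0 else 0.0
                sources.setdefault((j, bead), []).append((node, w))
        for j, to_resname in enumerate(mapping.to_resnames, start=1):
            block = target_ff.blocks.get(to_resname)
            if block is None:
                raise MappingError(
                    f"mapping {mapping.name!r} targets unknown block {to_resname!r}"
                )
            local: dict[str, int] = {}
            for bead_name in block.graph.nodes:
                battrs = block.graph.nodes[bead_name]
                src = sources.get((j, bead_name), [])
                attrs = _inherit_attrs(molecule, src, placement, j)
                position, note = _bead_position(molecule, src)
                if note and ledger is not None:
                    ledger.warn(
                        "missing-coordinates",
                        f"bead {bead_name} of residue {to_resname} "
                        f"{attrs.get('chain','')}{attrs.get('resid','?')}: {note}",
                        bead=bead_name, resid=attrs.get("resid"),
                        chain=attrs.get("chain", ""),
                    )
                out.add_node(
                    bead_id,
                    atom_name=bead_name,
                    resname=to_resname,
                    resid=attrs.get("resid", 0),
                    chain=attrs.get("chain", ""),
                    icode=attrs.get("icode", ""),
                    secstruct=attrs.get("secstruct", "C"),
                    element="",
                    particle_type=battrs.get("particle_type"),
                    charge=battrs.get("charge", 0.0),
                    mass=battrs.get("mass", 0.0),
                    position=position,
                    source_atoms=[n for n, _ in src],
                )
                bead_of[(p_idx, j, bead_name)] = bead_id
                local[bead_name] = bead_id
                for node, w in src:
                    if w > 0:
                        node_to_beads.setdefault(node, []).append((bead_id, w))
                bead_id += 1
            # intra-fragment interactions and edges from the target block
            for a, b in block.graph.edges:
                out.add_edge(local[a], local[b])
            for kind in sorted(block.graph.interactions):
                for term in block.graph.interactions[kind]:
                    out.add_interaction(
                        term.replace(particles=tuple(local[x] for x in term.particles))
                    )
            out.citations |= block.citations
            # modification bead edits recorded on the source residue
            key = placement.residues[j - 1]
            _apply_bead_edits(molecule, key, local, out, target_ff)

    # edges between beads sharing a mapped source bond
    for u, v in molecule.edges:
        for bu, wu in node_to_beads.get(u, []):
            for bv, wv in node_to_beads.get(v, []):
                if bu != bv:
                    out.add_edge(bu, bv)
    out.citations |= molecule.citations
    out.graph["source_molecule"] = molecule
    return out


def _inherit_attrs(molecule, src, placement: Placement, j: int) -> dict:
    """Dominant source residue (largest total weight, ties lowest resid)."""
    if not src:
        # coordinate-free bead with no sources: fall back to the scope residue
        key = placement.residues[j - 1]
        chain, resid, icode = key
        probe = {"chain": chain, "resid": resid, "icode": icode}
        return probe
    totals: dict[tuple, float] = {}
    sample: dict[tuple, dict] = {}
    for node, w in src:
        attrs = molecule.nodes[node]
        key = (attrs.get("chain", ""), attrs["resid"], attrs.get("icode", ""))
        totals[key] = totals.get(key, 0.0) + w
        sample.setdefault(key, attrs)
    best = max(totals, key=lambda k: (totals[k], -k[1]))
    attrs = sample[best]
    return {
        "chain": attrs.get("chain", ""), "resid": attrs["resid"],
        "icode": attrs.get("icode", ""), "secstruct": attrs.get("secstruct", "C"),
    }


def _bead_position(molecule, src):
    weighted = [
        (np.asarray(molecule.nodes[n]["position"]), w)
        for n, w in src
        if molecule.nodes[n].get("position") is not None and w > 0
    ]
    n_weighted = sum(1 for n, w in src if w > 0)
    if not weighted:
        if n_weighted:
            return None, "all source atoms lack coordinates; bead has none"
        return None, None  # declared coordinate-free (virtual site etc.)
    total = sum(w for _, w in weighted)
    pos = sum(p * w for p, w in weighted) / total
    if len(weighted) < n_weighted:
        return pos, "position estimated from a subset of source atoms"
    return pos, None


def _apply_bead_edits(molecule, residue_key, local, out, target_ff) -> None:
    mods: list[str] = molecule.graph.get("_residue_mods", {}).get(residue_key, [])
    source_ff_mods = molecule.graph.get("modification_library", {})
    for name in mods:
        mod = source_ff_mods.get(name)
        if mod is None:
            continue
        for bead, key, value in mod.bead_edits:
            node = local.get(bead)
            if node is not None:
                out.nodes[node][key] = value


# ---------------------------------------------------------------------------
# virtual sites

def construct_virtual_sites(
    molecule: MoleculeGraph,
    ledger: Optional[WarningLedger] = None,
) -> None:
    """Compute virtual-site positions from their constructing particles.

    Sites are evaluated in dependency order so sites built on sites work;
    a dependency cycle is an error.  Function type 2 is mass-weighted,
    anything else is the plain centroid.  Virtual sites carry no mass.
    """
    import networkx as nx

    vsites = {
        term.particles[0]: term
        for term in molecule.interactions.get("virtual_site_n", [])
    }
    dep = nx.DiGraph()
    dep.add_nodes_from(vsites)
    for site, term in vsites.items():
        for c in term.particles[1:]:
            if c in vsites:
                dep.add_edge(c, site)
    try:
        order = list(nx.topological_sort(dep))
    except nx.NetworkXUnfeasible as exc:
        raise MappingError("cyclic virtual-site dependencies") from exc
    for site in order:
        term = vsites[site]
        funct = term.parameters[0] if term.parameters else "1"
        points, weights = [], []
        incomplete = False
        for c in term.particles[1:]:
            pos = molecule.nodes[c].get("position")
            if pos is None:
                incomplete = True
                break
            points.append(np.asarray(pos))
            weights.append(
                float(molecule.nodes[c].get("mass") or 1.0) if funct == "2" else 1.0
            )
        if incomplete:
            molecule.nodes[site]["position"] = None
            if ledger is not None:
                ledger.warn(
                    "missing-coordinates",
                    f"virtual site {molecule.nodes[site].get('atom_name')} has a "
                    "coordinate-free constructing particle",
                    atom=molecule.nodes[site].get("atom_name"),
                )
            continue
        w = np.asarray(weights)
        molecule.nodes[site]["position"] = (np.asarray(points) * w[:, None]).sum(0) / w.sum()
        molecule.nodes[site]["mass"] = 0.0
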