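"""Residue identification and repair against canonical blocks.

Each residue of a molecule is compared to the canonical block selected by
its residue name: a maximum common subgraph correspondence (element-aware,
so unreliable atom names do not matter) rewrites atom names to their
canonical form, lists atoms the input lacks, and lists atoms the canonical
block does not describe.  Unexplained extra atoms are then matched against
the force field's *modifications* — protonation states, tautomers, PTMs —
and chain ends receive the default terminal modifications.

Structures without hydrogens are valid inputs (crystal structures): absent
hydrogens in otherwise complete residues are treated as missing-but-
unwarned by default (``strict_h`` restores warnings for them).  Missing
heavy atoms are added back as coordinate-free nodes — repair detects, it
does not rebuild geometry.
"""
from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Any, Optional

import networkx as nx

from .ffdata import Block, ForceField, Modification
from .ledger import WarningLedger
from .molgraph import (
    MoleculeGraph,
    default_node_match,
    maximum_common_correspondence,
    residue_groups,
    subgraph_isomorphisms,
)


class RepairError(ValueError):
    pass


@dataclasses.dataclass
class RepairReport:
    residue: tuple  # (chain, resid, icode)
    resname: str
    correspondence: dict = dataclasses.field(default_factory=dict)  # node -> block atom
    missing_atoms: set[str] = dataclasses.field(default_factory=set)
    extra_atoms: set = dataclasses.field(default_factory=set)  # node ids
    renamed: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    applied_modifications: list[str] = dataclasses.field(default_factory=list)
    recognized: bool = True


def _fast_name_match(molecule: nx.Graph, nodes: list, block: Block) -> Optional[dict]:
    """Identity correspondence when names already agree with the block.

    Valid when every input atom name is a distinct block atom of the same
    element and the induced edge sets agree on the present atoms.
    """
    mapping = {}
    for node in nodes:
        attrs = molecule.nodes[node]
        name = attrs["atom_name"]
        if name not in block.graph or name in mapping.values():
            return None
        belem = (block.graph.nodes[name].get("element") or "").upper()
        ielem = (attrs.get("element") or "").upper()
        if belem and ielem and belem != ielem:
            return None
        mapping[node] = name
    rev = {v: k for k, v in mapping.items()}
    for u, v in combinations(mapping, 2):
        if molecule.has_edge(u, v) != block.graph.has_edge(mapping[u], mapping[v]):
            return None
    # also: no block edge between present atoms may be absent from the input
    for a, b in block.graph.edges:
        if a in rev and b in rev and not molecule.has_edge(rev[a], rev[b]):
            return None
    return mapping


def match_canonical(
    molecule: MoleculeGraph,
    residue_nodes: list,
    block: Block,
    ledger: Optional[WarningLedger] = None,
    strict_h: bool = False,
) -> RepairReport:
    """Compare one residue to its canonical block and repair it in place.

    Atom names of matched atoms are rewritten to the block's names, block
    attributes (element, particle type, charge, mass) are copied onto the
    matched nodes, and missing atoms are added as coordinate-free nodes
    wired up according to the block's edges.
    """
    first = molecule.nodes[residue_nodes[0]]
    report = RepairReport(
        residue=(first.get("chain", ""), first["resid"], first.get("icode", "")),
        resname=block.name,
    )
    sub = molecule.subgraph(residue_nodes)
    corr = _fast_name_match(sub, residue_nodes, block)
    if corr is None:
        # element-graph maximum common subgraph: block is the pattern so the
        # correspondence speaks canonical names
        rev = maximum_common_correspondence(
            block.graph, sub, node_match=default_node_match, name_key="atom_name"
        )
        corr = {node: bname for bname, node in rev.items()}
    report.correspondence = dict(corr)

    matched_block_atoms = set(corr.values())
    for node, bname in corr.items():
        attrs = molecule.nodes[node]
        old = attrs["atom_name"]
        if old != bname:
            report.renamed.append((old, bname))
            attrs["atom_name"] = bname
        battrs = block.graph.nodes[bname]
        attrs["element"] = battrs.get("element") or attrs.get("element", "")
        for key in ("particle_type", "charge", "mass"):
            if battrs.get(key) is not None:
                attrs[key] = battrs[key]
        attrs["resname"] = block.name

    # extra atoms: present in input, not described by the block
    report.extra_atoms = {n for n in residue_nodes if n not in corr}

    # missing atoms: described by the block, absent from the input
    chain, resid, icode = report.residue
    rev_corr = {v: k for k, v in corr.items()}
    new_nodes: dict[str, Any] = {}
    for bname in block.graph.nodes:
        if bname in matched_block_atoms:
            continue
        is_h = (block.graph.nodes[bname].get("element") or "").upper() == "H"
        if is_h and not strict_h:
            continue  # crystal structures legitimately lack hydrogens
        report.missing_atoms.add(bname)
        node_id = max(molecule.nodes) + 1 if len(molecule) else 0
        battrs = block.graph.nodes[bname]
        molecule.add_node(
            node_id,
            atom_name=bname, resname=block.name, resid=resid, chain=chain,
            icode=icode, element=battrs.get("element", ""),
            particle_type=battrs.get("particle_type"),
            charge=battrs.get("charge"), mass=battrs.get("mass"),
            position=None,
        )
        new_nodes[bname] = node_id
        rev_corr[bname] = node_id
        if ledger is not None:
            ledger.warn(
                "missing-atoms",
                f"residue {block.name} {chain}{resid} misses atom {bname}; "
                "added without coordinates",
                chain=chain, resid=resid, atom=bname,
            )
    for a, b in block.graph.edges:
        if (a in new_nodes or b in new_nodes) and a in rev_corr and b in rev_corr:
            molecule.add_edge(rev_corr[a], rev_corr[b])
    return report


def repair_molecule(
    molecule: MoleculeGraph,
    forcefield: ForceField,
    ledger: WarningLedger,
    strict_h: bool = False,
) -> dict[tuple, RepairReport]:
    """Run canonical comparison for every residue of *molecule*.

    Residue names found in the force field's alias table (CHARMM/AMBER
    protonation-state names like HSP or HIP) are first translated to their
    canonical block plus preset modifications — the direct route for
    correctly named non-default states.  Unknown residue names leave the
    residue untouched apart from an ``unrecognized-residue`` warning.
    """
    reports: dict[tuple, RepairReport] = {}
    for key, nodes in residue_groups(molecule).items():
        chain, resid, icode = key
        resname = molecule.nodes[nodes[0]]["resname"]
        block_name, preset_mods = forcefield.aliases.get(resname, (resname, ()))
        block = forcefield.blocks.get(block_name)
        if block is None:
            ledger.warn(
                "unrecognized-residue",
                f"residue name {resname!r} not in force field; left unmodified",
                chain=chain, resid=resid, resname=resname,
            )
            reports[key] = RepairReport(residue=key, resname=resname, recognized=False)
            continue
        report = match_canonical(molecule, nodes, block, ledger, strict_h=strict_h)
        for n in nodes:  # extras inherit the canonical residue name too
            molecule.nodes[n]["resname"] = block.name
        report.applied_modifications.extend(preset_mods)
        reports[key] = report
    molecule.graph["repair_reports"] = reports
    return reports


# ---------------------------------------------------------------------------
# modification resolution (route b: unexpected atoms explained by deltas)

def _mod_pattern(mod: Modification) -> nx.Graph:
    g = nx.Graph()
    for name, d in mod.atoms.items():
        g.add_node(name, atom_name=name, element=d["element"], role=d["role"])
    g.add_edges_from(mod.edges)
    return g


def _find_mod_embedding(
    molecule: MoleculeGraph,
    residue_nodes: list,
    extras: set,
    mod: Modification,
) -> Optional[dict]:
    """Embed a modification into the residue: anchors onto canonical atoms
    (by canonical name), added atoms onto extra atoms (by element)."""
    pattern = _mod_pattern(mod)
    sub = molecule.subgraph(residue_nodes)

    def node_match(p: dict, t: dict) -> bool:
        node = t.get("_node")
        if p["role"] == "anchor":
            return t.get("atom_name") == p["atom_name"] and node not in extras
        return node in extras and default_node_match(p, t)

    # tag target attrs with their node id so the predicate can see membership
    tagged = nx.Graph()
    for n in sub.nodes:
        tagged.add_node(n, _node=n, **sub.nodes[n])
    tagged.add_edges_from(sub.edges)
    for corr in subgraph_isomorphisms(pattern, tagged, node_match):
        return corr
    return None


def resolve_modifications(
    molecule: MoleculeGraph,
    reports: dict[tuple, RepairReport],
    forcefield: ForceField,
    ledger: WarningLedger,
) -> dict[tuple, list[str]]:
    """Explain every residue's extra atoms as a set of modifications.

    The chosen set must cover the extra atoms exactly; among valid covers
    the one with the fewest modifications wins, ties broken by name order.
    Extra atoms no combination explains raise an ``unexpected-atoms``
    warning and flag the residue.
    """
    applied: dict[tuple, list[str]] = {}
    groups = residue_groups(molecule)
    for key, report in reports.items():
        if not report.recognized:
            continue
        nodes = groups.get(key, [])
        extras = set(report.extra_atoms)
        # route (a) presets recorded during repair are applied first
        for mod_name in list(report.applied_modifications):
            mod = forcefield.modifications.get(mod_name)
            if mod is not None:
                _apply_modification(molecule, nodes, mod, embedding=None)
        if not extras:
            applied[key] = list(report.applied_modifications)
            continue
        candidates: list[tuple[str, Modification, dict, frozenset]] = []
        for name in sorted(forcefield.modifications):
            mod = forcefield.modifications[name]
            if report.resname not in mod.base_resnames and "*" not in mod.base_resnames:
                continue
            if not mod.added_nodes:
                continue
            emb = _find_mod_embedding(molecule, nodes, extras, mod)
            if emb is not None:
                covered = frozenset(emb[a] for a in mod.added_nodes)
                candidates.append((name, mod, emb, covered))
        chosen = _exact_cover(extras, candidates)
        if chosen is None:
            chain, resid, _ = key
            names = sorted(molecule.nodes[n]["atom_name"] for n in extras)
            ledger.warn(
                "unexpected-atoms",
                f"residue {report.resname} {chain}{resid} has unexplained atoms: "
                + ", ".join(names),
                chain=chain, resid=resid, atoms=names,
            )
            for n in extras:
                molecule.nodes[n]["unexpected"] = True
        else:
            for name, mod, emb, _ in chosen:
                _apply_modification(molecule, nodes, mod, embedding=emb)
                if name not in report.applied_modifications:
                    report.applied_modifications.append(name)
        applied[key] = list(report.applied_modifications)
    return applied


def _exact_cover(extras: set, candidates: list) -> Optional[list]:
    """Smallest subset of candidates whose added atoms partition *extras*.

    Candidate lists are tiny (a residue carries at most a few deltas), so
    subset enumeration in size order is plenty.
    """
    for size in range(1, len(candidates) + 1):
        for combo in combinations(candidates, size):
            covered: set = set()
            ok = True
            for _, _, _, cov in combo:
                if covered & cov:
                    ok = False
                    break
                covered |= cov
            if ok and covered == extras:
                return list(combo)
    return None


def _apply_modification(
    molecule: MoleculeGraph,
    residue_nodes: list,
    mod: Modification,
    embedding: Optional[dict],
) -> None:
    by_name = {molecule.nodes[n]["atom_name"]: n for n in residue_nodes}
    if embedding is not None:
        for added in mod.added_nodes:
            node = embedding[added]
            attrs = molecule.nodes[node]
            attrs["atom_name"] = added
            attrs["modification"] = mod.name
            bead = mod.extra_to_bead.get(added)
            if bead is not None:
                attrs["mapped_bead"] = bead
            by_name[added] = node
    for atom, key, value in mod.attribute_edits:
        node = by_name.get(atom)
        if node is not None:
            molecule.nodes[node][key] = value
    # record residue-level modification for the mapping stage
    for n in residue_nodes:
        mods = molecule.nodes[n].setdefault("modifications", [])
        if mod.name not in mods:
            mods.append(mod.name)
    molecule.citations |= mod.citations


# ---------------------------------------------------------------------------
# termini

def assign_termini(
    molecule: MoleculeGraph,
    forcefield: ForceField,
    ledger: WarningLedger,
    nter: Optional[str] = None,
    cter: Optional[str] = None,
) -> dict[tuple, list[str]]:
    """Apply default terminal modifications at degree-deficient chain ends.

    A protein residue whose link-in atom (``nter_atom``, typically N) has no
    bond leaving the residue is an amino terminus; likewise ``cter_atom``
    (C) for the carboxy terminus.  Cyclic chains have neither; a
    single-residue molecule has both on the same residue.
    """
    protein = set(forcefield.variable("protein_resnames"))
    n_atom = forcefield.scalar("nter_atom", "N")
    c_atom = forcefield.scalar("cter_atom", "C")
    nter = nter or forcefield.scalar("nter_mod")
    cter = cter or forcefield.scalar("cter_mod")
    reports = molecule.graph.get("repair_reports", {})
    applied: dict[tuple, list[str]] = {}
    for key, nodes in residue_groups(molecule).items():
        resname = molecule.nodes[nodes[0]]["resname"]
        if resname not in protein:
            continue
        by_name = {molecule.nodes[n]["atom_name"]: n for n in nodes}
        here = set(nodes)
        for atom, mod_name in ((n_atom, nter), (c_atom, cter)):
            node = by_name.get(atom)
            if node is None:
                continue
            external = [m for m in molecule.adj[node] if m not in here]
            if external:
                continue
            mod = forcefield.modifications.get(mod_name)
            if mod is None:
                ledger.warn(
                    "unrecognized-residue",
                    f"terminus at {resname} {key[0]}{key[1]} matches no modification "
                    f"{mod_name!r}",
                    chain=key[0], resid=key[1],
                )
                continue
            _apply_modification(molecule, nodes, mod, embedding=None)
            applied.setdefault(key, []).append(mod_name)
            if key in reports:
                reports[key].applied_modifications.append(mod_name)
    return applied


# ---------------------------------------------------------------------------
# secondary structure

def annotate_secondary_structure(
    molecule: MoleculeGraph,
    ss: Optional[str],
    forcefield: ForceField,
    ledger: WarningLedger,
) -> None:
    """Attach one secondary-structure letter per protein residue.

    ``ss`` is a per-residue string over the molecule's protein residues in
    (chain, resid) order, or ``"auto"``.  No external annotation tool is
    bundled: ``auto`` degrades to all-coil but first demands complete
    backbone coordinates, mirroring the way structure-based assignment
    fails on gapped backbones.  Non-protein residues are annotated coil.
    """
    protein = set(forcefield.variable("protein_resnames"))
    backbone = forcefield.variable("backbone", ["N", "CA", "C"])
    keys = [
        (key, nodes)
        for key, nodes in residue_groups(molecule).items()
        if molecule.nodes[nodes[0]]["resname"] in protein
    ]
    if ss == "auto":
        for key, nodes in keys:
            by_name = {molecule.nodes[n]["atom_name"]: n for n in nodes}
            for atom in backbone:
                node = by_name.get(atom)
                if node is None or molecule.nodes[node].get("position") is None:
                    ledger.warn(
                        "ss-failure",
                        f"cannot assign secondary structure: backbone atom {atom} of "
                        f"{key[0]}{key[1]} has no coordinates",
                        chain=key[0], resid=key[1], atom=atom,
                    )
                    raise RepairError(
                        "cannot assign secondary structure: missing backbone coordinates"
                    )
        letters = "C" * len(keys)
    elif ss is None:
        letters = "C" * len(keys)
    else:
        if len(ss) != len(keys):
            raise RepairError(
                f"secondary-structure string has {len(ss)} letters for "
                f"{len(keys)} protein residues"
            )
        letters = ss
    for (key, nodes), letter in zip(keys, letters):
        for n in nodes:
            molecule.nodes[n]["secstruct"] = letter
    for node in molecule.nodes:
        molecule.nodes[node].setdefault("secstruct", "C")
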