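"""Reading and writing atomistic/CG structures; bond inference; partitioning.

Structures are read into a flat :class:`StructureRecord`; bonds are then
inferred by one of three strategies — interatomic distances against covalent
radii, atom names matched against force-field blocks and links, or explicit
CONECT records — and the bonded graph is partitioned into molecules: every
set of particles connected by bonds is one molecule, so two chains joined by
a disulfide bridge become a single molecule while an unbonded cofactor stays
separate.

All positions are handled in nm internally (PDB files are Å on disk).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .ffdata import ForceField, guess_element
from .ledger import WarningLedger
from .molgraph import MoleculeGraph, SystemOfMolecules, connected_components

#: Cordero covalent radii, nm.
COVALENT_RADII = {
    "H": 0.031, "C": 0.076, "N": 0.071, "O": 0.066, "F": 0.057,
    "P": 0.107, "S": 0.105, "CL": 0.102, "BR": 0.120, "SE": 0.120,
    "NA": 0.166, "MG": 0.141, "K": 0.203, "CA": 0.176, "FE": 0.132,
    "ZN": 0.122,
}
DEFAULT_RADIUS = 0.077
#: conventional tolerance on the sum of covalent radii
DEFAULT_BOND_SCALE = 1.2


class StructureError(ValueError):
    pass


@dataclasses.dataclass
class Particle:
    serial: int
    atom_name: str
    resname: str
    resid: int
    chain: str = ""
    icode: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    element: str = ""
    position: Optional[np.ndarray] = None  # nm
    hetero: bool = False

    def radius(self) -> float:
        return COVALENT_RADII.get(self.element.upper(), DEFAULT_RADIUS)


@dataclasses.dataclass
class StructureRecord:
    particles: list[Particle] = dataclasses.field(default_factory=list)
    conect_pairs: set[tuple[int, int]] = dataclasses.field(default_factory=set)
    model_index: int = 0

    def serial_to_index(self) -> dict[int, int]:
        return {p.serial: i for i, p in enumerate(self.particles)}


# ---------------------------------------------------------------------------
# PDB

def read_pdb(text: str) -> StructureRecord:
    """Parse PDB text (fixed columns). First MODEL only; CONECT symmetrized;
    alternate locations resolved to the highest-occupancy conformer
    (ties: alphabetically first altloc)."""
    particles: list[Particle] = []
    conect: set[tuple[int, int]] = set()
    model_seen = 0
    in_first_model = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            model_seen += 1
            in_first_model = model_seen == 1
            continue
        if record == "ENDMDL":
            in_first_model = False
            continue
        if record in ("ATOM", "HETATM") and in_first_model:
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:21].strip()
                chain = line[21].strip()
                resid = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise StructureError(
                    f"line {lineno}: unparseable coordinate record: {line!r}"
                ) from exc
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 77 else ""
            if not element:
                element = guess_element(name)
            particles.append(
                Particle(
                    serial=serial, atom_name=name, resname=resname, resid=resid,
                    chain=chain, icode=icode, altloc=altloc, occupancy=occupancy,
                    element=element,
                    position=np.array([x, y, z]) / 10.0,  # Angstrom -> nm
                    hetero=record == "HETATM",
                )
            )
        elif record == "CONECT":
            serials = []
            for start in range(6, min(len(line), 31), 5):
                field = line[start:start + 5].strip()
                if field:
                    serials.append(int(field))
            for other in serials[1:]:
                pair = tuple(sorted((serials[0], other)))
                if pair[0] != pair[1]:
                    conect.add(pair)
    particles = _resolve_altlocs(particles)
    if not particles:
        raise StructureError("no atoms found in PDB input")
    serials = [p.serial for p in particles]
    if len(set(serials)) != len(serials):
        raise StructureError("duplicate atom serial numbers within one model")
    return StructureRecord(particles=particles, conect_pairs=conect)


def _resolve_altlocs(particles: list[Particle]) -> list[Particle]:
    groups: dict[tuple, list[Particle]] = {}
    order: list[tuple] = []
    for p in particles:
        key = (p.chain, p.resid, p.icode, p.resname, p.atom_name)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(p)
    resolved = []
    for key in order:
        group = groups[key]
        # highest occupancy wins; ties -> alphabetically first altloc
        resolved.append(max(group, key=lambda p: (p.occupancy, _neg_alt(p.altloc))))
    resolved.sort(key=lambda p: p.serial)
    return resolved


def _neg_alt(altloc: str) -> tuple:
    # larger = preferred; empty altloc beats lettered ones, 'A' beats 'B'
    return tuple(-ord(c) for c in altloc) if altloc else (1,)


def write_pdb(
    system: Union[SystemOfMolecules, MoleculeGraph],
    path: Union[str, Path],
    allow_missing: bool = False,
    ledger: Optional[WarningLedger] = None,
    write_conect: bool = False,
) -> None:
    """Write molecules as PDB (positions in Å; missing positions as the
    (0,0,0) sentinel with a warning when *allow_missing* is set)."""
    molecules = system.molecules if isinstance(system, SystemOfMolecules) else [system]
    lines: list[str] = []
    serial = 0
    conect: list[tuple[int, int]] = []
    for mol in molecules:
        serial_of: dict = {}
        for node in sorted(mol.nodes):
            attrs = mol.nodes[node]
            serial += 1
            serial_of[node] = serial
            pos = attrs.get("position")
            pos = _checked_position(pos, attrs, allow_missing, ledger)
            x, y, z = (np.asarray(pos) * 10.0).tolist()
            element = (attrs.get("element") or "")[:2]
            name = attrs["atom_name"]
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            lines.append(
                f"ATOM  {serial:>5d} {name_field}{'':1s}{attrs['resname']:<4.4s}"
                f"{(attrs.get('chain') or 'A')[:1]}{attrs['resid']:>4d}{attrs.get('icode', ''):1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
        if write_conect:
            for u, v in sorted(tuple(sorted(e)) for e in mol.edges):
                conect.append((serial_of[u], serial_of[v]))
        lines.append("TER")
    for u, v in conect:
        lines.append(f"CONECT{u:>5d}{v:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GRO

def read_gro(text: str) -> StructureRecord:
    lines = text.replace("\r\n", "\n").split("\n")
    if len(lines) < 3:
        raise StructureError("truncated gro file")
    try:
        natoms = int(lines[1].strip())
    except ValueError as exc:
        raise StructureError(f"bad atom count line: {lines[1]!r}") from exc
    particles = []
    for i in range(natoms):
        line = lines[2 + i]
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise StructureError(f"line {3 + i}: unparseable gro atom line") from exc
        particles.append(
            Particle(
                serial=serial, atom_name=name, resname=resname, resid=resid,
                element=guess_element(name), position=np.array([x, y, z]),
            )
        )
    if not particles:
        raise StructureError("no atoms found in gro input")
    # gro serials wrap at 100000; renumber to keep them unique
    for i, p in enumerate(particles):
        p.serial = i + 1
    return StructureRecord(particles=particles)


def write_gro(
    system: Union[SystemOfMolecules, MoleculeGraph],
    path: Union[str, Path],
    allow_missing: bool = False,
    ledger: Optional[WarningLedger] = None,
    title: str = "generated by cgweaver",
) -> None:
    """Write molecules as GRO (nm, 3 decimals, box line from the bounding box)."""
    molecules = system.molecules if isinstance(system, SystemOfMolecules) else [system]
    rows = []
    positions = []
    for mol in molecules:
        for node in sorted(mol.nodes):
            attrs = mol.nodes[node]
            pos = _checked_position(attrs.get("position"), attrs, allow_missing, ledger)
            positions.append(pos)
            rows.append((attrs["resid"], attrs["resname"], attrs["atom_name"], pos))
    lines = [title, f"{len(rows):5d}"]
    for i, (resid, resname, name, pos) in enumerate(rows, start=1):
        x, y, z = pos
        lines.append(
            f"{resid % 100000:5d}{resname:<5.5s}{name:>5.5s}{i % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    arr = np.array(positions, dtype=float)
    span = arr.max(axis=0) - arr.min(axis=0) + 2.0 if len(arr) else np.ones(3)
    lines.append(f"{span[0]:10.5f}{span[1]:10.5f}{span[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _checked_position(pos, attrs, allow_missing: bool, ledger: Optional[WarningLedger]):
    if pos is not None and np.all(np.isfinite(pos)):
        return np.asarray(pos, dtype=float)
    if not allow_missing:
        raise StructureError(
            f"particle {attrs.get('atom_name')} of residue "
            f"{attrs.get('resname')}{attrs.get('resid')} has no position "
            "(pass allow_missing to write the sentinel)"
        )
    if ledger is not None:
        ledger.warn(
            "missing-coordinates",
            "particle written with sentinel coordinates (0,0,0)",
            atom=attrs.get("atom_name"), resname=attrs.get("resname"),
            resid=attrs.get("resid"),
        )
    return np.zeros(3)


# ---------------------------------------------------------------------------
# bond inference

def infer_bonds(
    record: StructureRecord,
    strategy: str = "auto",
    forcefield: Optional[ForceField] = None,
    scale: float = DEFAULT_BOND_SCALE,
    ledger: Optional[WarningLedger] = None,
) -> list[tuple[int, int]]:
    """Infer bonded edges between particles (returned as index pairs).

    Strategies: ``distance`` (covalent-radius criterion, hydrogens capped
    at one bond), ``names`` (block + link lookup by atom names; requires
    *forcefield*), ``conect`` (explicit records only) and ``auto``
    (CONECT if present, else distance when positions are complete, else
    names).
    """
    if strategy == "auto":
        if record.conect_pairs:
            strategy = "conect"
        elif all(p.position is not None for p in record.particles):
            strategy = "distance"
        else:
            strategy = "names"
    if strategy == "conect":
        s2i = record.serial_to_index()
        return sorted(
            tuple(sorted((s2i[a], s2i[b])))
            for a, b in record.conect_pairs
            if a in s2i and b in s2i
        )
    if strategy == "distance":
        return _bonds_by_distance(record, scale)
    if strategy == "names":
        if forcefield is None:
            raise ValueError("names strategy requires a force field")
        return _bonds_by_names(record, forcefield, ledger)
    raise ValueError(f"unknown bond inference strategy: {strategy!r}")


def _bonds_by_distance(record: StructureRecord, scale: float) -> list[tuple[int, int]]:
    missing = [
        f"{p.atom_name}/{p.resname}{p.resid}"
        for p in record.particles
        if p.position is None
    ]
    if missing:
        raise StructureError(
            "distance-based bond inference needs positions for all particles; "
            "missing: " + ", ".join(missing[:10])
        )
    pos = np.array([p.position for p in record.particles])
    radii = np.array([p.radius() for p in record.particles])
    tree = cKDTree(pos)
    max_cut = scale * 2 * radii.max()
    edges = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        cutoff = scale * (radii[i] + radii[j])
        if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
            edges.append((i, j))
    # hydrogens bond only to their closest partner
    is_h = [p.element.upper() == "H" for p in record.particles]
    best: dict[int, tuple[float, tuple[int, int]]] = {}
    kept = []
    for i, j in edges:
        h = i if is_h[i] else (j if is_h[j] else None)
        if h is None:
            kept.append((i, j))
            continue
        if is_h[i] and is_h[j]:
            continue  # no H-H bonds
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if h not in best or d < best[h][0]:
            best[h] = (d, (i, j))
    kept.extend(pair for _, pair in best.values())
    return sorted(tuple(sorted(e)) for e in kept)


def _residue_runs(record: StructureRecord):
    """Group particle indices by residue, preserving file order."""
    runs: list[tuple[tuple, list[int]]] = []
    seen: dict[tuple, int] = {}
    for i, p in enumerate(record.particles):
        key = (p.chain, p.resid, p.icode)
        if key not in seen:
            seen[key] = len(runs)
            runs.append((key, []))
        runs[seen[key]][1].append(i)
    return runs


def _bonds_by_names(
    record: StructureRecord,
    ff: ForceField,
    ledger: Optional[WarningLedger],
) -> list[tuple[int, int]]:
    edges: list[tuple[int, int]] = []
    runs = _residue_runs(record)
    # intra-residue bonds from the block matching the residue name
    for (chain, resid, icode), indices in runs:
        resname = record.particles[indices[0]].resname
        block_name = ff.aliases.get(resname, (resname, ()))[0]
        block = ff.blocks.get(block_name)
        if block is None:
            if ledger is not None:
                ledger.warn(
                    "unrecognized-residue",
                    f"no block for residue {resname!r}; left unbonded internally",
                    resname=resname, resid=resid, chain=chain,
                )
            continue
        by_name = {record.particles[i].atom_name: i for i in indices}
        for a, b in block.graph.edges:
            if a in by_name and b in by_name:
                edges.append(tuple(sorted((by_name[a], by_name[b]))))
    # inter-residue bonds from two-node links with a contiguous offset window
    pair_links = []
    for link in ff.links:
        nodes = list(link.pattern.nodes(data=True))
        if len(nodes) != 2:
            continue
        offsets = {d["offset"] for _, d in nodes}
        if None in offsets:
            continue
        if max(offsets) - min(offsets) != 1:
            continue
        lo = min(offsets)
        spec = sorted(
            ((d["offset"] - lo, d["atom_name"], d["matchers"].get("resname"))
             for _, d in nodes),
        )
        pair_links.append(spec)
    for k in range(len(runs) - 1):
        (chain_a, resid_a, _), idx_a = runs[k]
        (chain_b, resid_b, _), idx_b = runs[k + 1]
        if chain_a != chain_b or resid_b - resid_a != 1:
            continue
        res = (
            {record.particles[i].atom_name: i for i in idx_a},
            {record.particles[i].atom_name: i for i in idx_b},
        )
        resnames = (record.particles[idx_a[0]].resname, record.particles[idx_b[0]].resname)
        for spec in pair_links:
            (o1, name1, rn1), (o2, name2, rn2) = spec
            if rn1 and resnames[o1] not in rn1:
                continue
            if rn2 and resnames[o2] not in rn2:
                continue
            if name1 in res[o1] and name2 in res[o2]:
                edges.append(tuple(sorted((res[o1][name1], res[o2][name2]))))
    return sorted(set(edges))


# ---------------------------------------------------------------------------
# partitioning

def to_system(
    record: StructureRecord,
    edges: Iterable[tuple[int, int]],
    forcefield: Optional[ForceField] = None,
) -> SystemOfMolecules:
    """Partition particles + inferred edges into an ordered molecule system."""
    graph = MoleculeGraph()
    for i, p in enumerate(record.particles):
        graph.add_node(
            i,
            atom_name=p.atom_name, resname=p.resname, resid=p.resid,
            chain=p.chain, icode=p.icode, element=p.element,
            position=None if p.position is None else np.asarray(p.position),
            serial=p.serial, hetero=p.hetero,
        )
    graph.add_edges_from(edges)
    molecules = connected_components(graph)
    system = SystemOfMolecules(molecules=molecules)
    if forcefield is not None:
        system.forcefield_name = forcefield.name
        for mol in molecules:
            mol.forcefield_name = forcefield.name
    return system
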