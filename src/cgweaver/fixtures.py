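"""Deterministic generators for synthetic test structures.

Every generator produces a chemically consistent heavy-atom structure with
idealized geometry: bonded pairs sit within the covalent-radius criterion
used by distance-based bond inference, non-bonded pairs sit safely outside
it, so the inferred graph reproduces the intended connectivity exactly.
Alongside the structure a ground-truth *manifest* records residues, chains,
disulfides, the expected molecule count, the intended bond list and — for
corrupted variants — exactly which residues were damaged and how, so
oracle tests can check that the pipeline flags all of them and nothing
else.

Geometry is idealized (planar zigzags, regular rings); the fixtures make
topological claims, not physical ones.
"""
from __future__ import annotations

import dataclasses
import json
import math
from typing import Any, Optional

import numpy as np

from .structure_io import Particle, StructureRecord

KINDS = (
    "linear_peptide",
    "cyclic_peptide",
    "two_chain_disulfide",
    "crown_ether",
    "branched_polyethylene",
    "idr_tail_protein",
)
CORRUPTIONS = (
    "drop_atoms",
    "drop_coordinates",
    "rename_atoms",
    "swap_elements",
    "perturb_distances",
    "add_atom",
)

#: default residue spacing along the backbone, nm
RESIDUE_SPACING = 0.36


def _pentagon(center: np.ndarray, radius: float, e: float, names: list[str]):
    """Regular pentagon in the z=center.z plane; vertex 0 points +y*e."""
    out = {}
    for k, name in enumerate(names):
        theta = math.radians(90 - 72 * k)
        out[name] = center + np.array(
            [radius * math.cos(theta), e * radius * math.sin(theta), 0.0]
        )
    return out


def _hexagon(center: np.ndarray, radius: float, e: float, names: list[str]):
    out = {}
    for k, name in enumerate(names):
        theta = math.radians(90 - 60 * k)
        out[name] = center + np.array(
            [radius * math.cos(theta), e * radius * math.sin(theta), 0.0]
        )
    return out


def _amino_atoms(resname: str, e: float) -> dict[str, np.ndarray]:
    """Heavy atoms (plus canonical ring hydrogens) of one residue, local frame."""
    atoms = {
        "N": np.array([0.00, 0.05 * e, 0.0]),
        "CA": np.array([0.12, -0.05 * e, 0.0]),
        "C": np.array([0.26, 0.0, 0.0]),
        "O": np.array([0.26, 0.0, 0.13]),
    }
    if resname == "GLY":
        return atoms
    cb = np.array([0.12, -0.19 * e, -0.10])
    atoms["CB"] = cb
    if resname == "ALA":
        return atoms
    if resname == "SER":
        atoms["OG"] = cb + np.array([0.0, -0.13 * e, -0.05])
        return atoms
    if resname == "CYS":
        atoms["SG"] = cb + np.array([0.0, -0.17 * e, -0.05])
        return atoms
    if resname in ("HIS", "HISD", "HIS:HP"):
        cg = cb + np.array([0.0, -0.14 * e, 0.0])
        atoms["CG"] = cg
        r = 0.14 / (2 * math.sin(math.pi / 5))
        center = cg + np.array([0.0, -r * e, 0.0])
        ring = _pentagon(center, r, e, ["CG", "ND1", "CE1", "NE2", "CD2"])
        atoms.update({k: v for k, v in ring.items() if k != "CG"})
        # ring protons, radially outward from the ring centre
        protons = {"HIS": ["HE2"], "HISD": ["HD1"], "HIS:HP": ["HE2", "HD1"]}[resname]
        site = {"HE2": "NE2", "HD1": "ND1"}
        for hname in protons:
            u = ring[site[hname]] - center
            atoms[hname] = ring[site[hname]] + 0.10 * u / np.linalg.norm(u)
        return atoms
    if resname in ("TYR", "TYR:P"):
        cg = cb + np.array([0.0, -0.14 * e, 0.0])
        atoms["CG"] = cg
        center = cg + np.array([0.0, -0.14 * e, 0.0])
        ring = _hexagon(center, 0.14, e, ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"])
        atoms.update({k: v for k, v in ring.items() if k != "CG"})
        u = (ring["CZ"] - center) / np.linalg.norm(ring["CZ"] - center)
        atoms["OH"] = ring["CZ"] + 0.135 * u
        if resname == "TYR:P":
            p = atoms["OH"] + 0.16 * u
            atoms["P"] = p
            atoms["O1P"] = p + 0.15 * u
            atoms["O2P"] = p + np.array([0.0, 0.0, 0.15])
            atoms["O3P"] = p + np.array([0.0, 0.0, -0.15])
        return atoms
    raise ValueError(f"fixture generator knows no residue {resname!r}")


_AMINO_BONDS = {
    "GLY": [("N", "CA"), ("CA", "C"), ("C", "O")],
    "ALA": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")],
    "SER": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "OG")],
    "CYS": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "SG")],
    "HIS": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"), ("NE2", "CD2"),
            ("CD2", "CG"), ("NE2", "HE2")],
    "HISD": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
             ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"), ("NE2", "CD2"),
             ("CD2", "CG"), ("ND1", "HD1")],
    "TYR": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"), ("CZ", "CE2"),
            ("CE2", "CD2"), ("CD2", "CG"), ("CZ", "OH")],
}
# structure variants carrying a non-default protonation state or PTM;
# "HIS:HP" / "HSP" = protonated His written with the default / CHARMM name,
# "TYR:P" = phosphotyrosine written as plain TYR plus the phosphate atoms
_AMINO_BONDS["HIS:HP"] = _AMINO_BONDS["HIS"] + [("ND1", "HD1")]
_AMINO_BONDS["TYR:P"] = _AMINO_BONDS["TYR"] + [
    ("OH", "P"), ("P", "O1P"), ("P", "O2P"), ("P", "O3P"),
]
_VARIANT_GEOMETRY = {"HSP": "HIS:HP"}
_VARIANT_RESNAME = {"HIS:HP": "HIS", "TYR:P": "TYR"}

_ELEMENT_OF = {"N": "N", "O": "O", "S": "S", "C": "C", "H": "H", "P": "P"}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF[atom_name[0]]


@dataclasses.dataclass
class FixtureSpec:
    kind: str
    n_residues: int = 5
    sequence: Optional[list[str]] = None
    corruption: Optional[str] = None
    n_corrupt: int = 1
    seed: int = 0
    # two_chain_disulfide parameters
    chain_a: Optional[list[str]] = None
    chain_b: Optional[list[str]] = None
    # crown ether / polymer sizes
    n_repeat: int = 6
    n_linear_head: int = 2
    n_branched: int = 3
    n_linear_tail: int = 2
    # idr_tail_protein
    n_tail: int = 4
    n_core: int = 8

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.corruption is not None and self.corruption not in CORRUPTIONS:
            raise ValueError(f"unknown corruption {self.corruption!r}")
        if self.kind == "cyclic_peptide" and (self.sequence is None and self.n_residues < 3):
            raise ValueError("cyclic peptide needs at least 3 residues")
        if self.kind == "crown_ether" and self.n_repeat < 3:
            raise ValueError("cyclic crown ether needs at least 3 repeat units")


_DEFAULT_CYCLE = ["GLY", "ALA"]
_DEFAULT_SEQ = ["ALA", "GLY", "SER", "CYS", "TYR", "HIS", "ALA", "GLY"]


class _Builder:
    def __init__(self) -> None:
        self.particles: list[Particle] = []
        self.bonds: list[tuple[int, int]] = []  # serial pairs
        self.residues: list[dict[str, Any]] = []
        self._index: dict[tuple[str, int, str], int] = {}

    def add_residue(self, chain: str, resid: int, resname: str,
                    atoms: dict[str, np.ndarray], bonds) -> None:
        serial_of = {}
        for name in atoms:
            serial = len(self.particles) + 1
            serial_of[name] = serial
            self.particles.append(
                Particle(
                    serial=serial, atom_name=name, resname=resname, resid=resid,
                    chain=chain, element=_element(name),
                    position=np.asarray(atoms[name], dtype=float),
                )
            )
            self._index[(chain, resid, name)] = serial
        for a, b in bonds:
            self.bonds.append((serial_of[a], serial_of[b]))
        self.residues.append(
            {"chain": chain, "resid": resid, "resname": resname,
             "atoms": list(atoms)}
        )

    def serial(self, chain: str, resid: int, atom: str) -> int:
        return self._index[(chain, resid, atom)]

    def bond(self, chain_a: str, resid_a: int, atom_a: str,
             chain_b: str, resid_b: int, atom_b: str) -> None:
        self.bonds.append(
            (self.serial(chain_a, resid_a, atom_a), self.serial(chain_b, resid_b, atom_b))
        )


def _build_linear_chain(builder: _Builder, chain: str, sequence: list[str],
                        origin: np.ndarray, start_resid: int = 1) -> None:
    for i, entry in enumerate(sequence):
        geometry = _VARIANT_GEOMETRY.get(entry, entry)
        resname = _VARIANT_RESNAME.get(entry, entry)
        e = 1.0 if i % 2 == 0 else -1.0
        local = _amino_atoms(geometry, e)
        shifted = {k: v + origin + np.array([i * RESIDUE_SPACING, 0, 0])
                   for k, v in local.items()}
        builder.add_residue(chain, start_resid + i, resname, shifted,
                            _AMINO_BONDS[geometry])
        if i > 0:
            builder.bond(chain, start_resid + i - 1, "C", chain, start_resid + i, "N")


def _build_cyclic_peptide(builder: _Builder, sequence: list[str]) -> None:
    """Backbone atoms evenly on a circle; O outward, CB inward (GLY/ALA only)."""
    for resname in sequence:
        if resname not in ("GLY", "ALA"):
            raise ValueError("cyclic peptide fixture supports GLY/ALA residues")
    n = len(sequence)
    n_bb = 3 * n
    radius = 0.145 / (2 * math.sin(math.pi / n_bb))
    def ring_pos(k: int, extra_r: float = 0.0) -> np.ndarray:
        theta = 2 * math.pi * k / n_bb
        r = radius + extra_r
        return np.array([r * math.cos(theta), r * math.sin(theta), 0.0])
    for i, resname in enumerate(sequence):
        atoms = {
            "N": ring_pos(3 * i),
            "CA": ring_pos(3 * i + 1),
            "C": ring_pos(3 * i + 2),
            "O": ring_pos(3 * i + 2, 0.13),
        }
        if resname == "ALA":
            atoms["CB"] = ring_pos(3 * i + 1, -0.148)
        builder.add_residue("A", i + 1, resname, atoms, _AMINO_BONDS[resname])
        if i > 0:
            builder.bond("A", i, "C", "A", i + 1, "N")
    builder.bond("A", n, "C", "A", 1, "N")  # ring closure


def _build_crown_ether(builder: _Builder, n_repeat: int) -> None:
    n_atoms = 3 * n_repeat
    radius = 0.145 / (2 * math.sin(math.pi / n_atoms))
    names = ["C1", "C2", "O1"]
    for i in range(n_repeat):
        atoms = {}
        for j, name in enumerate(names):
            theta = 2 * math.pi * (3 * i + j) / n_atoms
            atoms[name] = np.array(
                [radius * math.cos(theta), radius * math.sin(theta), 0.0]
            )
        builder.add_residue("A", i + 1, "PEO", atoms, [("C1", "C2"), ("C2", "O1")])
        if i > 0:
            builder.bond("A", i, "O1", "A", i + 1, "C1")
    builder.bond("A", n_repeat, "O1", "A", 1, "C1")


def _build_branched_pe(builder: _Builder, n1: int, nb: int, n2: int) -> None:
    units = ["ETH"] * n1 + ["ETB"] * nb + ["ETH"] * n2
    for i, resname in enumerate(units):
        k1, k2 = 2 * i, 2 * i + 1
        atoms = {
            "C1": np.array([0.13 * k1, 0.03 * (-1) ** k1, 0.0]),
            "C2": np.array([0.13 * k2, 0.03 * (-1) ** k2, 0.0]),
        }
        bonds = [("C1", "C2")]
        if resname == "ETB":
            y = atoms["C1"][1]
            atoms["C3"] = atoms["C1"] + np.array([0.0, 0.14 * math.copysign(1, y), 0.0])
            bonds.append(("C1", "C3"))
        builder.add_residue("A", i + 1, resname, atoms, bonds)
        if i > 0:
            builder.bond("A", i, "C2", "A", i + 1, "C1")


def _pick_sequence(spec: FixtureSpec) -> list[str]:
    if spec.sequence is not None:
        return list(spec.sequence)
    reps = (spec.n_residues + len(_DEFAULT_SEQ) - 1) // len(_DEFAULT_SEQ)
    return (_DEFAULT_SEQ * reps)[: spec.n_residues]


def make_structure(spec: FixtureSpec) -> tuple[StructureRecord, dict[str, Any]]:
    """Build the structure and its ground-truth manifest for *spec*.

    Same (spec, seed) always yields an identical structure.
    """
    builder = _Builder()
    manifest: dict[str, Any] = {
        "kind": spec.kind,
        "seed": spec.seed,
        "corruption": spec.corruption,
        "corrupted": [],
        "disulfides": [],
    }
    if spec.kind in ("linear_peptide", "idr_tail_protein"):
        if spec.kind == "idr_tail_protein":
            sequence = (
                ["GLY", "SER"] * (spec.n_tail // 2 + 1)
            )[: spec.n_tail] + _pick_sequence(
                dataclasses.replace(spec, sequence=None, n_residues=spec.n_core)
            ) + (["SER", "GLY"] * (spec.n_tail // 2 + 1))[: spec.n_tail]
            manifest["core_range"] = [spec.n_tail + 1, spec.n_tail + spec.n_core]
        else:
            sequence = _pick_sequence(spec)
        _build_linear_chain(builder, "A", sequence, np.zeros(3))
        manifest["expected_molecules"] = 1
    elif spec.kind == "cyclic_peptide":
        sequence = spec.sequence or (_DEFAULT_CYCLE * spec.n_residues)[: spec.n_residues]
        _build_cyclic_peptide(builder, sequence)
        manifest["expected_molecules"] = 1
        manifest["cyclic"] = True
    elif spec.kind == "two_chain_disulfide":
        chain_a = spec.chain_a or ["ALA", "GLY", "CYS", "SER", "ALA"]
        chain_b = spec.chain_b or ["GLY", "CYS", "ALA", "SER"]
        cys_a = chain_a.index("CYS")
        cys_b = chain_b.index("CYS")
        if cys_a % 2 != 0 or cys_b % 2 != 1:
            raise ValueError(
                "disulfide fixture needs CYS at an even index in chain A "
                "and an odd index in chain B (sidechain geometry)"
            )
        _build_linear_chain(builder, "A", chain_a, np.zeros(3))
        x_shift = (cys_a - cys_b) * RESIDUE_SPACING
        _build_linear_chain(builder, "B", chain_b, np.array([x_shift, -0.93, 0.0]))
        builder.bond("A", cys_a + 1, "SG", "B", cys_b + 1, "SG")
        manifest["expected_molecules"] = 1
        manifest["disulfides"] = [
            [["A", cys_a + 1], ["B", cys_b + 1]],
        ]
    elif spec.kind == "crown_ether":
        _build_crown_ether(builder, spec.n_repeat)
        manifest["expected_molecules"] = 1
        manifest["cyclic"] = True
    elif spec.kind == "branched_polyethylene":
        _build_branched_pe(builder, spec.n_linear_head, spec.n_branched, spec.n_linear_tail)
        manifest["expected_molecules"] = 1
    manifest["residues"] = builder.residues
    manifest["n_residues"] = len(builder.residues)

    if spec.corruption is not None:
        _apply_corruption(builder, spec, manifest)

    record = StructureRecord(
        particles=builder.particles,
        conect_pairs={tuple(sorted(b)) for b in builder.bonds},
    )
    manifest["bonds"] = sorted(tuple(sorted(b)) for b in builder.bonds)
    manifest["n_atoms"] = len(record.particles)
    return record, manifest


# ---------------------------------------------------------------------------
# corruption machinery

#: per corruption: which residues are eligible
_SIDECHAIN_BEARING = ("SER", "CYS", "HIS", "HISD", "TYR")
#: leaf heavy atoms per residue (removable without splitting the graph)
_LEAF_ATOMS = {
    "GLY": ["O"], "ALA": ["O", "CB"], "SER": ["O", "OG"], "CYS": ["O", "SG"],
    "HIS": ["O"], "HISD": ["O"], "TYR": ["O", "OH"],
    "PEO": ["O1"], "ETH": [], "ETB": ["C3"],
}


def _apply_corruption(builder: _Builder, spec: FixtureSpec, manifest) -> None:
    rng = np.random.default_rng(spec.seed)
    corruption = spec.corruption

    def eligible(res: dict[str, Any]) -> bool:
        if corruption == "add_atom":
            return res["resname"] == "GLY"
        if corruption == "drop_coordinates":
            return res["resname"] in _SIDECHAIN_BEARING
        if corruption == "drop_atoms":
            return bool(_LEAF_ATOMS.get(res["resname"]))
        if corruption == "rename_atoms":
            return res["resname"] in ("ALA", "SER", "CYS")
        if corruption == "swap_elements":
            return res["resname"] in ("ALA", "SER", "CYS", "GLY")
        if corruption == "perturb_distances":
            return res["resname"] in ("HIS", "HISD", "TYR", "SER", "CYS")
        return True

    candidates = [r for r in builder.residues if eligible(r)]
    if not candidates:
        raise ValueError(
            f"corruption {corruption!r} needs an eligible residue in the sequence"
        )
    n = min(spec.n_corrupt, len(candidates))
    chosen_idx = rng.choice(len(candidates), size=n, replace=False)
    for idx in sorted(int(i) for i in chosen_idx):
        res = candidates[idx]
        _corrupt_residue(builder, res, corruption, rng)
        manifest["corrupted"].append(
            {"chain": res["chain"], "resid": res["resid"],
             "resname": res["resname"], "category": corruption}
        )


def _corrupt_residue(builder: _Builder, res, corruption: str, rng) -> None:
    chain, resid, resname = res["chain"], res["resid"], res["resname"]

    def particle(atom: str) -> Particle:
        serial = builder.serial(chain, resid, atom)
        return next(p for p in builder.particles if p.serial == serial)

    def drop(atom: str) -> None:
        serial = builder.serial(chain, resid, atom)
        builder.particles = [p for p in builder.particles if p.serial != serial]
        builder.bonds = [b for b in builder.bonds if serial not in b]
        res["atoms"].remove(atom)

    if corruption == "drop_atoms":
        atom = _LEAF_ATOMS[resname][int(rng.integers(len(_LEAF_ATOMS[resname])))]
        drop(atom)
    elif corruption == "drop_coordinates":
        # remove every sidechain atom: the sidechain bead loses all sources
        sidechain = [a for a in list(res["atoms"]) if a not in ("N", "CA", "C", "O")]
        for atom in sidechain:
            drop(atom)
    elif corruption == "rename_atoms":
        # garble names, elements untouched: repairable by graph matching
        renameable = [a for a in res["atoms"] if a not in ("N", "O")]
        k = max(1, len(renameable) // 2)
        picked = rng.choice(len(renameable), size=k, replace=False)
        for i, ai in enumerate(sorted(int(x) for x in picked)):
            p = particle(renameable[ai])
            p.atom_name = f"{p.element}X{i}"
    elif corruption == "swap_elements":
        # misreport one sidechain/backbone atom's element (N/O style mixup)
        swaps = {"O": "N", "N": "O", "C": "O", "S": "O"}
        atoms = [a for a in res["atoms"] if a != "CA"]
        atom = atoms[int(rng.integers(len(atoms)))]
        p = particle(atom)
        p.element = swaps.get(p.element, "N")
    elif corruption == "perturb_distances":
        # push one sidechain atom far out: its bonds vanish on inference
        sidechain = [a for a in res["atoms"] if a not in ("N", "CA", "C", "O", "CB")]
        atom = sidechain[int(rng.integers(len(sidechain)))]
        p = particle(atom)
        p.position = p.position + np.array([0.0, 0.0, 0.45])
        serial = p.serial
        builder.bonds = [b for b in builder.bonds if serial not in b]
    elif corruption == "add_atom":
        # the classic malformed glycine: an unexpected C-beta
        ca = particle("CA")
        n = particle("N")
        e = 1.0 if n.position[1] > ca.position[1] else -1.0
        serial = max(q.serial for q in builder.particles) + 1
        builder.particles.append(
            Particle(
                serial=serial, atom_name="CB", resname=resname, resid=resid,
                chain=chain, element="C",
                position=ca.position + np.array([0.0, -0.14 * e, -0.10]),
            )
        )
        builder.bonds.append((builder.serial(chain, resid, "CA"), serial))
        builder._index[(chain, resid, "CB")] = serial
        res["atoms"].append("CB")
    else:  # pragma: no cover
        raise ValueError(corruption)


def manifest_to_json(manifest: dict[str, Any]) -> str:
    return json.dumps(manifest, indent=1, sort_keys=True)
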