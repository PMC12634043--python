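"""Link matching and GROMACS topology (.itp/.top) reading and writing.

Links add the interactions that span residue boundaries.  A link pattern is
matched against the molecule by attribute-aware subgraph isomorphism, then
filtered for residue-offset consistency: pattern atoms tagged with numeric
offsets must land in residues of one chain whose residue numbers differ by
exactly those offsets, while offset-free tags (``=``-prefixed) only demand
a *different* residue — which is what lets a disulfide link or a cyclic
polymer's repeat-unit link apply regardless of numbering.

Link precedence is file order and later wins: an interaction added on the
same particle tuple replaces the earlier one, which both deduplicates the
two orientations of a symmetric match and lets a specialized link (say, a
helical backbone angle) override the generic one.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Union

from .ffdata import (
    KIND_N_PARTICLES,
    KIND_TO_SECTION,
    SECTION_TO_KIND,
    Link,
)
from .ledger import WarningLedger
from .molgraph import Interaction, MoleculeGraph, subgraph_isomorphisms


class TopologyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# link application

def _link_node_match(p_attrs: dict, t_attrs: dict) -> bool:
    if p_attrs["atom_name"] != t_attrs.get("atom_name"):
        return False
    for key, want in p_attrs["matchers"].items():
        have = t_attrs.get(key)
        if key == "resname":
            if have not in want:
                return False
        elif str(have) != str(want):
            return False
    return True


def _offset_consistent(link: Link, corr: dict, molecule: MoleculeGraph) -> bool:
    """Check residue-offset semantics of a candidate correspondence."""
    res_of = {}
    for ref, node in corr.items():
        a = molecule.nodes[node]
        res_of[ref] = (a.get("chain", ""), a["resid"], a.get("icode", ""))
    groups: dict[tuple, set] = {}
    for ref, d in link.pattern.nodes(data=True):
        tag = ("o", d["offset"]) if d["offset"] is not None else ("f", d["free_tag"])
        groups.setdefault(tag, set()).add(res_of[ref])
    # same tag -> same residue; different tags -> different residues
    for tag, residues in groups.items():
        if len(residues) != 1:
            return False
    seen = [next(iter(r)) for r in groups.values()]
    if len(set(seen)) != len(seen):
        return False
    # numeric offsets: one chain, arithmetic residue numbering
    numeric = {tag[1]: next(iter(res)) for tag, res in groups.items() if tag[0] == "o"}
    if len(numeric) > 1:
        chains = {res[0] for res in numeric.values()}
        if len(chains) != 1:
            return False
        base_off = min(numeric)
        base_resid = numeric[base_off][1]
        for off, (chain, resid, _) in numeric.items():
            if resid - base_resid != off - base_off:
                return False
    return True


def _canonical(particles: tuple) -> tuple:
    return min(particles, tuple(reversed(particles)))


def apply_links(
    molecule: MoleculeGraph,
    links: Iterable[Link],
    ledger: Optional[WarningLedger] = None,
) -> int:
    """Apply every link occurrence to the molecule; returns the number of
    interactions added (after deduplication)."""
    added = 0
    for link in links:
        for corr in subgraph_isomorphisms(link.pattern, molecule, _link_node_match):
            if not _offset_consistent(link, corr, molecule):
                continue
            for kind, refs in link.remove_interactions:
                molecule.remove_interaction(kind, tuple(corr[r] for r in refs))
            for term in link.add_interactions:
                particles = tuple(corr[r] for r in term.particles)
                replaced = _replace_interaction(
                    molecule, term.replace(particles=particles)
                )
                if not replaced:
                    added += 1
            for ref, key, value in link.attribute_edits:
                molecule.nodes[corr[ref]][key] = value
            molecule.citations |= link.citations
    return added


def _replace_interaction(molecule: MoleculeGraph, term: Interaction) -> bool:
    """Insert *term*, replacing any same-kind interaction on the same
    particle tuple (either orientation).  Returns True if it replaced."""
    terms = molecule.interactions.setdefault(term.kind, [])
    key = _canonical(term.particles)
    for i, existing in enumerate(terms):
        if _canonical(existing.particles) == key:
            terms[i] = term
            return True
    molecule.add_interaction(term)
    return False


# ---------------------------------------------------------------------------
# itp documents

#: canonical GROMACS section order
_SECTION_ORDER = [
    "bonds",
    "pairs",
    "constraints",
    "exclusions",
    "angles",
    "dihedrals",
    "virtual_sitesn",
    "position_restraints",
]


@dataclasses.dataclass
class TopologyDocument:
    name: str
    nrexcl: int
    text: str


def write_itp(
    molecule: MoleculeGraph,
    name: str = "molecule",
    nrexcl: Optional[int] = None,
    citation_texts: Optional[dict[str, str]] = None,
) -> str:
    """Serialize a molecule as a GROMACS included-topology file.

    Deterministic output: identical molecules give byte-identical text.
    Elastic-network bonds (``meta source=elastic_network``) are grouped in
    their own commented block at the end of ``[ bonds ]``; citations
    accumulated on the molecule are emitted as header comments.
    """
    missing = [
        str(n) for n in sorted(molecule.nodes)
        if not molecule.nodes[n].get("particle_type")
    ]
    if missing:
        raise TopologyError(
            "particles lack a type and cannot be written: " + ", ".join(missing[:10])
        )
    if nrexcl is None:
        nrexcl = 1
    index = {node: i + 1 for i, node in enumerate(sorted(molecule.nodes))}
    lines: list[str] = []
    if molecule.citations:
        lines.append("; please cite:")
        for key in sorted(molecule.citations):
            text = (citation_texts or {}).get(key, "")
            lines.append(f";   [{key}] {text}".rstrip())
    lines += ["[ moleculetype ]", f"{name} {nrexcl}", "", "[ atoms ]"]
    for node in sorted(molecule.nodes):
        a = molecule.nodes[node]
        lines.append(
            f"{index[node]:5d} {a['particle_type']:>6s} {a['resid']:5d} "
            f"{a['resname']:>6s} {a['atom_name']:>6s} {index[node]:5d} "
            f"{_num(a.get('charge', 0.0)):>8s} {_num(a.get('mass', 0.0)):>8s}"
        )
    by_section: dict[str, list[Interaction]] = {s: [] for s in _SECTION_ORDER}
    for kind in sorted(molecule.interactions):
        section = KIND_TO_SECTION[kind]
        if section == "impropers":
            section = "dihedrals"
        by_section.setdefault(section, []).extend(molecule.interactions[kind])
    for section in _SECTION_ORDER:
        terms = by_section.get(section, [])
        if not terms:
            continue
        plain = [t for t in terms if t.meta.get("source") != "elastic_network"]
        elastic = [t for t in terms if t.meta.get("source") == "elastic_network"]
        lines += ["", f"[ {section} ]"]
        for term in sorted(plain, key=lambda t: tuple(index[p] for p in t.particles)):
            lines.append(_itp_line(term, index))
        if elastic:
            lines.append("; elastic network (source=elastic_network)")
            for term in sorted(
                elastic, key=lambda t: tuple(index[p] for p in t.particles)
            ):
                lines.append(_itp_line(term, index))
    return "\n".join(lines) + "\n"


def _num(x) -> str:
    if x is None:
        return "0"
    f = float(x)
    return str(int(f)) if f == int(f) else f"{f:g}"


def _itp_line(term: Interaction, index: dict) -> str:
    ids = [index[p] for p in term.particles]
    if term.kind == "virtual_site_n":
        site, *constructors = ids
        fields = [str(site), *(term.parameters or ("1",)), *map(str, constructors)]
    else:
        fields = [*(str(i) for i in ids), *term.parameters]
        if not term.parameters and term.kind in ("bond", "angle", "dihedral"):
            fields.append("1")  # default function type
    return " ".join(f"{f:>6s}" for f in fields)


def read_itp(
    text: str, ledger: Optional[WarningLedger] = None
) -> tuple[MoleculeGraph, TopologyDocument]:
    """Parse a GROMACS itp into a molecule (nodes, edges, interactions).

    ``#include`` lines are not followed (recorded as a diagnostic); all
    interaction parameters are kept verbatim.
    """
    molecule = MoleculeGraph()
    name, nrexcl = "molecule", 1
    section = None
    n_atoms = 0
    for lineno, raw in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            if ledger is not None:
                ledger.warn("io", f"line {lineno}: preprocessor directive not followed: {line}")
            continue
        import re as _re
        m = _re.match(r"^\[\s*([A-Za-z_0-9]+)\s*\]$", line)
        if m:
            section = m.group(1).lower()
            continue
        tokens = line.split()
        if section == "moleculetype":
            name = tokens[0]
            nrexcl = int(tokens[1]) if len(tokens) > 1 else 1
        elif section == "atoms":
            idx = int(tokens[0])
            ptype, resid, resname, atom = tokens[1], int(tokens[2]), tokens[3], tokens[4]
            charge = float(tokens[6]) if len(tokens) > 6 else 0.0
            mass = float(tokens[7]) if len(tokens) > 7 else 0.0
            molecule.add_node(
                idx - 1,
                atom_name=atom, resname=resname, resid=resid, chain="",
                particle_type=ptype, charge=charge, mass=mass, element="",
                position=None,
            )
            n_atoms = max(n_atoms, idx)
        elif section in SECTION_TO_KIND or section == "impropers":
            kind = SECTION_TO_KIND.get(section, "improper")
            if kind == "virtual_site_n":
                site, funct, *constructors = tokens
                ids = [int(site), *map(int, constructors)]
                params = (funct,)
            elif kind == "exclusion":
                ids = [int(t) for t in tokens]
                params = ()
            else:
                n = KIND_N_PARTICLES[kind]
                ids = [int(t) for t in tokens[:n]]
                params = tuple(tokens[n:])
            for i in ids:
                if not 1 <= i <= n_atoms:
                    raise TopologyError(
                        f"[{section}] line {lineno}: atom index {i} out of range"
                    )
            particles = tuple(i - 1 for i in ids)
            molecule.add_interaction(Interaction(kind, particles, params))
            if kind in ("bond", "constraint"):
                molecule.add_edge(*particles)
        elif section is not None and ledger is not None:
            ledger.warn("io", f"line {lineno}: unsupported itp section [{section}] skipped")
    if not molecule.nodes:
        raise TopologyError("itp contains no atoms")
    doc = TopologyDocument(name=name, nrexcl=nrexcl, text=text)
    return molecule, doc


def write_top(
    path: Union[str, Path],
    itp_files: list[str],
    molecules: list[tuple[str, int]],
    system_name: str = "cgweaver system",
) -> None:
    """Write a minimal .top skeleton including the given itp files."""
    lines = [f'#include "{f}"' for f in itp_files]
    lines += ["", "[ system ]", system_name, "", "[ molecules ]"]
    for name, count in molecules:
        lines.append(f"{name} {count}")
    Path(path).write_text("\n".join(lines) + "\n")
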