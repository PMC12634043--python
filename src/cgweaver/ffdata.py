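"""Force-field fragment data: Blocks, Links, Modifications, Mappings.

A *Block* is the canonical graph of one residue / monomeric repeat unit,
including its intra-fragment interactions.  A *Link* is a small pattern
graph describing interactions that span residue boundaries.  A
*Modification* is a delta to a canonical block — extra atoms (protonation,
PTMs), attribute changes, and the effect on the coarse-grained mapping.  A
*FragmentMapping* ties a fragment at the source resolution to one at the
target resolution through a weighted particle correspondence.

Three text formats are read here:

* the fragment dialect (``.ff``) defining blocks, links and modifications
  (documented in ``docs/file_formats.md``),
* the mapping dialect (``.map``),
* GROMACS ``.rtp`` residue topologies.

All parsers accept LF and CRLF line endings and tolerate trailing
whitespace.  Serializers are provided so that parse -> serialize -> parse
is the identity, which keeps the bundled data user-editable.
"""
from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Any, Iterable, Optional

import networkx as nx

from .ledger import WarningLedger
from .molgraph import Interaction, MoleculeGraph

__all__ = [
    "Block",
    "Link",
    "Modification",
    "FragmentMapping",
    "ForceField",
    "FFParseError",
    "parse_fragment_file",
    "parse_mapping_file",
    "parse_rtp",
    "serialize_fragments",
    "serialize_mappings",
    "validate_forcefield",
    "load_forcefield",
    "bundled_data_path",
]

#: masses (u) and covalent radii (nm, Cordero) for the elements the demo
#: force field and the structure reader care about.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "F": 18.998, "CL": 35.45,
    "NA": 22.990, "MG": 24.305, "K": 39.098, "CA": 40.078,
    "FE": 55.845, "ZN": 65.38,
}

# interaction-kind <-> section-name table shared by the .ff and .itp dialects
SECTION_TO_KIND = {
    "bonds": "bond",
    "angles": "angle",
    "dihedrals": "dihedral",
    "impropers": "improper",
    "constraints": "constraint",
    "pairs": "pair",
    "exclusions": "exclusion",
    "virtual_sitesn": "virtual_site_n",
    "position_restraints": "position_restraint",
}
KIND_TO_SECTION = {v: k for k, v in SECTION_TO_KIND.items()}
#: how many leading tokens of an interaction line are particle references
KIND_N_PARTICLES = {
    "bond": 2, "angle": 3, "dihedral": 4, "improper": 4,
    "constraint": 2, "pair": 2, "position_restraint": 1,
}


class FFParseError(ValueError):
    """Syntax or consistency error in a force-field data file."""

    def __init__(self, message: str, lineno: Optional[int] = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# data classes


class Block:
    """Canonical fragment: particle graph plus intra-fragment interactions.

    Nodes of ``graph`` are keyed by atom name; attributes carry ``atom_name``,
    ``element``, ``particle_type``, ``charge`` and ``mass``.
    """

    def __init__(self, name: str, nrexcl: Optional[int] = None):
        self.name = name
        self.nrexcl = nrexcl
        self.graph = MoleculeGraph()
        self.citations: set[str] = set()

    @property
    def interactions(self) -> dict[str, list[Interaction]]:
        return self.graph.interactions

    def add_atom(self, name: str, **attrs: Any) -> None:
        attrs.setdefault("atom_name", name)
        self.graph.add_node(name, **attrs)

    def atom_names(self) -> list[str]:
        return sorted(self.graph.nodes)

    def heavy_atoms(self) -> list[str]:
        return [
            n for n in sorted(self.graph.nodes)
            if (self.graph.nodes[n].get("element") or "").upper() != "H"
        ]

    def signature(self) -> tuple:
        nodes = tuple(
            (n, tuple(sorted(self.graph.nodes[n].items())))
            for n in sorted(self.graph.nodes)
        )
        edges = tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))
        inter = tuple(
            (k, tuple((i.particles, i.parameters) for i in v))
            for k, v in sorted(self.graph.interactions.items())
        )
        return (self.name, self.nrexcl, nodes, edges, inter, tuple(sorted(self.citations)))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Block) and self.signature() == other.signature()

    def __repr__(self) -> str:
        return f"<Block {self.name}: {len(self.graph)} atoms>"


# A link-pattern atom reference: leading '+'/'-' runs encode a residue
# offset relative to the anchor residue (offset 0); leading '=' runs encode
# an *offset-free* tag — the atom must sit in a residue distinct from the
# anchor's (and from other tags), connected as the pattern edges demand.
_REF_RE = re.compile(r"^(\++|-+|=+)?([A-Za-z0-9_'*]+)$")


def parse_atom_ref(ref: str) -> tuple[str, Optional[int], Optional[int]]:
    """Split a link atom reference into (name, offset, free_tag)."""
    m = _REF_RE.match(ref)
    if not m:
        raise FFParseError(f"malformed atom reference {ref!r}")
    prefix, name = m.groups()
    if not prefix:
        return name, 0, None
    if prefix[0] == "+":
        return name, len(prefix), None
    if prefix[0] == "-":
        return name, -len(prefix), None
    return name, None, len(prefix)


@dataclasses.dataclass
class Link:
    """Inter-residue interaction pattern.

    ``pattern`` nodes are the literal reference strings (``BB``, ``+BB``,
    ``=SC1``); node attributes: ``atom_name``, ``offset`` (int or None),
    ``free_tag`` (int or None) and ``matchers`` (resname choices,
    secstruct, ...).  Edges are connectivity the molecule must already
    have for the link to apply.
    """

    pattern: nx.Graph = dataclasses.field(default_factory=nx.Graph)
    add_interactions: list[Interaction] = dataclasses.field(default_factory=list)
    remove_interactions: list[tuple[str, tuple[str, ...]]] = dataclasses.field(default_factory=list)
    attribute_edits: list[tuple[str, str, Any]] = dataclasses.field(default_factory=list)
    citations: set[str] = dataclasses.field(default_factory=set)

    def ensure_ref(self, ref: str) -> None:
        if ref in self.pattern:
            return
        name, offset, free = parse_atom_ref(ref)
        self.pattern.add_node(ref, atom_name=name, offset=offset, free_tag=free, matchers={})

    def offsets(self) -> set[int]:
        return {
            d["offset"] for _, d in self.pattern.nodes(data=True) if d["offset"] is not None
        }

    def signature(self) -> tuple:
        nodes = tuple(
            (n, d["atom_name"], d["offset"], d["free_tag"], tuple(sorted(d["matchers"].items())))
            for n, d in sorted(self.pattern.nodes(data=True))
        )
        edges = tuple(sorted(tuple(sorted(e)) for e in self.pattern.edges))
        return (
            nodes, edges,
            tuple((i.kind, i.particles, i.parameters) for i in self.add_interactions),
            tuple(self.remove_interactions),
            tuple(self.attribute_edits),
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Link) and self.signature() == other.signature()


@dataclasses.dataclass
class Modification:
    """Delta to a canonical block: added atoms, attribute and mapping edits."""

    name: str
    base_resnames: tuple[str, ...] = ()
    #: atom name -> {"element": ..., "role": "anchor" | "added"}
    atoms: dict[str, dict[str, str]] = dataclasses.field(default_factory=dict)
    edges: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    attribute_edits: list[tuple[str, str, Any]] = dataclasses.field(default_factory=list)
    #: target-resolution edits: (bead, attribute, value)
    bead_edits: list[tuple[str, str, Any]] = dataclasses.field(default_factory=list)
    #: added atom -> bead receiving it in the mapping
    extra_to_bead: dict[str, str] = dataclasses.field(default_factory=dict)
    citations: set[str] = dataclasses.field(default_factory=set)

    @property
    def added_nodes(self) -> list[str]:
        return [a for a, d in self.atoms.items() if d["role"] == "added"]

    @property
    def anchor_nodes(self) -> list[str]:
        return [a for a, d in self.atoms.items() if d["role"] == "anchor"]

    def validate(self) -> None:
        added = set(self.added_nodes)
        anchors = set(self.anchor_nodes)
        if not added:
            return
        # every added node must reach an anchor through added/anchor edges
        g = nx.Graph(self.edges)
        g.add_nodes_from(self.atoms)
        for node in added:
            reachable = nx.node_connected_component(g, node) if node in g else {node}
            if not reachable & anchors:
                raise FFParseError(
                    f"modification {self.name}: added atom {node} not connected to any anchor"
                )

    def signature(self) -> tuple:
        return (
            self.name,
            self.base_resnames,
            tuple(sorted((a, d["element"], d["role"]) for a, d in self.atoms.items())),
            tuple(sorted(tuple(sorted(e)) for e in self.edges)),
            tuple(self.attribute_edits),
            tuple(self.bead_edits),
            tuple(sorted(self.extra_to_bead.items())),
            tuple(sorted(self.citations)),
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Modification) and self.signature() == other.signature()


@dataclasses.dataclass
class FragmentMapping:
    """Weighted correspondence between a fragment at two resolutions.

    ``weights[(i, atom)]`` maps source atom *atom* of scope residue *i*
    (1-based) to ``{(j, bead): weight}`` at the target resolution.
    """

    name: str
    from_resnames: tuple[str, ...]
    to_resnames: tuple[str, ...]
    weights: dict[tuple[int, str], dict[tuple[int, str], float]] = dataclasses.field(
        default_factory=dict
    )

    @property
    def resname_scope(self) -> tuple[str, ...]:
        return self.from_resnames

    def beads(self) -> list[tuple[int, str]]:
        out: set[tuple[int, str]] = set()
        for targets in self.weights.values():
            out.update(targets)
        return sorted(out)

    def signature(self) -> tuple:
        return (
            self.name,
            self.from_resnames,
            self.to_resnames,
            tuple(
                (k, tuple(sorted(v.items())))
                for k, v in sorted(self.weights.items())
            ),
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FragmentMapping) and self.signature() == other.signature()


@dataclasses.dataclass
class ForceField:
    """Named collection of blocks, links, modifications and variables."""

    name: str = ""
    blocks: dict[str, Block] = dataclasses.field(default_factory=dict)
    links: list[Link] = dataclasses.field(default_factory=list)
    modifications: dict[str, Modification] = dataclasses.field(default_factory=dict)
    variables: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    citation_texts: dict[str, str] = dataclasses.field(default_factory=dict)
    #: input resname -> (block name, modification names); from `alias` lines
    aliases: dict[str, tuple[str, tuple[str, ...]]] = dataclasses.field(default_factory=dict)

    def variable(self, key: str, default: Optional[list[str]] = None) -> list[str]:
        return self.variables.get(key, default if default is not None else [])

    def scalar(self, key: str, default: str = "") -> str:
        vals = self.variables.get(key)
        return vals[0] if vals else default


@dataclasses.dataclass
class ParsedFragments:
    blocks: dict[str, Block]
    links: list[Link]
    modifications: dict[str, Modification]
    variables: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    citation_texts: dict[str, str] = dataclasses.field(default_factory=dict)

    def __iter__(self):
        # allow  blocks, links, mods = parse_fragment_file(...)
        return iter((self.blocks, self.links, self.modifications))


# ---------------------------------------------------------------------------
# fragment dialect parser

_TOP_SECTIONS = {"forcefield", "variables", "citations", "block", "link", "modification"}
_BLOCK_SECTIONS = {"atoms"} | set(SECTION_TO_KIND)
_LINK_SECTIONS = {"patterns", "edges", "attributes"} | set(SECTION_TO_KIND) | {
    "remove_" + s for s in SECTION_TO_KIND
}
_MOD_SECTIONS = {"atoms", "edges", "attributes", "cg"}


def _lines(text: str):
    for lineno, raw in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        line = raw.split(";", 1)[0].split("#", 1)[0].strip()
        if line:
            yield lineno, line


_SECTION_RE = re.compile(r"^\[\s*([A-Za-z_0-9]+)\s*\]$")


def _parse_value(token: str) -> Any:
    try:
        return int(token)
    except ValueError:
        try:
            return float(token)
        except ValueError:
            return token


def _parse_interaction_line(
    kind: str, tokens: list[str], lineno: int
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split an interaction line into particle references and parameters."""
    if kind == "virtual_site_n":
        # site  funct  constructing atoms...
        if len(tokens) < 3:
            raise FFParseError(f"virtual_sitesn line needs >=3 fields", lineno)
        site, funct, *constructors = tokens
        return (site, *constructors), (funct,)
    if kind == "exclusion":
        if len(tokens) < 2:
            raise FFParseError("exclusion line needs >=2 atoms", lineno)
        return tuple(tokens), ()
    n = KIND_N_PARTICLES[kind]
    if len(tokens) < n:
        raise FFParseError(f"{KIND_TO_SECTION[kind]} line needs {n} atoms", lineno)
    return tuple(tokens[:n]), tuple(tokens[n:])


def parse_fragment_file(
    text: str, ledger: Optional[WarningLedger] = None
) -> ParsedFragments:
    """Parse the fragment dialect into blocks, links and modifications.

    Unknown directives are skipped with an ``io`` warning in *ledger* (if
    given); syntax errors and references to undeclared atoms raise
    :class:`FFParseError` with the offending line number.
    """
    blocks: dict[str, Block] = {}
    links: list[Link] = []
    modifications: dict[str, Modification] = {}
    variables: dict[str, list[str]] = {}
    citation_texts: dict[str, str] = {}

    context = None  # "forcefield" | "variables" | "citations" | Block | Link | Modification
    section = None  # current subsection inside a block/link/modification

    def warn(msg: str) -> None:
        if ledger is not None:
            ledger.warn("io", msg)

    for lineno, line in _lines(text):
        m = _SECTION_RE.match(line)
        if m:
            name = m.group(1).lower()
            if name in _TOP_SECTIONS:
                if name == "block":
                    context = Block("")
                    section = None
                elif name == "link":
                    context = Link()
                    links.append(context)
                    section = None
                elif name == "modification":
                    context = Modification("")
                    section = None
                else:
                    context = name
                    section = None
                continue
            # subsection of current object
            if isinstance(context, Block) and name in _BLOCK_SECTIONS:
                section = name
            elif isinstance(context, Link) and name in _LINK_SECTIONS:
                section = name
            elif isinstance(context, Modification) and name in _MOD_SECTIONS:
                section = name
            else:
                warn(f"line {lineno}: unknown directive [{name}] skipped")
                section = ("skip", name)
            continue

        if isinstance(section, tuple):  # inside a skipped section
            continue

        tokens = line.split()

        if context == "forcefield":
            if tokens[0] == "name" and len(tokens) >= 2:
                variables.setdefault("forcefield_name", [tokens[1]])
            continue
        if context == "variables":
            variables[tokens[0]] = tokens[1:]
            continue
        if context == "citations":
            citation_texts[tokens[0]] = " ".join(tokens[1:])
            continue

        if isinstance(context, Block):
            blk = context
            if section is None:
                if tokens[0] == "name":
                    blk.name = tokens[1]
                    if blk.name in blocks:
                        raise FFParseError(f"duplicate block name {blk.name!r}", lineno)
                    blocks[blk.name] = blk
                elif tokens[0] == "nrexcl":
                    blk.nrexcl = int(tokens[1])
                elif tokens[0] == "citations":
                    blk.citations.update(tokens[1:])
                else:
                    raise FFParseError(f"unexpected line in block header: {line!r}", lineno)
            elif section == "atoms":
                # name element type charge [mass]
                if len(tokens) < 4:
                    raise FFParseError("block atom line needs: name element type charge [mass]", lineno)
                aname, element, ptype, charge = tokens[:4]
                element = "" if element == "-" else element
                try:
                    q = float(charge)
                except ValueError as exc:
                    raise FFParseError(f"bad charge {charge!r}", lineno) from exc
                mass = (
                    float(tokens[4])
                    if len(tokens) > 4
                    else ELEMENT_MASSES.get(element.upper(), 0.0)
                )
                blk.add_atom(
                    aname, element=element,
                    particle_type=(None if ptype == "-" else ptype),
                    charge=q, mass=mass,
                )
            else:
                kind = SECTION_TO_KIND[section]
                particles, params = _parse_interaction_line(kind, tokens, lineno)
                for p in particles:
                    if p not in blk.graph:
                        raise FFParseError(
                            f"interaction references undeclared atom {p!r} in block {blk.name!r}",
                            lineno,
                        )
                inter = Interaction(kind, particles, params)
                blk.graph.add_interaction(inter)
                if kind in ("bond", "constraint"):
                    blk.graph.add_edge(*particles)
            continue

        if isinstance(context, Link):
            lnk = context
            if section is None:
                if tokens[0] == "citations":
                    lnk.citations.update(tokens[1:])
                    continue
                raise FFParseError(f"unexpected line in link: {line!r}", lineno)
            if section == "patterns":
                ref = tokens[0]
                lnk.ensure_ref(ref)
                matchers = lnk.pattern.nodes[ref]["matchers"]
                for kv in tokens[1:]:
                    if "=" not in kv:
                        raise FFParseError(f"pattern matcher must be key=value, got {kv!r}", lineno)
                    key, value = kv.split("=", 1)
                    if key == "resname":
                        matchers[key] = tuple(value.split("|"))
                    else:
                        matchers[key] = value
            elif section == "edges":
                if len(tokens) != 2:
                    raise FFParseError("edge line needs exactly 2 atom references", lineno)
                for ref in tokens:
                    lnk.ensure_ref(ref)
                lnk.pattern.add_edge(*tokens)
            elif section == "attributes":
                ref, key, *value = tokens
                if not value:
                    raise FFParseError("attribute line needs: ref key value", lineno)
                lnk.ensure_ref(ref)
                lnk.attribute_edits.append((ref, key, _parse_value(" ".join(value))))
            elif section.startswith("remove_"):
                kind = SECTION_TO_KIND[section[len("remove_"):]]
                particles, _ = _parse_interaction_line(kind, tokens, lineno)
                for ref in particles:
                    lnk.ensure_ref(ref)
                lnk.remove_interactions.append((kind, particles))
            else:
                kind = SECTION_TO_KIND[section]
                particles, params = _parse_interaction_line(kind, tokens, lineno)
                for ref in particles:
                    lnk.ensure_ref(ref)
                lnk.add_interactions.append(Interaction(kind, particles, params))
            continue

        if isinstance(context, Modification):
            mod = context
            if section is None:
                if tokens[0] == "name":
                    mod.name = tokens[1]
                    if mod.name in modifications:
                        raise FFParseError(f"duplicate modification name {mod.name!r}", lineno)
                    modifications[mod.name] = mod
                elif tokens[0] == "resname":
                    mod.base_resnames = tuple(tokens[1].split("|"))
                elif tokens[0] == "citations":
                    mod.citations.update(tokens[1:])
                else:
                    raise FFParseError(f"unexpected line in modification header: {line!r}", lineno)
            elif section == "atoms":
                if len(tokens) != 3 or tokens[2] not in ("anchor", "added"):
                    raise FFParseError(
                        "modification atom line needs: name element anchor|added", lineno
                    )
                mod.atoms[tokens[0]] = {"element": tokens[1], "role": tokens[2]}
            elif section == "edges":
                if len(tokens) != 2:
                    raise FFParseError("edge line needs exactly 2 atoms", lineno)
                for a in tokens:
                    if a not in mod.atoms:
                        raise FFParseError(
                            f"edge references undeclared atom {a!r} in modification {mod.name!r}",
                            lineno,
                        )
                mod.edges.append((tokens[0], tokens[1]))
            elif section == "attributes":
                atom, key, *value = tokens
                if not value:
                    raise FFParseError("attribute line needs: atom key value", lineno)
                mod.attribute_edits.append((atom, key, _parse_value(" ".join(value))))
            elif section == "cg":
                if tokens[0] == "map":
                    if len(tokens) != 3:
                        raise FFParseError("cg map line needs: map atom bead", lineno)
                    mod.extra_to_bead[tokens[1]] = tokens[2]
                else:
                    bead, key, *value = tokens
                    if not value:
                        raise FFParseError("cg edit line needs: bead key value", lineno)
                    mod.bead_edits.append((bead, key, _parse_value(" ".join(value))))
            continue

        raise FFParseError(f"content outside any section: {line!r}", lineno)

    for blk in blocks.values():
        if not blk.name:
            raise FFParseError("block without a name")
    for mod in modifications.values():
        mod.validate()
    return ParsedFragments(blocks, links, modifications, variables, citation_texts)


# ---------------------------------------------------------------------------
# mapping dialect

def parse_mapping_file(text: str) -> list[FragmentMapping]:
    """Parse the mapping dialect into :class:`FragmentMapping` objects.

    An atom listed with several beads splits its weight equally between
    them (the dialect carries no explicit weights).
    """
    mappings: list[FragmentMapping] = []
    current: Optional[FragmentMapping] = None
    section = None
    for lineno, line in _lines(text):
        m = _SECTION_RE.match(line)
        if m:
            name = m.group(1).lower()
            if name == "mapping":
                current = FragmentMapping("", (), ())
                mappings.append(current)
                section = None
            elif name == "atoms" and current is not None:
                section = "atoms"
            else:
                raise FFParseError(f"unknown mapping directive [{name}]", lineno)
            continue
        if current is None:
            raise FFParseError(f"content outside [mapping]: {line!r}", lineno)
        tokens = line.split()
        if section is None:
            if tokens[0] == "name":
                current.name = tokens[1]
            elif tokens[0] == "from":
                current.from_resnames = tuple(tokens[1:])
            elif tokens[0] == "to":
                current.to_resnames = tuple(tokens[1:])
            else:
                raise FFParseError(f"unexpected mapping header line: {line!r}", lineno)
        else:
            # residx atom bead[,...]   with optional "j:" bead prefixes
            if len(tokens) < 3:
                raise FFParseError("mapping atom line needs: residx atom bead...", lineno)
            try:
                residx = int(tokens[0])
            except ValueError as exc:
                raise FFParseError(f"bad residue index {tokens[0]!r}", lineno) from exc
            atom = tokens[1]
            beads = []
            for bead_ref in tokens[2:]:
                if ":" in bead_ref:
                    j, bead = bead_ref.split(":", 1)
                    beads.append((int(j), bead))
                else:
                    beads.append((residx, bead_ref))
            w = 1.0 / len(beads)
            current.weights[(residx, atom)] = {b: w for b in beads}
    for mapping in mappings:
        if not mapping.from_resnames:
            raise FFParseError(f"mapping {mapping.name!r} lacks a 'from' line")
        if not mapping.to_resnames:
            raise FFParseError(f"mapping {mapping.name!r} lacks a 'to' line")
        for (residx, atom) in mapping.weights:
            if not 1 <= residx <= len(mapping.from_resnames):
                raise FFParseError(
                    f"mapping {mapping.name!r}: atom {atom} has residue index {residx} "
                    f"outside scope of length {len(mapping.from_resnames)}"
                )
    return mappings


# ---------------------------------------------------------------------------
# GROMACS .rtp reader

_RTP_SUBSECTIONS = {"atoms", "bonds", "angles", "dihedrals", "impropers", "exclusions"}


@dataclasses.dataclass
class RtpData:
    blocks: dict[str, Block]
    links: list[Link]
    bondedtypes: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.blocks, self.links))


def guess_element(atom_name: str) -> str:
    """Guess the element from an atom name (PDB/GROMACS conventions)."""
    name = atom_name.strip()
    if not name:
        return ""
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ("CL", "NA", "MG", "FE", "ZN", "BR", "SE") and len(stripped) >= 2:
        return two.capitalize()
    return stripped[0].upper()


def parse_rtp(text: str, ledger: Optional[WarningLedger] = None) -> RtpData:
    """Read a GROMACS .rtp residue-topology file.

    Returns one :class:`Block` per residue.  Bonds written with ``-``/``+``
    atom-name prefixes (previous/next residue) become inter-residue
    :class:`Link` patterns with residue offsets −1 / +1.
    """
    blocks: dict[str, Block] = {}
    links: list[Link] = []
    bondedtypes: tuple[str, ...] = ()
    current: Optional[Block] = None
    section = None
    seen_atoms: set[str] = set()

    def close_residue(lineno: int) -> None:
        if current is not None and current.name not in seen_atoms:
            raise FFParseError(f"residue {current.name!r} has no [atoms] section", lineno)

    for lineno, line in _lines(text):
        m = _SECTION_RE.match(line)
        if m:
            name = m.group(1)
            lname = name.lower()
            if lname == "bondedtypes":
                close_residue(lineno)
                current, section = None, "bondedtypes"
            elif lname in _RTP_SUBSECTIONS and current is not None:
                section = lname
                if lname == "atoms":
                    seen_atoms.add(current.name)
            elif lname in _RTP_SUBSECTIONS:
                raise FFParseError(f"[{name}] outside a residue entry", lineno)
            else:
                close_residue(lineno)
                current = Block(name, nrexcl=3)
                if name in blocks:
                    raise FFParseError(f"duplicate residue {name!r}", lineno)
                blocks[name] = current
                section = None
            continue
        tokens = line.split()
        if section == "bondedtypes":
            bondedtypes = tuple(tokens)
            continue
        if current is None:
            raise FFParseError(f"content outside any residue: {line!r}", lineno)
        if section == "atoms":
            if len(tokens) < 3:
                raise FFParseError("rtp atom line needs: name type charge [cgnr]", lineno)
            aname, ptype, charge = tokens[:3]
            current.add_atom(
                aname,
                element=guess_element(aname),
                particle_type=ptype,
                charge=float(charge),
                mass=ELEMENT_MASSES.get(guess_element(aname).upper(), 0.0),
            )
        elif section in ("bonds", "angles", "dihedrals", "impropers", "exclusions"):
            kind = {"bonds": "bond", "angles": "angle", "dihedrals": "dihedral",
                    "impropers": "improper", "exclusions": "exclusion"}[section]
            nref = {"bond": 2, "angle": 3, "dihedral": 4, "improper": 4}.get(kind, len(tokens))
            refs, params = tuple(tokens[:nref]), tuple(tokens[nref:])
            if any(r.startswith(("-", "+")) for r in refs):
                link = Link()
                for ref in refs:
                    link.ensure_ref(ref)
                for a, b in zip(refs, refs[1:]):
                    if kind in ("bond", "constraint"):
                        link.pattern.add_edge(a, b)
                link.add_interactions.append(Interaction(kind, refs, params))
                links.append(link)
            else:
                for r in refs:
                    if r not in current.graph:
                        raise FFParseError(
                            f"interaction references undeclared atom {r!r} "
                            f"in residue {current.name!r}",
                            lineno,
                        )
                current.graph.add_interaction(Interaction(kind, refs, params))
                if kind == "bond":
                    current.graph.add_edge(*refs)
        elif section is None:
            raise FFParseError(f"unexpected line in residue header: {line!r}", lineno)
        else:
            if ledger is not None:
                ledger.warn("io", f"line {lineno}: unsupported rtp section skipped")
    close_residue(-1)
    return RtpData(blocks, links, bondedtypes)


# ---------------------------------------------------------------------------
# serializers (round-trip partners of the parsers)

def _fmt_value(v: Any) -> str:
    return repr(v) if isinstance(v, float) else str(v)


def serialize_fragments(
    blocks: Iterable[Block] = (),
    links: Iterable[Link] = (),
    modifications: Iterable[Modification] = (),
    variables: Optional[dict[str, list[str]]] = None,
    citation_texts: Optional[dict[str, str]] = None,
) -> str:
    out: list[str] = []
    if variables:
        out.append("[ variables ]")
        for key, vals in variables.items():
            out.append(" ".join([key, *vals]))
        out.append("")
    if citation_texts:
        out.append("[ citations ]")
        for key, txt in citation_texts.items():
            out.append(f"{key} {txt}")
        out.append("")
    for blk in blocks:
        out.append("[ block ]")
        out.append(f"name {blk.name}")
        if blk.nrexcl is not None:
            out.append(f"nrexcl {blk.nrexcl}")
        if blk.citations:
            out.append("citations " + " ".join(sorted(blk.citations)))
        out.append("[ atoms ]")
        for aname in blk.graph.nodes:
            d = blk.graph.nodes[aname]
            fields = [
                aname,
                d.get("element") or "-",
                d.get("particle_type") or "-",
                repr(d.get("charge", 0.0)),
                repr(d.get("mass", 0.0)),
            ]
            out.append(" ".join(fields))
        # plain edges not backed by a bond/constraint interaction
        covered = {
            tuple(sorted(i.particles))
            for kind in ("bond", "constraint")
            for i in blk.graph.interactions.get(kind, [])
        }
        for kind in sorted(blk.graph.interactions):
            out.append(f"[ {KIND_TO_SECTION[kind]} ]")
            for term in blk.graph.interactions[kind]:
                out.append(" ".join(_format_interaction(term)))
        extra_edges = [
            e for e in blk.graph.edges if tuple(sorted(e)) not in covered
        ]
        if extra_edges:  # pragma: no cover - demo data has none
            out.append("[ bonds ]")
            for a, b in extra_edges:
                out.append(f"{a} {b}")
        out.append("")
    for link in links:
        out.append("[ link ]")
        if any(d["matchers"] for _, d in link.pattern.nodes(data=True)):
            out.append("[ patterns ]")
            for ref, d in sorted(link.pattern.nodes(data=True)):
                parts = [ref]
                for key, val in sorted(d["matchers"].items()):
                    sval = "|".join(val) if isinstance(val, tuple) else str(val)
                    parts.append(f"{key}={sval}")
                out.append(" ".join(parts))
        if link.pattern.edges:
            out.append("[ edges ]")
            for a, b in sorted(tuple(sorted(e)) for e in link.pattern.edges):
                out.append(f"{a} {b}")
        by_kind: dict[str, list[Interaction]] = {}
        for term in link.add_interactions:
            by_kind.setdefault(term.kind, []).append(term)
        for kind in sorted(by_kind):
            out.append(f"[ {KIND_TO_SECTION[kind]} ]")
            for term in by_kind[kind]:
                out.append(" ".join(_format_interaction(term)))
        rm_by_kind: dict[str, list[tuple[str, ...]]] = {}
        for kind, refs in link.remove_interactions:
            rm_by_kind.setdefault(kind, []).append(refs)
        for kind in sorted(rm_by_kind):
            out.append(f"[ remove_{KIND_TO_SECTION[kind]} ]")
            for refs in rm_by_kind[kind]:
                out.append(" ".join(refs))
        if link.attribute_edits:
            out.append("[ attributes ]")
            for ref, key, value in link.attribute_edits:
                out.append(f"{ref} {key} {_fmt_value(value)}")
        out.append("")
    for mod in modifications:
        out.append("[ modification ]")
        out.append(f"name {mod.name}")
        if mod.base_resnames:
            out.append("resname " + "|".join(mod.base_resnames))
        if mod.citations:
            out.append("citations " + " ".join(sorted(mod.citations)))
        out.append("[ atoms ]")
        for aname, d in mod.atoms.items():
            out.append(f"{aname} {d['element']} {d['role']}")
        if mod.edges:
            out.append("[ edges ]")
            for a, b in mod.edges:
                out.append(f"{a} {b}")
        if mod.attribute_edits:
            out.append("[ attributes ]")
            for atom, key, value in mod.attribute_edits:
                out.append(f"{atom} {key} {_fmt_value(value)}")
        if mod.bead_edits or mod.extra_to_bead:
            out.append("[ cg ]")
            for bead, key, value in mod.bead_edits:
                out.append(f"{bead} {key} {_fmt_value(value)}")
            for atom, bead in mod.extra_to_bead.items():
                out.append(f"map {atom} {bead}")
        out.append("")
    return "\n".join(out)


def _format_interaction(term: Interaction) -> list[str]:
    if term.kind == "virtual_site_n":
        site, *constructors = term.particles
        return [site, *term.parameters, *constructors]
    return [*term.particles, *term.parameters]


def serialize_mappings(mappings: Iterable[FragmentMapping]) -> str:
    out: list[str] = []
    for mapping in mappings:
        out.append("[ mapping ]")
        out.append(f"name {mapping.name}")
        out.append("from " + " ".join(mapping.from_resnames))
        out.append("to " + " ".join(mapping.to_resnames))
        out.append("[ atoms ]")
        for (residx, atom), targets in mapping.weights.items():
            beads = [f"{j}:{bead}" if j != residx else bead for (j, bead) in targets]
            out.append(" ".join([str(residx), atom, *beads]))
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# validation and bundled data

def validate_forcefield(
    ff: ForceField, mappings: Iterable[FragmentMapping] = ()
) -> list[str]:
    """Cross-check a force field against a mapping set (diagnostics only)."""
    diagnostics: list[str] = []
    mappings = list(mappings)
    mapped_resnames = {rn for m in mappings for rn in m.from_resnames}
    for name in sorted(ff.blocks):
        if mapped_resnames and name not in mapped_resnames:
            diagnostics.append(f"block {name!r} has no mapping")
    for m in mappings:
        for rn in m.to_resnames:
            if rn not in ff.blocks:
                diagnostics.append(f"mapping {m.name!r} targets unknown block {rn!r}")
                continue
            block = ff.blocks[rn]
            for j, bead in m.beads():
                if m.to_resnames[j - 1] == rn and bead not in block.graph:
                    diagnostics.append(
                        f"mapping {m.name!r} names bead {bead!r} absent from block {rn!r}"
                    )
    for i, link in enumerate(ff.links):
        resnames: set[str] = set()
        for _, d in link.pattern.nodes(data=True):
            choices = d["matchers"].get("resname")
            if choices:
                resnames.update(choices)
        if resnames and not resnames & set(ff.blocks):
            diagnostics.append(f"link #{i} matches no known block resname")
    for mod in ff.modifications.values():
        for rn in mod.base_resnames:
            if rn != "*" and rn not in ff.blocks:
                diagnostics.append(
                    f"modification {mod.name!r} applies to unknown block {rn!r}"
                )
    return diagnostics


def bundled_data_path() -> Path:
    """Directory holding the bundled demonstration force-field data."""
    return Path(__file__).resolve().parent / "data"


def load_forcefield(
    name_or_dir: str, ledger: Optional[WarningLedger] = None
) -> tuple[ForceField, list[FragmentMapping]]:
    """Load a force field (and its mapping files) by bundled name or directory.

    A directory is scanned for ``*.ff``, ``*.rtp`` and ``*.map`` files.
    Bundled names: ``demo-aa``, ``demo-cg``.
    """
    path = Path(name_or_dir)
    if not path.is_dir():
        candidate = bundled_data_path() / name_or_dir
        if not candidate.is_dir():
            raise FileNotFoundError(f"no such force field: {name_or_dir}")
        path = candidate
    ff = ForceField(name=path.name)
    mappings: list[FragmentMapping] = []
    for file in sorted(path.glob("*.ff")):
        parsed = parse_fragment_file(file.read_text(), ledger)
        for bname, blk in parsed.blocks.items():
            if bname in ff.blocks:
                raise FFParseError(f"duplicate block {bname!r} across files")
            ff.blocks[bname] = blk
        ff.links.extend(parsed.links)
        for mname, mod in parsed.modifications.items():
            if mname in ff.modifications:
                raise FFParseError(f"duplicate modification {mname!r} across files")
            ff.modifications[mname] = mod
        ff.variables.update(parsed.variables)
        ff.citation_texts.update(parsed.citation_texts)
    for file in sorted(path.glob("*.rtp")):
        rtp = parse_rtp(file.read_text(), ledger)
        for bname, blk in rtp.blocks.items():
            ff.blocks.setdefault(bname, blk)
        ff.links.extend(rtp.links)
    for file in sorted(path.glob("*.map")):
        mappings.extend(parse_mapping_file(file.read_text()))
    if "forcefield_name" in ff.variables:
        ff.name = ff.variables["forcefield_name"][0]
    # residue-name alias table, written as variables:  alias.HSP HIS HIS-HP
    for key in sorted(ff.variables):
        if key.startswith("alias."):
            vals = ff.variables[key]
            if vals:
                ff.aliases[key[len("alias."):]] = (vals[0], tuple(vals[1:]))
    return ff, mappings
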