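"""Elastic-network (EN) generation with fine-tuning controls.

An EN is a set of weak harmonic bonds between (by default) backbone beads
that preserves tertiary structure, generated after the resolution
transformation as a pure post-processing step.  Eligibility of a bead pair
is a triple filter:

* geometric — the measured distance lies within [lower_cutoff, upper_cutoff];
* topological — the *residue minimum distance* (RMD), a graph distance on
  the residue graph, is at least ``rmd``.  Because it is a graph distance,
  residues joined through a disulfide bridge are close and get no EN bond,
  which is the intended behaviour;
* scoping — both beads belong to the same EN *unit*: the whole system
  (``all``), one molecule, one chain, or one declared residue-index range.
  Two disulfide-bridged chains are a single molecule, so ``chain`` is the
  way to bias them separately.

EN bonds are emitted as interactions only — never as graph edges — so they
cannot change molecule partitioning or residue-graph distances.  They use
GROMACS bond function type 6 (harmonic, no exclusions generated) so the
bias cannot perturb the nonbonded exclusion topology.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import networkx as nx
import numpy as np

from .ledger import WarningLedger
from .molgraph import Interaction, MoleculeGraph, SystemOfMolecules, residue_key

#: defaults; rmd = 3 is part of the protein model and should not be changed,
#: the others are declared, overridable conventions.
DEFAULT_UPPER_CUTOFF = 0.9
DEFAULT_LOWER_CUTOFF = 0.0
DEFAULT_FORCE_CONSTANT = 700.0
DEFAULT_RMD = 3
EN_BOND_FUNCT = "6"


@dataclasses.dataclass
class ENParams:
    lower_cutoff: float = DEFAULT_LOWER_CUTOFF  # nm
    upper_cutoff: float = DEFAULT_UPPER_CUTOFF  # nm
    force_constant: float = DEFAULT_FORCE_CONSTANT  # kJ mol^-1 nm^-2
    rmd: int = DEFAULT_RMD  # residues (graph distance)
    #: bead eligibility: list of atom names, or a predicate over attrs;
    #: None = backbone beads (force-field variable ``cg_backbone``)
    selection: Optional[object] = None
    unit: str = "molecule"  # all | molecule | chain | region
    regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.lower_cutoff <= self.upper_cutoff:
            raise ValueError("need 0 <= lower_cutoff <= upper_cutoff")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.rmd < 0:
            raise ValueError("rmd must be >= 0")
        if self.unit not in ("all", "molecule", "chain", "region"):
            raise ValueError(f"unknown EN unit {self.unit!r}")
        if (self.unit == "region") != bool(self.regions):
            raise ValueError("regions must be given iff unit='region'")
        for lo, hi in self.regions:
            if lo > hi:
                raise ValueError(f"empty region {lo}:{hi}")


def residue_graph(molecule: MoleculeGraph) -> nx.Graph:
    """One node per residue; an edge wherever any bond joins two residues.

    Disulfide bridges therefore connect their residues at distance 1.
    """
    g = nx.Graph()
    for node in molecule.nodes:
        g.add_node(residue_key(molecule.nodes[node]))
    for u, v in molecule.edges:
        ku, kv = residue_key(molecule.nodes[u]), residue_key(molecule.nodes[v])
        if ku != kv:
            g.add_edge(ku, kv)
    return g


def select_beads(
    molecule: MoleculeGraph,
    predicate: Optional[object] = None,
    ledger: Optional[WarningLedger] = None,
) -> list:
    """Beads eligible for the EN.

    ``predicate`` is a list of bead names or a callable over particle
    attributes; default is the single name ``BB``.  An empty selection is
    reported, not silently accepted.
    """
    if predicate is None:
        predicate = ["BB"]
    if callable(predicate):
        test: Callable[[dict], bool] = predicate
    else:
        names = set(predicate)
        test = lambda attrs: attrs.get("atom_name") in names  # noqa: E731
    chosen = [n for n in sorted(molecule.nodes) if test(molecule.nodes[n])]
    if not chosen and ledger is not None:
        ledger.warn("empty-selection", "elastic-network bead selection is empty")
    return chosen


def _virtual_site_nodes(molecule: MoleculeGraph) -> set:
    return {t.particles[0] for t in molecule.interactions.get("virtual_site_n", [])}


def _in_same_unit(a: dict, b: dict, params: ENParams) -> bool:
    if params.unit in ("all", "molecule"):
        return True  # molecule scoping is handled by operating per molecule
    if params.unit == "chain":
        return a.get("chain", "") == b.get("chain", "")
    for lo, hi in params.regions:
        if lo <= a["resid"] <= hi and lo <= b["resid"] <= hi:
            return True
    return False


def generate_en(
    molecule: MoleculeGraph,
    params: ENParams,
    ledger: Optional[WarningLedger] = None,
    attach: bool = True,
) -> list[Interaction]:
    """Generate harmonic EN bonds for one molecule.

    Each emitted bond records the measured distance (nm, rounded to 5
    decimals for byte-stable output) as its equilibrium length and is
    tagged ``source=elastic_network``.  The molecule's node and edge sets
    are left untouched.
    """
    beads = select_beads(molecule, params.selection, ledger)
    vsites = _virtual_site_nodes(molecule)
    eligible = []
    for n in beads:
        if n in vsites:
            continue
        if molecule.nodes[n].get("position") is None:
            if ledger is not None:
                ledger.warn(
                    "missing-coordinates",
                    f"EN-eligible bead {molecule.nodes[n]['atom_name']} of residue "
                    f"{molecule.nodes[n]['resname']}{molecule.nodes[n]['resid']} has no "
                    "position; its pairs are skipped",
                    resid=molecule.nodes[n]["resid"],
                    chain=molecule.nodes[n].get("chain", ""),
                )
            continue
        eligible.append(n)
    rgraph = residue_graph(molecule)
    # residue-graph distances only among residues that host eligible beads
    res_of = {n: residue_key(molecule.nodes[n]) for n in eligible}
    dist: dict[tuple, dict[tuple, int]] = {}
    wanted = set(res_of.values())
    for src in wanted:
        lengths = nx.single_source_shortest_path_length(rgraph, src)
        dist[src] = lengths
    bonds: list[Interaction] = []
    for i, a in enumerate(eligible):
        pa = np.asarray(molecule.nodes[a]["position"])
        for b in eligible[i + 1:]:
            attrs_a, attrs_b = molecule.nodes[a], molecule.nodes[b]
            d = float(np.linalg.norm(pa - np.asarray(attrs_b["position"])))
            if not params.lower_cutoff <= d <= params.upper_cutoff:
                continue
            rd = dist[res_of[a]].get(res_of[b], float("inf"))
            if rd < params.rmd:
                continue
            if not _in_same_unit(attrs_a, attrs_b, params):
                continue
            bonds.append(
                Interaction(
                    "bond",
                    (a, b),
                    (EN_BOND_FUNCT, f"{round(d, 5):.5f}", _fmt_k(params.force_constant)),
                    meta={"source": "elastic_network"},
                )
            )
    if attach:
        for bond in bonds:
            molecule.add_interaction(bond)
    return bonds


def _fmt_k(k: float) -> str:
    return str(int(k)) if float(k) == int(k) else f"{k:g}"


def generate_en_system(
    system: SystemOfMolecules,
    params: ENParams,
    ledger: Optional[WarningLedger] = None,
) -> list[Interaction]:
    """Apply EN generation to every molecule of a system.

    For ``unit='all'`` bonds between distinct molecules would also be
    eligible; since an interaction cannot span two molecule graphs, a
    cross-molecule pair within the cutoff merges nothing — the pair is
    reported once as a diagnostic and skipped.  (Within this package the
    ``all`` unit therefore differs from ``molecule`` only in that report.)
    """
    out: list[Interaction] = []
    for mol in system.molecules:
        out.extend(generate_en(mol, params, ledger))
    return out
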