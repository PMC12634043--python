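# Methods

## The pipeline model

cgweaver treats topology generation as transformations of one data
structure: an undirected *molecule graph* whose nodes are particles
(atoms or coarse-grained beads) with attributes — only atom name, residue
name and residue number are mandatory — and whose edges are bonded
connectivity. Everything a force field knows is expressed as small
graphs too: *blocks* (canonical residue content), *links* (inter-residue
interaction patterns), *modifications* (deltas to canonical residues) and
*mappings* (a fragment at two resolutions plus a weighted particle
correspondence). The pipeline is six stages:

1. **Read.** PDB (fixed columns, first model, altloc by occupancy) or
   GRO. Coordinates are nm internally.
2. **Bond inference and partitioning.** Bonds come from CONECT records,
   from interatomic distances, or from atom names matched against blocks
   and links; every bonded component becomes one molecule. Two chains
   joined by a disulfide bridge are one molecule; an unbonded cofactor is
   its own molecule.
3. **Identify and repair.** Every residue is compared to the block its
   residue name selects. The comparison is a maximum common induced
   subgraph on the element-labelled graphs, so misnamed atoms are
   recovered and renamed; block atoms absent from the input are added as
   coordinate-free nodes (detection, not reconstruction); input atoms the
   block does not describe are *extras*. Extras are then explained by
   modifications: the smallest set of modifications whose added atoms
   exactly cover the extras, anchors matching canonical atoms, is applied
   (protonated histidine = neutral histidine + one ring proton;
   phosphotyrosine = tyrosine + phosphate). Non-default residue names
   (HSP, HIP, HSD, HSE) short-circuit this search through an alias table.
   Chain ends with a free link-in/out atom receive terminal
   modifications.
4. **Resolution transformation.** Mappings are placed greedily,
   longest residue scope first; each bead's position is the weighted mean
   of its source atoms (file weights by default; mass or uniform
   weighting on request). If only some sources have coordinates the
   position is estimated from those and a warning is recorded; if none
   have, the bead is emitted coordinate-free. Bead edges appear wherever
   a mapped source bond crosses two beads — this is what turns the
   atomistic disulfide bond into a CG sidechain-sidechain edge. Virtual
   sites are computed afterwards in dependency order.
5. **Links and post-processing.** Link patterns are matched by subgraph
   isomorphism with attribute matchers (names, residue-name choices,
   secondary structure) and residue-offset consistency; file order is
   precedence and later links replace earlier interactions on the same
   particles. The elastic network (below) is generated last.
6. **Write.** Deterministic GROMACS itp/top and gro/pdb output, with the
   citations of every block/modification/link actually used emitted as
   header comments.

## Subgraph matching

The matcher is a VF2-style recursive monomorphism search: pattern nodes
are ordered once by (candidate rarity, degree), candidates are tried in
sorted node order, and a new pair must preserve every pattern edge into
already-matched nodes. Enumeration is therefore deterministic, which the
pipeline relies on for reproducible output. Residue repair uses a
McGregor-style branch-and-bound maximum-common-induced-subgraph variant
of the same idea, scoring candidates by (matched atoms, exact name
agreements) so that symmetric rings (TYR, HIS) resolve to the
correspondence that preserves the most input names, ties broken by the
search's fixed order. A fast path accepts the identity correspondence
outright when names, elements and induced edges already agree, so the
search only runs on damaged residues. These routines are intended for
residue-sized graphs (tens of nodes), not whole molecules.

The default node predicate is element equality when both elements are
known, atom-name equality otherwise — names in deposited structures are
unreliable, elements are not.

## Bond inference

The distance criterion accepts a pair as bonded when
`d <= 1.2 * (r_i + r_j)` with Cordero covalent radii; 1.2 is the
conventional tolerance. Hydrogens are capped at one bond (their closest
heavy atom). The names strategy copies intra-residue bonds from the
block and applies two-atom links with a contiguous offset window across
consecutive residue numbers; `auto` prefers CONECT, then distance, then
names.

## Elastic network

EN bonds are emitted for every unordered pair of eligible beads passing a
triple filter: measured distance within `[lower_cutoff, upper_cutoff]`,
residue-graph distance at least the residue minimum distance (RMD), and
both beads inside the same EN unit (`all`/`molecule`/`chain`/`region`).
Defaults: upper cutoff 0.9 nm, lower 0.0 nm, force constant
700 kJ·mol⁻¹·nm⁻², RMD 3 (part of the protein model — the RMD keeps the
EN from competing with backbone bonds/angles/dihedrals), unit
`molecule`; all CLI-overridable. Because the RMD is a graph distance,
residues joined by a disulfide bridge count as neighbours and get no EN
bond. EN bonds use GROMACS bond function type 6 so they generate no
exclusions, are tagged `source=elastic_network`, record the measured
distance rounded to 5 decimals as their equilibrium length, and never
become graph edges — they cannot alter partitioning or later graph
distances. Pairs spanning two different declared regions get no bond
(regions are independent units). One deliberate narrowing: EN units
larger than a molecule (`all`) generate the same bonds as `molecule`,
because an interaction cannot span two molecule graphs in this package's
output model; the `all` unit is retained for interface compatibility.

## Warning ledger and output policy

Diagnostics form a closed taxonomy (`unrecognized-residue`,
`unexpected-atoms`, `missing-atoms`, `missing-coordinates`, `ss-failure`,
`empty-selection`, `io`). Categories can be ignored selectively and a
warning budget can be granted; otherwise a single unignored warning
blocks *all* output and the run exits 1, so corrupted inputs cannot leak
into downstream simulation steps. Hard stage errors exit 2. The
pipeline itself has no randomness; identical inputs give byte-identical
outputs.

Structures without hydrogens are valid inputs: absent hydrogens in
otherwise complete residues are missing-but-unwarned by default
(`-strict-h` restores the warnings).

## Synthetic fixtures: what they emulate and what they do not

The bundled generator builds heavy-atom structures with idealized
geometry — planar zigzag backbones (0.36 nm residue spacing), regular
rings, bonded pairs placed inside the distance criterion and non-bonded
pairs safely outside it — for six shapes: linear peptides, cyclic
peptides, disulfide-bridged two-chain dimers, the cyclic six-unit crown
ether, branched polyethylene (two linear, three branched, two linear
units) and a protein with disordered tails flanking a structured core.
Corruption operators reproduce the classic failure taxonomy of
high-throughput structure sets: dropped atoms, whole sidechains removed
(missing bead coordinates), garbled atom names, swapped elements,
stretched ring bonds, and the glycine-with-Cβ malformation. Each
corrupted structure carries a ground-truth manifest of exactly which
residues were damaged, so tests can assert that the ledger flags all of
them and nothing else.

Passing on these fixtures demonstrates *topological* correctness —
graph repair, mapping covers, link matching, EN filters, exit-status
policy. It does not demonstrate physical realism: geometries are
idealized, the bundled force-field parameters are synthetic
demonstrations (explicitly not for production use), and real crystal
structures add disorder (occupancies, insertion codes, chain breaks) far
beyond what the generator emulates.

## Numerical and design choices

* Mapping placement is validated by residue-name runs over bonded,
  consecutively numbered residues after repair has canonicalized all
  names; the general isomorphism machinery still backs repair, link
  matching and modification detection.
* Dominant-residue attribute inheritance for beads: largest total mapped
  weight, ties to the lowest residue number.
* Modification cover selection: fewest modifications, then name order.
* Duplicate interactions: same kind + same particle set ⇒ the later
  source replaces the earlier one (idempotent link application).
* Missing positions are written as a (0,0,0) sentinel plus a warning,
  never silently.
* `nrexcl` defaults to 1 for the CG demonstration force field and 3 for
  the atomistic one, stored as a force-field variable.
* Robustness sweeps in the test suite use 100 variants per corruption
  class of 6-residue peptides (≥500 corrupted structures total), sized so
  the whole suite stays interactive on one CPU.

## Known limitations

No mmCIF, trajectories or periodic imaging; no hydrogen reconstruction
or pKa prediction; no secondary-structure algorithm (annotation is
supplied externally, with an all-coil fallback that still demands
complete backbone coordinates in `auto` mode); no Gō-model workflow; no
backmapping; no energy evaluation or MD-engine invocation. The bundled
force field is a reduced demonstration set, not Martini.
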