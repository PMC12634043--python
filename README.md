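# cgweaver

Graph-based generation of molecular-dynamics topologies from atomistic
structures — for people who need GROMACS input files for coarse-grained
(Martini-style) or atomistic models of proteins, modified proteins, and
arbitrary polymers, and who need the conversion to *fail loudly* on
corrupted structures instead of producing quietly broken topologies.

Everything is a graph. A structure is read into a particle graph, bonds
are inferred (by distance against covalent radii, by atom names against
library fragments, or from CONECT records), and every bonded component
becomes a molecule — so two chains joined by a disulfide bridge are one
molecule and an unbonded cofactor is not. Each residue is compared to its
canonical library *block* by maximum-common-subgraph matching on the
element-labelled graphs: misnamed atoms are renamed, missing atoms
detected, and unexplained extra atoms matched against *modifications*
(protonation states, tautomers, PTMs, termini) as graph deltas — a
protonated histidine is recognized as neutral histidine plus one ring
proton, whether or not the residue name says so. Weighted fragment
*mappings* then transform the molecule to the target resolution
(bead position `= Σ wᵢrᵢ / Σ wᵢ` over source atoms), *links* add the
interactions that span residue boundaries, and an optional elastic
network adds harmonic bonds `V(r) = ½k(r − r₀)²` between backbone beads
filtered by distance cutoff, residue minimum distance (a graph distance,
default 3), and EN unit (`all`/`molecule`/`chain`/`region`).

A typed warning ledger governs output: unless warnings are explicitly
ignored (`-ignore`, `-maxwarn`), nothing is written and the run exits
nonzero. A bundled fixture generator produces synthetic peptides,
disulfide-bridged dimers, cyclic and branched polymers, and corrupted
variants with ground-truth manifests, so the whole pipeline is testable
without downloading anything.

## Worked example

Generate a tripeptide whose middle histidine carries an extra ring
proton (a protonated His written with the ordinary `HIS` residue name),
then convert it to the bundled demonstration CG force field:

```
$ cgweaver-fixtures linear_peptide -sequence ALA,HIS:HP,GLY -seed 0 -o his.pdb
wrote his.pdb (21 atoms)
$ cgweaver -f his.pdb -itp his.itp -x his.gro -cite
please cite:
  [demo_cg] cgweaver demonstration CG parameters (synthetic, not for production use)
  [demo_ff] cgweaver demonstration force field (synthetic parameters, not for production use)
wrote his.itp
wrote his.gro
```

The written `his.itp` begins:

```
[ atoms ]
    1     Qd     1    ALA     BB     1        1       72
    2     P5     2    HIS     BB     2        0       72
    3    SC4     2    HIS    SC1     3        0       36
    4     Qd     2    HIS    SC2     4        1       36
    5    SP1     2    HIS    SC3     5        0       36
    6     Qa     3    GLY     BB     6       -1       72
```

Reading it: the repair stage matched the extra hydrogen to the
`HIS-HP` modification, so the imidazole bead `SC2` became a charged `Qd`
bead with charge +1 — the protonation state survived the resolution
transformation even though the input resname was plain `HIS`. The
terminal residues picked up the charged N-/C-terminus modifications
(`Qd`/+1 on the first backbone bead, `Qa`/−1 on the last). Feeding the
same structure with a glycine carrying a spurious Cβ instead would print
an `unexpected-atoms` warning, write nothing, and exit 1.

An elastic network with explicit fine-tuning (10 nm cutoff, residue
minimum distance 4, per-chain units):

```
cgweaver -f protein.pdb -itp protein.itp -elastic -eu 10.0 -ermd 4 -eunit chain
```

## Layout

- `src/cgweaver/molgraph.py` — molecule graphs, subgraph isomorphism,
  maximum-common-subgraph matching
- `src/cgweaver/ffdata.py` — blocks/links/modifications/mappings and the
  `.ff`/`.map`/`.rtp` parsers (`docs/file_formats.md` documents the dialects)
- `src/cgweaver/structure_io.py` — PDB/GRO, bond inference, partitioning
- `src/cgweaver/repair.py` — canonical matching, modifications, termini
- `src/cgweaver/mapping.py` — resolution transformation, virtual sites
- `src/cgweaver/topology.py` — link application, itp read/write
- `src/cgweaver/elastic.py` — elastic networks
- `src/cgweaver/cli.py` — pipeline orchestration, `cgweaver` /
  `cgweaver-fixtures` entry points
- `src/cgweaver/fixtures.py` — synthetic structure generator
- `docs/methods.md` — model, assumptions, defaults and limitations
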