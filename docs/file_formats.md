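# Data file formats

All cgweaver data files are line-based text: `;` or `#` starts a comment,
fields are whitespace-separated, LF and CRLF are both accepted, trailing
whitespace is ignored. Sections are introduced by bracketed directives
(`[ atoms ]`). The bundled demonstration force field under
`src/cgweaver/data/` is written in these dialects and is meant to be read
and edited by hand.

## Fragment files (`.ff`)

A fragment file defines any number of *blocks*, *links* and
*modifications*, plus force-field-level variables and citation texts.

### `[ block ]`

Canonical graph and intra-fragment interactions of one residue / monomeric
repeat unit.

```
[ block ]
name ALA
nrexcl 3
citations demo_ff
[ atoms ]
; name  element  type  charge  [mass]
N  N NH1 -0.47
CA C CT1  0.07
[ bonds ]
N CA 1 0.147 5000     ; atom atom [funct + parameters...]
```

`-` marks an unknown element or type. Omitted masses come from the
element. Interaction sections: `bonds`, `angles`, `dihedrals`,
`impropers`, `constraints`, `pairs`, `exclusions`, `virtual_sitesn`
(`site funct constructing-atoms...`), `position_restraints`. Bonds and
constraints also create graph edges. Parameters are kept verbatim.

### `[ link ]`

A pattern of atoms in *different residues* plus the interactions to add
when it matches.

```
[ link ]
[ patterns ]
BB   resname=ALA|GLY secstruct=H   ; matchers are key=value, '|' = choice
+BB  secstruct=H
[ edges ]
BB +BB                             ; connectivity the molecule must have
[ angles ]
-BB BB +BB 2 96 700
```

Atom references carry a residue tag as a prefix:

* none — the anchor residue (offset 0);
* `+`/`-` runs — residues at that signed offset of the anchor's residue
  number, same chain (`++CA` = offset +2);
* `=` runs — *offset-free*: any other residue, as long as the `[ edges ]`
  requirements hold. Offset-free tags are how disulfide bridges and the
  repeat-unit links of cyclic polymers match regardless of numbering.

Other sections: `[ attributes ]` (`ref key value` node edits),
`[ remove_bonds ]` etc. (interaction patterns to delete). Links apply in
file order and a later link replaces an earlier interaction on the same
particles, so specialized links simply come later in the file.

### `[ modification ]`

A delta to a canonical block: protonation states, tautomers, PTMs,
termini.

```
[ modification ]
name TYR-P
resname TYR
[ atoms ]
; name element anchor|added
OH  O anchor
P   P added
[ edges ]
OH P
[ attributes ]
OH charge -0.5        ; edits on canonical atoms
[ cg ]
SC3 particle_type Qa  ; bead edits at the target resolution
SC3 charge -2.0
map P SC3             ; fold an added atom into a bead
```

Anchors must match canonical atoms by name; added atoms are matched to
the residue's unexplained atoms by element and connectivity. Every added
atom must be connected to an anchor.

### `[ variables ]` and `[ citations ]`

Free key/value lists. Keys the pipeline reads: `backbone` (atom names),
`cg_backbone`, `protein_resnames`, `nter_atom`/`cter_atom`,
`nter_mod`/`cter_mod`, `nrexcl`, and the alias table for force-field
protonation naming conventions:

```
alias.HSP HIS HIS-HP   ; input resname -> canonical block + modifications
alias.HSD HISD
```

## Mapping files (`.map`)

One `[ mapping ]` per fragment; equal weight split when an atom lists
several beads (the dialect carries no explicit weights).

```
[ mapping ]
name PEO2
from PEO PEO          ; source residue scope (may span several residues)
to PEO PEO            ; target blocks, one per scope position
[ atoms ]
; scope-index  atom  bead[...]   — beads may carry a "j:" scope prefix
1 C1 B1
1 O1 B1 2:B1          ; shared atom: half weight to each bead
2 C1 2:B1
```

Hydrogens are simply not listed: they carry zero mapping weight.

## GROMACS files

* `.rtp` (read): `[ bondedtypes ]`, residue sections with
  `[ atoms ]`/`[ bonds ]`/`[ impropers ]`…; `-`/`+` atom-name prefixes in
  bonds become inter-residue links with offsets −1/+1.
* `.itp` (read/write): `[ moleculetype ]`, `[ atoms ]`, interaction
  sections in canonical order. Elastic-network bonds are grouped under a
  `; elastic network` comment; `#include` is recorded as a diagnostic and
  not followed.
* `.pdb`/`.gro` (read/write): fixed-column; PDB is Å on disk, everything
  is nm in memory; first MODEL only; CONECT pairs are deduplicated and
  symmetrized; alternate locations resolve to the highest occupancy
  (ties: alphabetically first).
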