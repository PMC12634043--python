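; Demonstration coarse-grained force field (Martini-style bead model with
; synthetic parameters).  One backbone bead per amino acid plus 0-3
; sidechain beads; one bead per polymer repeat unit.

[ forcefield ]
name demo-cg

[ variables ]
cg_backbone BB
protein_resnames GLY ALA SER CYS HIS HISD TYR
nrexcl 1

[ citations ]
demo_cg cgweaver demonstration CG parameters (synthetic, not for production use)

[ block ]
name GLY
nrexcl 1
citations demo_cg
[ atoms ]
BB - P5 0.0 72.0

[ block ]
name ALA
nrexcl 1
citations demo_cg
[ atoms ]
BB - P4 0.0 72.0

[ block ]
name SER
nrexcl 1
citations demo_cg
[ atoms ]
BB  - P5 0.0 72.0
SC1 - P1 0.0 36.0
[ bonds ]
BB SC1 1 0.250 7500

[ block ]
name CYS
nrexcl 1
citations demo_cg
[ atoms ]
BB  - P5 0.0 72.0
SC1 - C5 0.0 36.0
[ bonds ]
BB SC1 1 0.310 7500

[ block ]
name HIS
nrexcl 1
citations demo_cg
[ atoms ]
BB  - P5  0.0 72.0
SC1 - SC4 0.0 36.0
SC2 - SP1 0.0 36.0
SC3 - SP1 0.0 36.0
[ bonds ]
BB SC1 1 0.320 7500
[ constraints ]
SC1 SC2 1 0.270
SC1 SC3 1 0.270
SC2 SC3 1 0.270

[ block ]
name HISD
nrexcl 1
citations demo_cg
[ atoms ]
BB  - P5  0.0 72.0
SC1 - SC4 0.0 36.0
SC2 - SP1 0.0 36.0
SC3 - SP1 0.0 36.0
[ bonds ]
BB SC1 1 0.320 7500
[ constraints ]
SC1 SC2 1 0.270
SC1 SC3 1 0.270
SC2 SC3 1 0.270

[ block ]
name TYR
nrexcl 1
citations demo_cg
[ atoms ]
BB  - P5  0.0 72.0
SC1 - SC4 0.0 36.0
SC2 - SC4 0.0 36.0
SC3 - SP1 0.0 36.0
[ bonds ]
BB SC1 1 0.320 7500
[ constraints ]
SC1 SC2 1 0.270
SC1 SC3 1 0.270
SC2 SC3 1 0.270

[ block ]
name PEO
nrexcl 1
citations demo_cg
[ atoms ]
B1 - EO 0.0 45.0

[ block ]
name ETH
nrexcl 1
citations demo_cg
[ atoms ]
B1 - C1 0.0 28.0

[ block ]
name ETB
nrexcl 1
citations demo_cg
[ atoms ]
B1 - C2 0.0 42.0

; ---------------------------------------------------------------- links
; protein backbone bond between bonded residues (offset-free so cyclic
; peptides close their backbone seam too)
[ link ]
[ patterns ]
BB
=BB
[ edges ]
BB =BB
[ bonds ]
BB =BB 1 0.350 1250

; default (coil) backbone angle
[ link ]
[ patterns ]
BB
=BB
==BB
[ edges ]
BB =BB
=BB ==BB
[ angles ]
BB =BB ==BB 2 127 20

; helical backbone angle: overrides the coil angle (file order = precedence)
[ link ]
[ patterns ]
BB   secstruct=H
+BB  secstruct=H
++BB secstruct=H
[ edges ]
BB +BB
+BB ++BB
[ angles ]
BB +BB ++BB 2 96 700

; disulfide bridge between cysteine sidechain beads (offset-free)
[ link ]
[ patterns ]
SC1  resname=CYS
=SC1 resname=CYS
[ edges ]
SC1 =SC1
[ bonds ]
SC1 =SC1 1 0.240 5000

; PEO backbone bond/angle (offset-free so cyclic molecules work)
[ link ]
[ patterns ]
B1  resname=PEO
=B1 resname=PEO
[ edges ]
B1 =B1
[ bonds ]
B1 =B1 1 0.330 7000

[ link ]
[ patterns ]
B1   resname=PEO
=B1  resname=PEO
==B1 resname=PEO
[ edges ]
B1 =B1
=B1 ==B1
[ angles ]
B1 =B1 ==B1 2 130 50

; polyethylene backbone bond between bonded repeat units
[ link ]
[ patterns ]
B1  resname=ETH|ETB
=B1 resname=ETH|ETB
[ edges ]
B1 =B1
[ bonds ]
B1 =B1 1 0.360 8000
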