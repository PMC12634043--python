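; Demonstration atomistic force field: a reduced amino-acid set
; (incl. two histidine tautomers), a PEO repeat unit and linear/branched
; polyethylene repeat units.  Canonical blocks are used by the repair
; stage; modifications describe protonation, a phospho-PTM and termini.

[ forcefield ]
name demo-aa

[ variables ]
backbone N CA C O
protein_resnames GLY ALA SER CYS HIS HISD TYR
nter_atom N
cter_atom C
nter_mod N-ter
cter_mod C-ter
nrexcl 3
alias.HSP HIS HIS-HP
alias.HIP HIS HIS-HP
alias.HSE HIS
alias.HSD HISD

[ citations ]
demo_ff cgweaver demonstration force field (synthetic parameters, not for production use)
demo_ptm cgweaver demonstration PTM parameters (synthetic)

[ block ]
name GLY
nrexcl 3
citations demo_ff
[ atoms ]
N  N NH1 0.0
CA C CT2 0.0
C  C C   0.0
O  O O   0.0
[ bonds ]
N CA
CA C
C O

[ block ]
name ALA
nrexcl 3
citations demo_ff
[ atoms ]
N  N NH1 0.0
CA C CT1 0.0
C  C C   0.0
O  O O   0.0
CB C CT3 0.0
[ bonds ]
N CA
CA C
C O
CA CB

[ block ]
name SER
nrexcl 3
citations demo_ff
[ atoms ]
N  N NH1 0.0
CA C CT1 0.0
C  C C   0.0
O  O O   0.0
CB C CT2 0.0
OG O OH1 0.0
[ bonds ]
N CA
CA C
C O
CA CB
CB OG

[ block ]
name CYS
nrexcl 3
citations demo_ff
[ atoms ]
N  N NH1 0.0
CA C CT1 0.0
C  C C   0.0
O  O O   0.0
CB C CT2 0.0
SG S S   0.0
[ bonds ]
N CA
CA C
C O
CA CB
CB SG

[ block ]
; epsilon tautomer: ring proton on NE2
name HIS
nrexcl 3
citations demo_ff
[ atoms ]
N   N NH1 0.0
CA  C CT1 0.0
C   C C   0.0
O   O O   0.0
CB  C CT2 0.0
CG  C CPH 0.0
ND1 N NR2 0.0
CD2 C CPH 0.0
CE1 C CPH 0.0
NE2 N NR1 0.0
HE2 H H   0.0
[ bonds ]
N CA
CA C
C O
CA CB
CB CG
CG ND1
ND1 CE1
CE1 NE2
NE2 CD2
CD2 CG
NE2 HE2

[ block ]
; delta tautomer: ring proton on ND1
name HISD
nrexcl 3
citations demo_ff
[ atoms ]
N   N NH1 0.0
CA  C CT1 0.0
C   C C   0.0
O   O O   0.0
CB  C CT2 0.0
CG  C CPH 0.0
ND1 N NR1 0.0
CD2 C CPH 0.0
CE1 C CPH 0.0
NE2 N NR2 0.0
HD1 H H   0.0
[ bonds ]
N CA
CA C
C O
CA CB
CB CG
CG ND1
ND1 CE1
CE1 NE2
NE2 CD2
CD2 CG
ND1 HD1

[ block ]
name TYR
nrexcl 3
citations demo_ff
[ atoms ]
N   N NH1 0.0
CA  C CT1 0.0
C   C C   0.0
O   O O   0.0
CB  C CT2 0.0
CG  C CA  0.0
CD1 C CA  0.0
CD2 C CA  0.0
CE1 C CA  0.0
CE2 C CA  0.0
CZ  C CA  0.0
OH  O OH1 0.0
[ bonds ]
N CA
CA C
C O
CA CB
CB CG
CG CD1
CD1 CE1
CE1 CZ
CZ CE2
CE2 CD2
CD2 CG
CZ OH

[ block ]
; poly(ethylene oxide) repeat unit  -CH2-CH2-O-
name PEO
nrexcl 3
citations demo_ff
[ atoms ]
C1 C CT2 0.0
C2 C CT2 0.0
O1 O OE  0.0
[ bonds ]
C1 C2
C2 O1

[ block ]
; linear polyethylene repeat unit  -CH2-CH2-
name ETH
nrexcl 3
citations demo_ff
[ atoms ]
C1 C CT2 0.0
C2 C CT2 0.0
[ bonds ]
C1 C2

[ block ]
; branched polyethylene repeat unit: backbone C1-C2, methyl branch on C1
name ETB
nrexcl 3
citations demo_ff
[ atoms ]
C1 C CT1 0.0
C2 C CT2 0.0
C3 C CT3 0.0
[ bonds ]
C1 C2
C1 C3

; ---------------------------------------------------------------- links
; peptide bond
[ link ]
[ patterns ]
C  resname=GLY|ALA|SER|CYS|HIS|HISD|TYR
+N resname=GLY|ALA|SER|CYS|HIS|HISD|TYR
[ edges ]
C +N
[ bonds ]
C +N 1

; PEO ether linkage between repeat units
[ link ]
[ patterns ]
O1  resname=PEO
+C1 resname=PEO
[ edges ]
O1 +C1
[ bonds ]
O1 +C1 1

; polyethylene C-C linkage between repeat units
[ link ]
[ patterns ]
C2  resname=ETH|ETB
+C1 resname=ETH|ETB
[ edges ]
C2 +C1
[ bonds ]
C2 +C1 1

; disulfide bridge (offset-free: the two cysteines may be anywhere,
; including on what were different chains)
[ link ]
[ patterns ]
SG  resname=CYS
=SG resname=CYS
[ edges ]
SG =SG
[ bonds ]
SG =SG 1

; -------------------------------------------------------- modifications
[ modification ]
; protonated epsilon-tautomer histidine: extra ring proton on ND1
name HIS-HP
resname HIS
citations demo_ff
[ atoms ]
ND1 N anchor
HD1 H added
[ edges ]
ND1 HD1
[ attributes ]
ND1 charge 0.5
NE2 charge 0.5
[ cg ]
SC2 particle_type Qd
SC2 charge 1.0

[ modification ]
; protonated delta-tautomer histidine: extra ring proton on NE2
name HISD-HP
resname HISD
citations demo_ff
[ atoms ]
NE2 N anchor
HE2 H added
[ edges ]
NE2 HE2
[ attributes ]
ND1 charge 0.5
NE2 charge 0.5
[ cg ]
SC3 particle_type Qd
SC3 charge 1.0

[ modification ]
; phosphorylated tyrosine: phosphate group on the hydroxyl oxygen
name TYR-P
resname TYR
citations demo_ptm
[ atoms ]
OH  O anchor
P   P added
O1P O added
O2P O added
O3P O added
[ edges ]
OH P
P O1P
P O2P
P O3P
[ attributes ]
OH charge -0.5
[ cg ]
SC3 particle_type Qa
SC3 charge -2.0
map P SC3
map O1P SC3
map O2P SC3
map O3P SC3

[ modification ]
; charged amino terminus (attribute-only delta: crystal structures carry
; no extra heavy atom at the N-terminus)
name N-ter
resname GLY|ALA|SER|CYS|HIS|HISD|TYR
citations demo_ff
[ atoms ]
N N anchor
[ attributes ]
N charge 1.0
[ cg ]
BB particle_type Qd
BB charge 1.0

[ modification ]
; charged carboxy terminus
name C-ter
resname GLY|ALA|SER|CYS|HIS|HISD|TYR
citations demo_ff
[ atoms ]
C C anchor
[ attributes ]
O charge -1.0
[ cg ]
BB particle_type Qa
BB charge -1.0
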