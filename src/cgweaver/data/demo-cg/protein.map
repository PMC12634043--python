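; Atomistic -> CG mappings for the demonstration amino-acid set.
; Hydrogens are not listed: they carry zero mapping weight.

[ mapping ]
name GLY
from GLY
to GLY
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB

[ mapping ]
name ALA
from ALA
to ALA
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB
1 CB BB

[ mapping ]
name SER
from SER
to SER
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB
1 CB SC1
1 OG SC1

[ mapping ]
name CYS
from CYS
to CYS
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB
1 CB SC1
1 SG SC1

[ mapping ]
name HIS
from HIS
to HIS
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB
1 CB SC1
1 CG SC1
1 ND1 SC2
1 CE1 SC2
1 CD2 SC3
1 NE2 SC3

[ mapping ]
name HISD
from HISD
to HISD
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB
1 CB SC1
1 CG SC1
1 ND1 SC2
1 CE1 SC2
1 CD2 SC3
1 NE2 SC3

[ mapping ]
name TYR
from TYR
to TYR
[ atoms ]
1 N BB
1 CA BB
1 C BB
1 O BB
1 CB SC1
1 CG SC1
1 CD1 SC2
1 CE1 SC2
1 CD2 SC3
1 CE2 SC3
1 CZ SC3
1 OH SC3
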