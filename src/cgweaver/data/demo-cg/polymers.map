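; Polymer repeat-unit mappings: one bead per monomeric repeat unit.

[ mapping ]
name PEO
from PEO
to PEO
[ atoms ]
1 C1 B1
1 C2 B1
1 O1 B1

[ mapping ]
name ETH
from ETH
to ETH
[ atoms ]
1 C1 B1
1 C2 B1

[ mapping ]
name ETB
from ETB
to ETB
[ atoms ]
1 C1 B1
1 C2 B1
1 C3 B1
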