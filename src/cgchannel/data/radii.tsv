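# Default effective bead radii (Å) for the one-bead-per-residue model.
# The radius stands in for the side-chain extent about the Cα position and
# scales with side-chain size; values are package defaults in the 2.0-4.0 Å
# range and can be replaced wholesale, or overridden per residue for
# active-site and channel-lining residues measured from a crystal structure.
# residue	radius_A
ALA	2.4
ARG	4.0
ASN	2.9
ASP	2.8
CYS	2.7
GLN	3.1
GLU	3.0
GLY	2.1
HIS	3.1
ILE	3.1
LEU	3.1
LYS	3.6
MET	3.2
PHE	3.4
PRO	2.8
SER	2.5
THR	2.7
TRP	3.6
TYR	3.5
VAL	2.9
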