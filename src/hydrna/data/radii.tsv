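# Group radii (Angstrom) used for solvent accessible surface area.
# NACCESS-style defaults: trigonal carbonyl carbon is narrower than
# tetrahedral/aromatic carbon; other elements by element symbol.
# kind	key	radius
name	C	1.76
element	C	1.87
element	N	1.65
element	O	1.40
element	S	1.85
element	P	1.90
element	SE	1.90
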