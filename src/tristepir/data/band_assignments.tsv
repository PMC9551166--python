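wavenumber_cm1	assignment	compound_class	part
3391	O-H, ν	Various	flower
3400	O-H, ν	Various	seed
3420	O-H, ν	Various	leaf
2930	C-H, ν_as	Alkane	flower
2927	C-H, ν_as	Alkane	seed
2922	C-H, ν_as	Alkane	leaf
2856	C-H, ν_s	Alkane	seed
2853	C-H, ν_s	Alkane	leaf
1736	C=O, ν	Ester	flower
1743	C=O, ν	Ester	seed
1729	C=O, ν	Ester	leaf
1648	N-H, δ	Amide I	seed
1626	C=O	Oxalate/aromatic amine	flower
1629	C=O	Oxalate/aromatic amine	flower
1624	C=O	Oxalate/aromatic amine	leaf
1548	N-H, δ	Amide II	seed
1443	C-H, δ	Alkane	flower
1459	C-H, δ	Alkane	seed
1417	C-H, δ	Alkene	flower
1318	C-O, ν	Saccharides	leaf
1145	C-O, ν	Saccharides	flower
1159	C-O, ν	Saccharides	seed
1156	C-O, ν	Saccharides	leaf
1102	C-O, ν	Saccharides	flower
1098	C-O, ν	Saccharides	leaf
1079	C-O, ν	Saccharides	seed
1058	C-O, ν	Saccharides	flower
1046	C-O, ν	Saccharides	seed
1050	C-O, ν	Saccharides	leaf
1019	C-O, ν	Saccharides	seed
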