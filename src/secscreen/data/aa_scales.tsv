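# Amino-acid property scales (one column per scale, standard compilation values).
# Provenance (citation key per scale):
#   polarity               Zimmerman-1968      (J Theor Biol 21:170)
#   hydrophobicity         Kyte-Doolittle-1982 (J Mol Biol 157:105)
#   area_buried            Rose-1985           (Science 229:834; average area buried on transfer to folded protein, A^2)
#   buried_residues        Chothia-1976        (J Mol Biol 105:1; % of residues 95% buried)
#   bulkiness              Zimmerman-1968      (J Theor Biol 21:170)
#   molar_refractivity     Jones-1975          (J Theor Biol 50:167)
#   recognition_factors    Fraga-1982          (Can J Chem 60:2606)
#   molecular_weight       residue formula weight, Da
#   transmembrane_tendency Zhao-London-2006    (Protein Sci 15:1987)
#   hplc_retention         Meek-1980           (PNAS 77:1632; retention at pH 7.4, min)
residue	polarity	hydrophobicity	area_buried	buried_residues	bulkiness	molar_refractivity	recognition_factors	molecular_weight	transmembrane_tendency	hplc_retention
A	0.00	1.8	86.6	11.2	11.50	4.34	78	89.09	0.38	0.5
C	1.48	2.5	132.3	4.1	13.46	35.77	89	121.16	-0.30	-6.8
D	49.70	-3.5	97.8	2.9	11.68	12.00	81	133.10	-3.27	-8.2
E	49.90	-3.5	113.9	1.8	13.57	17.26	78	147.13	-2.90	-16.9
F	0.35	2.8	194.1	5.1	19.80	29.40	81	165.19	1.98	13.2
G	0.00	-0.4	62.9	11.8	3.40	0.00	84	75.07	-0.19	0.0
H	51.60	-3.2	155.8	2.0	13.69	21.81	84	155.16	-1.44	-3.5
I	0.13	4.5	158.0	8.6	21.40	19.06	88	131.17	1.97	13.9
K	49.50	-3.9	115.5	0.05	15.71	21.29	87	146.19	-3.46	0.1
L	0.13	3.8	164.1	11.7	21.40	18.78	85	131.17	1.82	8.8
M	1.43	1.9	172.9	1.9	16.25	21.64	80	149.21	1.40	4.8
N	3.38	-3.5	103.3	2.9	12.82	13.28	94	132.12	-1.62	0.8
P	1.58	-1.6	92.9	2.7	17.43	10.93	91	115.13	-1.44	6.1
Q	3.53	-3.5	119.2	1.6	14.45	17.56	87	146.15	-1.84	-4.8
R	52.00	-4.5	162.2	0.5	14.28	26.66	95	174.20	-2.57	0.8
S	1.67	-0.8	85.6	8.0	9.47	6.35	107	105.09	-0.53	1.2
T	1.66	-0.7	106.5	4.9	15.77	11.01	93	119.12	-0.32	2.7
V	0.13	4.2	141.0	12.9	21.57	13.92	89	117.15	1.46	2.7
W	2.10	-0.9	224.6	2.2	21.67	42.53	104	204.23	1.53	14.9
Y	1.61	-1.3	177.7	2.6	18.03	31.53	84	181.19	0.49	6.1
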