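# Auxiliary amino-acid scales used by the synthetic-screen generator's planted
# secretability signal (structure/flexibility proxies). Not part of the ten
# property scales used for classifier feature extraction.
#   helix_propensity  Chou-Fasman-1978          (Annu Rev Biochem 47:251; P_alpha)
#   flexibility       Bhaskaran-Ponnuswamy-1988 (Int J Pept Protein Res 32:241)
residue	helix_propensity	flexibility
A	1.42	0.357
C	0.70	0.346
D	1.01	0.511
E	1.51	0.497
F	1.13	0.314
G	0.57	0.544
H	1.00	0.323
I	1.08	0.462
K	1.16	0.466
L	1.21	0.365
M	1.45	0.295
N	0.67	0.463
P	0.57	0.509
Q	1.11	0.493
R	0.98	0.529
S	0.77	0.507
T	0.83	0.444
V	1.06	0.386
W	1.08	0.305
Y	0.69	0.420
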