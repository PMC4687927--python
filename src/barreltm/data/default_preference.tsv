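# SYNTHETIC default boundary-preference table.
# Estimated from a generated barrel corpus (barreltm.synthetic,
# BarrelSpec defaults, 101 proteins, seed 20150101) for out-of-the-box
# operation and demos. NOT derived from real structures: estimate your
# own table from annotated proteins, or supply one, for real use.
amino_acid	score_N	score_C
A	3.165006	-0.120855
C	3.040718	-0.915836
D	-3.124831	0.176003
E	-3.490672	-0.004283
F	4.758201	1.224721
G	-3.564487	-0.078098
H	-1.790506	-0.162097
I	3.123278	-0.205244
K	-3.275444	0.210945
L	3.405982	-0.582281
M	3.187149	-0.720495
N	-2.737578	-0.354282
P	-2.988456	-0.150594
Q	-2.759536	0.038798
R	-3.153179	-0.354846
S	-3.427720	0.058669
T	-3.151903	-0.201566
V	3.080753	-0.390375
W	4.793342	1.258252
Y	4.909883	1.273464
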