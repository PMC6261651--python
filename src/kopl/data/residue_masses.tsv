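residue	monoisotopic_Da	average_Da
A	71.03711378471	71.0788
C	103.00918478471	103.1388
D	115.02694302383001	115.0886
E	129.04259308796998	129.1155
F	147.06841391298997	147.1766
G	57.02146372057	57.0519
H	137.05891185845002	137.1411
I	113.08406397713001	113.1594
K	128.09496301399997	128.1741
L	113.08406397713001	113.1594
M	131.04048491299	131.1926
N	114.04292744114001	114.1038
P	97.05276384885	97.1167
Q	128.05857750527997	128.1307
R	156.10111102359997	156.1875
S	87.03202840427001	87.0782
T	101.04767846841	101.1051
V	99.06841391299	99.1326
W	186.07931294985997	186.2132
Y	163.06332853254997	163.176
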