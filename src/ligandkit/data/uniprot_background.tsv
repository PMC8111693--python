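# Amino-acid background frequencies (percent) from the UniProtKB/Swiss-Prot
# proteome-wide composition statistics. Normalized to sum to 1 on load.
aa	percent
A	8.25
R	5.53
N	4.06
D	5.46
C	1.38
Q	3.93
E	6.72
G	7.07
H	2.27
I	5.91
L	9.65
K	5.80
M	2.41
F	3.86
P	4.74
S	6.65
T	5.36
W	1.10
Y	2.92
V	6.86
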