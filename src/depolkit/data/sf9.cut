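# Spodoptera frugiperda (Sf9) codon usage table.
# Columns: codon, one-letter amino acid ('*' = stop), fraction of synonymous use.
# Fractions are representative values; the reader renormalizes per amino acid.
TTT F 0.51
TTC F 0.49
TTA L 0.11
TTG L 0.19
CTT L 0.17
CTC L 0.15
CTA L 0.09
CTG L 0.29
ATT I 0.40
ATC I 0.33
ATA I 0.27
ATG M 1.00
GTT V 0.25
GTC V 0.21
GTA V 0.17
GTG V 0.37
TCT S 0.19
TCC S 0.15
TCA S 0.17
TCG S 0.12
AGT S 0.19
AGC S 0.18
CCT P 0.26
CCC P 0.19
CCA P 0.33
CCG P 0.22
ACT T 0.27
ACC T 0.24
ACA T 0.29
ACG T 0.20
GCT A 0.30
GCC A 0.24
GCA A 0.27
GCG A 0.19
TAT Y 0.53
TAC Y 0.47
CAT H 0.55
CAC H 0.45
CAA Q 0.51
CAG Q 0.49
AAT N 0.52
AAC N 0.48
AAA K 0.46
AAG K 0.54
GAT D 0.56
GAC D 0.44
GAA E 0.52
GAG E 0.48
TGT C 0.52
TGC C 0.48
TGG W 1.00
CGT R 0.19
CGC R 0.14
CGA R 0.14
CGG R 0.09
AGA R 0.26
AGG R 0.18
GGT G 0.26
GGC G 0.22
GGA G 0.34
GGG G 0.18
TAA * 0.46
TAG * 0.21
TGA * 0.33
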