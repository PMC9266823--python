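# Heavy-atom nonbonded parameter table (Amber-99-style subset).
# Hydrogen partial charges are collapsed onto their bonded heavy atoms so
# per-residue sums equal the residue formal charge.
# columns: resname atomname charge(e) epsilon(kcal/mol) rmin_half(A)
# combining: lorentz-berthelot
ALA  N    -0.1438 0.1700 1.8240
ALA  CA    0.1160 0.0860 1.9080
ALA  C     0.5973 0.0860 1.9080
ALA  O    -0.5679 0.2100 1.6612
ALA  CB   -0.0016 0.0860 1.9080
ARG  N    -0.1438 0.1700 1.8240
ARG  CA    0.1160 0.0860 1.9080
ARG  C     0.5973 0.0860 1.9080
ARG  O    -0.5679 0.2100 1.6612
ARG  CB   -0.0516 0.0860 1.9080
ARG  CG    0.0700 0.0860 1.9080
ARG  CD    0.2300 0.0860 1.9080
ARG  NE    0.0100 0.1700 1.8240
ARG  CZ    0.6400 0.0860 1.9080
ARG  NH1   0.0500 0.1700 1.8240
ARG  NH2   0.0500 0.1700 1.8240
ASN  N    -0.1438 0.1700 1.8240
ASN  CA    0.1160 0.0860 1.9080
ASN  C     0.5973 0.0860 1.9080
ASN  O    -0.5679 0.2100 1.6612
ASN  CB    0.1128 0.0860 1.9080
ASN  CG    0.5973 0.0860 1.9080
ASN  OD1  -0.5679 0.2100 1.6612
ASN  ND2  -0.1438 0.1700 1.8240
ASP  N    -0.1438 0.1700 1.8240
ASP  CA    0.1160 0.0860 1.9080
ASP  C     0.5973 0.0860 1.9080
ASP  O    -0.5679 0.2100 1.6612
ASP  CB   -0.1982 0.0860 1.9080
ASP  CG    0.7994 0.0860 1.9080
ASP  OD1  -0.8014 0.2100 1.6612
ASP  OD2  -0.8014 0.2100 1.6612
CYS  N    -0.1438 0.1700 1.8240
CYS  CA    0.1160 0.0860 1.9080
CYS  C     0.5973 0.0860 1.9080
CYS  O    -0.5679 0.2100 1.6612
CYS  CB    0.1984 0.0860 1.9080
CYS  SG   -0.2000 0.2500 2.0000
GLN  N    -0.1438 0.1700 1.8240
GLN  CA    0.1160 0.0860 1.9080
GLN  C     0.5973 0.0860 1.9080
GLN  O    -0.5679 0.2100 1.6612
GLN  CB    0.1128 0.0860 1.9080
GLN  CG    0.0000 0.0860 1.9080
GLN  CD    0.5973 0.0860 1.9080
GLN  OE1  -0.5679 0.2100 1.6612
GLN  NE2  -0.1438 0.1700 1.8240
GLU  N    -0.1438 0.1700 1.8240
GLU  CA    0.1160 0.0860 1.9080
GLU  C     0.5973 0.0860 1.9080
GLU  O    -0.5679 0.2100 1.6612
GLU  CB   -0.0494 0.0860 1.9080
GLU  CG   -0.1200 0.0860 1.9080
GLU  CD    0.8054 0.0860 1.9080
GLU  OE1  -0.8188 0.2100 1.6612
GLU  OE2  -0.8188 0.2100 1.6612
GLY  N    -0.1438 0.1700 1.8240
GLY  CA    0.1144 0.0860 1.9080
GLY  C     0.5973 0.0860 1.9080
GLY  O    -0.5679 0.2100 1.6612
HIS  N    -0.1438 0.1700 1.8240
HIS  CA    0.1160 0.0860 1.9080
HIS  C     0.5973 0.0860 1.9080
HIS  O    -0.5679 0.2100 1.6612
HIS  CB   -0.0516 0.0860 1.9080
HIS  CG    0.1400 0.0860 1.9080
HIS  ND1  -0.1700 0.1700 1.8240
HIS  CD2   0.1000 0.0860 1.9080
HIS  CE1   0.2500 0.0860 1.9080
HIS  NE2  -0.2700 0.1700 1.8240
ILE  N    -0.1438 0.1700 1.8240
ILE  CA    0.1160 0.0860 1.9080
ILE  C     0.5973 0.0860 1.9080
ILE  O    -0.5679 0.2100 1.6612
ILE  CB   -0.0016 0.0860 1.9080
ILE  CG1   0.0000 0.0860 1.9080
ILE  CG2   0.0000 0.0860 1.9080
ILE  CD1   0.0000 0.0860 1.9080
LEU  N    -0.1438 0.1700 1.8240
LEU  CA    0.1160 0.0860 1.9080
LEU  C     0.5973 0.0860 1.9080
LEU  O    -0.5679 0.2100 1.6612
LEU  CB   -0.0516 0.0860 1.9080
LEU  CG    0.0500 0.0860 1.9080
LEU  CD1   0.0000 0.0860 1.9080
LEU  CD2   0.0000 0.0860 1.9080
LYS  N    -0.1438 0.1700 1.8240
LYS  CA    0.1160 0.0860 1.9080
LYS  C     0.5973 0.0860 1.9080
LYS  O    -0.5679 0.2100 1.6612
LYS  CB   -0.0316 0.0860 1.9080
LYS  CG    0.0200 0.0860 1.9080
LYS  CD    0.0600 0.0860 1.9080
LYS  CE    0.3300 0.0860 1.9080
LYS  NZ    0.6200 0.1700 1.8240
MET  N    -0.1438 0.1700 1.8240
MET  CA    0.1160 0.0860 1.9080
MET  C     0.5973 0.0860 1.9080
MET  O    -0.5679 0.2100 1.6612
MET  CB    0.0384 0.0860 1.9080
MET  CG    0.1000 0.0860 1.9080
MET  SD   -0.2700 0.2500 2.0000
MET  CE    0.1300 0.0860 1.9080
PHE  N    -0.1438 0.1700 1.8240
PHE  CA    0.1160 0.0860 1.9080
PHE  C     0.5973 0.0860 1.9080
PHE  O    -0.5679 0.2100 1.6612
PHE  CB   -0.0116 0.0860 1.9080
PHE  CG    0.0100 0.0860 1.9080
PHE  CD1   0.0000 0.0860 1.9080
PHE  CD2   0.0000 0.0860 1.9080
PHE  CE1   0.0000 0.0860 1.9080
PHE  CE2   0.0000 0.0860 1.9080
PHE  CZ    0.0000 0.0860 1.9080
PRO  N    -0.2548 0.1700 1.8240
PRO  CA    0.1160 0.0860 1.9080
PRO  C     0.5973 0.0860 1.9080
PRO  O    -0.5679 0.2100 1.6612
PRO  CB   -0.0106 0.0860 1.9080
PRO  CG    0.0200 0.0860 1.9080
PRO  CD    0.1000 0.0860 1.9080
SER  N    -0.1438 0.1700 1.8240
SER  CA    0.1160 0.0860 1.9080
SER  C     0.5973 0.0860 1.9080
SER  O    -0.5679 0.2100 1.6612
SER  CB    0.2684 0.0860 1.9080
SER  OG   -0.2700 0.2100 1.6612
THR  N    -0.1438 0.1700 1.8240
THR  CA    0.1160 0.0860 1.9080
THR  C     0.5973 0.0860 1.9080
THR  O    -0.5679 0.2100 1.6612
THR  CB    0.3384 0.0860 1.9080
THR  OG1  -0.3400 0.2100 1.6612
THR  CG2   0.0000 0.0860 1.9080
TRP  N    -0.1438 0.1700 1.8240
TRP  CA    0.1160 0.0860 1.9080
TRP  C     0.5973 0.0860 1.9080
TRP  O    -0.5679 0.2100 1.6612
TRP  CB   -0.1716 0.0860 1.9080
TRP  CG   -0.1400 0.0860 1.9080
TRP  CD1   0.1000 0.0860 1.9080
TRP  CD2   0.1200 0.0860 1.9080
TRP  NE1  -0.0500 0.1700 1.8240
TRP  CE2   0.1400 0.0860 1.9080
TRP  CE3   0.0000 0.0860 1.9080
TRP  CZ2   0.0000 0.0860 1.9080
TRP  CZ3   0.0000 0.0860 1.9080
TRP  CH2   0.0000 0.0860 1.9080
TYR  N    -0.1438 0.1700 1.8240
TYR  CA    0.1160 0.0860 1.9080
TYR  C     0.5973 0.0860 1.9080
TYR  O    -0.5679 0.2100 1.6612
TYR  CB   -0.0016 0.0860 1.9080
TYR  CG   -0.0300 0.0860 1.9080
TYR  CD1   0.0000 0.0860 1.9080
TYR  CD2   0.0000 0.0860 1.9080
TYR  CE1   0.0000 0.0860 1.9080
TYR  CE2   0.0000 0.0860 1.9080
TYR  CZ    0.3300 0.0860 1.9080
TYR  OH   -0.3000 0.2100 1.6612
VAL  N    -0.1438 0.1700 1.8240
VAL  CA    0.1160 0.0860 1.9080
VAL  C     0.5973 0.0860 1.9080
VAL  O    -0.5679 0.2100 1.6612
VAL  CB   -0.0016 0.0860 1.9080
VAL  CG1   0.0000 0.0860 1.9080
VAL  CG2   0.0000 0.0860 1.9080
ACE  CH3  -0.0293 0.0860 1.9080
ACE  C     0.5972 0.0860 1.9080
ACE  O    -0.5679 0.2100 1.6612
NME  N    -0.1438 0.1700 1.8240
NME  CH3   0.1438 0.0860 1.9080
HOH  O     0.0000 0.2100 1.6612
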