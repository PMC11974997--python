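# Default RNA 3D motif library (curated).
#
# Dialect: one record per line,  NAME TYPE role=CONSENSUS ...
#   HL  roles: L1..Lk loop Rk..R1   (k correlated flank pairs, k <= 4)
#   BL  roles: L loop R
#   IL  roles: outL loopL inL inR loopR outR
#   J3  roles: S1 S2 S3
#   J4  roles: S1 S2 S3 S4
#   BS  roles: seg
# CONSENSUS is an IUPAC RNA string; '-' marks an empty segment (modeled by
# an empty-consensus profile HMM that still admits insertions).
# Closing Watson-Crick pairs are never part of a motif.
#
# 51 motifs; with topological variants (HL 1, BL 2, IL 2, J3 3, J4 4, BS 1)
# they compile to 96 variant models.

# --- hairpin loop motifs (15) ---
GNRA        HL  L1=G loop=N R1=RA
UNCG        HL  L1=U loop=NC R1=G
UUCG        HL  L1=U loop=UC R1=G
CUUG        HL  L1=C loop=UU R1=G
GANC        HL  L1=G loop=AN R1=C
UMAC        HL  L1=U loop=MA R1=C
AGNN        HL  L1=A loop=GN R1=N
GAGAU       HL  L1=GA loop=G R1=AU
U-turn      HL  L1=U loop=NR R1=-
T-loop      HL  L1=UG loop=GUUCRA R1=UC
CsrA-loop   HL  L1=A loop=GGA R1=U
ANYA        HL  L1=A loop=NY R1=A
IRE-loop    HL  L1=C loop=AGU R1=G
s2m-loop    HL  L1=GG loop=CGNGG R1=CU
D-loop      HL  L1=AG loop=UU R1=GA

# --- bulge loop motifs (4) ---
DockingElbow BL  L=U loop=RA R=-
A-bulge      BL  L=- loop=A R=-
TAR-UCU      BL  L=U loop=CU R=-
UU-bulge     BL  L=- loop=UU R=-

# --- internal loop motifs (17) ---
K-turn      IL  outL=- loopL=- inL=GA inR=AG loopR=RNN outR=-
K-turn-b    IL  outL=- loopL=- inL=GA inR=AG loopR=NN outR=-
pK-turn     IL  outL=- loopL=N inL=GA inR=AG loopR=RN outR=-
rK-turn     IL  outL=AG loopL=NNR inL=- inR=- loopR=- outR=GA
C-loop      IL  outL=C loopL=ACA inL=- inR=- loopR=UAU outR=G
C-loop-b    IL  outL=C loopL=AC inL=- inR=- loopR=UA outR=G
LoopE       IL  outL=A loopL=GUA inL=G inR=A loopR=AUG outR=U
SarcinRicin IL  outL=G loopL=UA inL=G inR=A loopR=GAR outR=A
G-bulge     IL  outL=- loopL=G inL=A inR=A loopR=- outR=G
Hook-turn   IL  outL=- loopL=UG inL=A inR=A loopR=CC outR=-
J4a4b       IL  outL=A loopL=GG inL=- inR=- loopR=GAA outR=U
TandemGA    IL  outL=- loopL=GA inL=- inR=- loopR=AG outR=-
ShearedGA   IL  outL=G loopL=A inL=- inR=- loopR=A outR=G
UAA-GAN     IL  outL=U loopL=AA inL=- inR=- loopR=GAN outR=-
E-loop      IL  outL=A loopL=GU inL=A inR=A loopR=UG outR=A
TandemUG    IL  outL=U loopL=G inL=- inR=- loopR=U outR=G
PlatformIL  IL  outL=- loopL=AA inL=- inR=- loopR=N outR=-

# --- 3-way junction motifs (6) ---
HammerheadJ3 J3  S1=CUGANGA S2=GAAA S3=-
TPP-J3       J3  S1=CU S2=GAGA S3=A
J3-groupII   J3  S1=AGC S2=- S3=UA
PurineJ3     J3  S1=UCCA S2=UA S3=CU
SAM-J3       J3  S1=GA S2=AU S3=C
Mg-J3        J3  S1=AC S2=GA S3=-

# --- 4-way junction motifs (4) ---
HCV-IRES-J4  J4  S1=- S2=UA S3=- S4=GG
U1-J4        J4  S1=AU S2=- S3=CC S4=-
tRNA-J4      J4  S1=U S2=- S3=G S4=UC
HpRz-J4      J4  S1=GA S2=- S3=AC S4=-

# --- branch segment motifs (5) ---
TloopDomain  BS  seg=UUCG
CRC-domain   BS  seg=GGAU
CsrA-BS      BS  seg=AGGA
LoopE-BS1    BS  seg=AGUA
LoopE-BS2    BS  seg=AUGG
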