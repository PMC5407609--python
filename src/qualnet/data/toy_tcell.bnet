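# @nodes: TCR S1 LCK ZAP70 PI3K S2 ITK LAT PLCG1 DAG DGK RAS RAF1 MAPK1 AP1 NFAT NFKB1
TCR = S1
LCK = TCR
ZAP70 = LCK
PI3K = S2
ITK = PI3K
LAT = ITK | ZAP70
PLCG1 = LAT
DAG = !DGK & PLCG1
DGK = MAPK1
RAS = DAG
RAF1 = RAS
MAPK1 = RAF1
AP1 = MAPK1
NFAT = DAG
NFKB1 = ITK & LAT & ZAP70
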