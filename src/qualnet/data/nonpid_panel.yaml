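# Non-PID screen over the feedback-loop-rich proteins of the CD4+ T-cell
# model: knockouts throughout, except CBL as knockin because CBL is off in
# the wild-type attractor.
- {node: MAPK1, state: 0}
- {node: DAG, state: 0}
- {node: PRKCQ, state: 0}
- {node: MAP3K7, state: 0}
- {node: LCP2, state: 0}
- {node: PLCG1, state: 0}
- {node: LAT, state: 0}
- {node: CBL, state: 1}
- {node: ABL1, state: 0}
- {node: GRAP2, state: 0}
- {node: TRAF6, state: 0}
- {node: VAV1, state: 0}
- {node: MAP2K1, state: 0}
- {node: RAF1, state: 0}
- {node: RAS, state: 0}
- {node: RASGRP1, state: 0}
- {node: PIP3, state: 0}
- {node: SOS, state: 0}
- {node: TCRP, state: 0}
- {node: DGK, state: 0}
- {node: PDPK1, state: 0}
- {node: MAP3K4, state: 0}
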