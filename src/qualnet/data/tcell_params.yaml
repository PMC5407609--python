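# Non-default normalized-HillCube parameters of the CD4+ T-cell activation
# model (nodes on negative feedback loops).  source "*" covers all
# influencing nodes of the target.  Records apply in order; repeated keys
# are flagged and the later record wins.
defaults:
  n: 3
  k: 0.5
  tau: 1
overrides:
  - {target: PAG1, source: "*", tau: 1, n: 20, k: 0.9}
  - {target: PAG1, source: "*", tau: 1, n: 20, k: 0.9}
  - {target: DAG, source: DGK, tau: 1, n: 20, k: 0.9}
  - {target: DGK, source: "*", tau: 1, n: 20, k: 0.9}
  - {target: DGK, source: "*", tau: 1, n: 3, k: 0.9}
  - {target: DGK, source: "*", tau: 1, n: 3, k: 0.9}
  - {target: LCK, source: MAPK1, tau: 10, n: 20, k: 0.1}
  - {target: CBL, source: "*", tau: 3, n: 20, k: 0.9}
  - {target: CALN, source: CABIN1, tau: 1, n: 3, k: 0.9}
  - {target: CALN, source: RCAN1, tau: 1, n: 3, k: 0.9}
  - {target: CALN, source: AKAP5, tau: 1, n: 3, k: 0.9}
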