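# Primary-immunodeficiency perturbation panel for the CD4+ T-cell model:
# knockouts (state 0) for loss-of-function PIDs, knockin (state 1) for
# PI3K overactivity.
- {node: LCK, state: 0, label: LCK-deficiency}
- {node: ZAP70, state: 0, label: ZAP70-deficiency}
- {node: ITK, state: 0, label: ITK-deficiency}
- {node: IKKB, state: 0, label: IKKB-deficiency}
- {node: NEMO, state: 0, label: NEMO-deficiency}
- {node: CARD11, state: 0, label: CARD11-deficiency}
- {node: MALT1, state: 0, label: MALT1-deficiency}
- {node: BCL10, state: 0, label: BCL10-deficiency}
- {node: NFKBIA, state: 0, label: NFKBIA-deficiency}
- {node: PTPRC, state: 0, label: PTPRC-deficiency}
- {node: MAP3K14, state: 0, label: MAP3K14-deficiency}
- {node: PI3K, state: 1, label: PI3K-overactivity}
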