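# Cotranscriptional folding pathway of a fluoride-riboswitch-like RNA.
#
# Thresholds are emerged-RNA lengths (nt of RNA outside the polymerase,
# f_rna = 14).  Positions use 1-based transcript coordinates.  Classes map
# to per-nt, per-pulse SHAPE modification rates.  The target sequence
# bundled with this fixture is synthetic; coordinates follow the crcB
# riboswitch convention (P1 loop 11-16, PK1 partner 42-47, upper
# terminator stem 52-55, termination window 80-82).
name: fluoride_riboswitch_synthetic
length: 120
f_rna: 14
baseline: high
rates:
  high: 0.04
  medium: 0.02
  low: 0.004
elements:
  - name: aptamer_A10_A22_premodulation
    threshold: 23
    condition: both
    effects:
      - positions: [10, 22]
        class: medium
  - name: P1_stem
    threshold: 25
    condition: both
    effects:
      - positions: [[2, 9], [17, 24]]
        class: low
      - positions: [10, 22]
        class: medium
  - name: PK1
    threshold: 43
    condition: both
    effects:
      - positions: [[11, 16], [42, 47]]
        class: low
      - positions: [10, 22]
        class: low
  - name: terminator_hairpin
    threshold: 62
    condition: "-F"
    caps_backtracking: true
    fold_back_edge: 62
    effects:
      - positions: [[52, 55]]
        class: low
      - positions: [[11, 16]]
        class: high
  - name: partial_terminator
    threshold: 74
    condition: "+F"
    effects:
      - positions: [[52, 55]]
        class: medium
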