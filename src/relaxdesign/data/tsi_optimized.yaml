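# Min-max CRB-optimized TSI design (TR 6 s, 3 imaging + 2 inversion pulses)
tr_ms: 6000.0
pulses:
  - {time_ms: 0.0, flip_deg: 24.0, kind: imaging}
  - {time_ms: 1804.0, flip_deg: 180.0, kind: inversion}
  - {time_ms: 2751.0, flip_deg: 68.0, kind: imaging}
  - {time_ms: 3555.0, flip_deg: 180.0, kind: inversion}
  - {time_ms: 3655.0, flip_deg: 87.0, kind: imaging}
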