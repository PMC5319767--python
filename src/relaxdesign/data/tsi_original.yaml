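# Original contrast-optimized TSI design (TR 6 s)
tr_ms: 6000.0
pulses:
  - {time_ms: 0.0, flip_deg: 46.0, kind: imaging}
  - {time_ms: 3020.0, flip_deg: 180.0, kind: inversion}
  - {time_ms: 3573.0, flip_deg: 23.0, kind: imaging}
  - {time_ms: 5112.0, flip_deg: 180.0, kind: inversion}
  - {time_ms: 5575.0, flip_deg: 83.0, kind: imaging}
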