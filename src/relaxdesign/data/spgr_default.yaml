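# Default SPGR/DESPOT1 protocol for cross-sequence comparison
tr_ms: 7.8
te_ms: 2.4
flips_deg: [2.0, 14.0]
bandwidth_khz: 31.3
sense_rate: 1.0
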