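{
  "name": "tiprack_300ul",
  "kind": "tip_rack",
  "rows": 8,
  "cols": 12,
  "wellPitch": 9.0,
  "a1Offset": [14.24, 10.84],
  "wellDepth": 59.3,
  "wellVolume": 300.0,
  "footprint": [127.76, 85.48],
  "height": 64.5
}
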