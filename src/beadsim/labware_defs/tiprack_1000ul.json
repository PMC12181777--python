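{
  "name": "tiprack_1000ul",
  "kind": "tip_rack",
  "rows": 8,
  "cols": 12,
  "wellPitch": 9.0,
  "a1Offset": [14.24, 10.84],
  "wellDepth": 88.0,
  "wellVolume": 1000.0,
  "footprint": [127.76, 85.48],
  "height": 97.0
}
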