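{
  "name": "vialrack_54_2ml",
  "kind": "vial_rack",
  "rows": 6,
  "cols": 9,
  "wellPitch": 13.0,
  "a1Offset": [12.0, 10.0],
  "wellDepth": 32.0,
  "wellVolume": 2000.0,
  "footprint": [128.0, 85.0],
  "height": 45.0
}
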