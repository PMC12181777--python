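{
  "name": "plate_96_wellplate_360ul",
  "kind": "microplate",
  "rows": 8,
  "cols": 12,
  "wellPitch": 9.0,
  "a1Offset": [14.38, 11.24],
  "wellDepth": 10.67,
  "wellVolume": 360.0,
  "footprint": [127.76, 85.48],
  "height": 14.22
}
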