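{
  "name": "camera_tool_holder",
  "kind": "tool_holder",
  "rows": 2,
  "cols": 3,
  "wellPitch": 40.0,
  "a1Offset": [24.0, 22.5],
  "wellDepth": 60.0,
  "wellVolume": 0.0,
  "footprint": [128.0, 85.0],
  "height": 75.0
}
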