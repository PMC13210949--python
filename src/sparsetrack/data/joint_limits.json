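{
  "elbow": {"order": "ZXY", "bounds_deg": [[5, 150], [0, 0], [0, 0]]},
  "knee": {"order": "ZXY", "bounds_deg": [[0, 140], [0, 0], [0, 0]]},
  "left_upper_arm": {"order": "YXZ", "bounds_deg": [[-45, 150], [-45, 150], [-45, 150]]},
  "right_upper_arm": {"order": "YXZ", "bounds_deg": [[-45, 150], [-45, 150], [-45, 150]]},
  "left_upper_leg": {"order": "YXZ", "bounds_deg": [[-45, 150], [-45, 150], [-45, 150]]},
  "right_upper_leg": {"order": "YXZ", "bounds_deg": [[-45, 150], [-45, 150], [-45, 150]]}
}
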