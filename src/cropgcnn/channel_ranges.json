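{
  "RGB":   [[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
  "HSV":   [[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
  "HLS":   [[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
  "XYZ":   [[0.0, 0.950456], [0.0, 1.0], [0.0, 1.088754]],
  "LAB":   [[0.0, 100.0], [-86.2, 98.3], [-107.9, 94.5]],
  "LUV":   [[0.0, 100.0], [-83.1, 175.1], [-134.2, 107.4]],
  "YCrCb": [[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
  "YUV":   [[0.0, 1.0], [-0.43601035, 0.43601035], [-0.61497538, 0.61497538]]
}
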