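{
  "R1_k3": {
    "normal_max": 58,
    "cirrhotic_min": 71
  },
  "R1_k4": {
    "normal_max": 28,
    "cirrhotic_min": 42
  },
  "R1_k5": {
    "normal_max": 13,
    "cirrhotic_min": 27
  },
  "R2_k3": {
    "normal_max": 119,
    "cirrhotic_min": 148
  },
  "R2_k4": {
    "normal_max": 68,
    "cirrhotic_min": 106
  },
  "R2_k5": {
    "normal_max": 47,
    "cirrhotic_min": 62
  },
  "R3_k3": {
    "normal_max": 139,
    "cirrhotic_min": 159
  },
  "R3_k4": {
    "normal_max": 92,
    "cirrhotic_min": 111
  },
  "R3_k5": {
    "normal_max": 65,
    "cirrhotic_min": 79
  }
}
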