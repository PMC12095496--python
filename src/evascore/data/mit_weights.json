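{
  "name": "hsu2013-experimental",
  "description": "Per-position mismatch weights for the MIT (Hsu) specificity score, position 1 = PAM-distal, position 20 = PAM-proximal.",
  "weights": [0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
              0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583]
}
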