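{
  "name": "STO-3G",
  "comment": "Minimal STO-3G contractions (Hehre, Stewart & Pople) for light elements; shipped for fast smoke calculations.",
  "elements": {
    "H": [
      {"l": 0, "exponents": [3.42525091, 0.62391373, 0.16885540],
       "coefficients": [0.15432897, 0.53532814, 0.44463454]}
    ],
    "He": [
      {"l": 0, "exponents": [6.36242139, 1.15892300, 0.31364979],
       "coefficients": [0.15432897, 0.53532814, 0.44463454]}
    ],
    "O": [
      {"l": 0, "exponents": [130.70932000, 23.80886100, 6.44360830],
       "coefficients": [0.15432897, 0.53532814, 0.44463454]},
      {"l": 0, "exponents": [5.03315130, 1.16959610, 0.38038900],
       "coefficients": [-0.09996723, 0.39951283, 0.70011547]},
      {"l": 1, "exponents": [5.03315130, 1.16959610, 0.38038900],
       "coefficients": [0.15591627, 0.60768372, 0.39195739]}
    ],
    "C": [
      {"l": 0, "exponents": [71.61683700, 13.04509600, 3.53051220],
       "coefficients": [0.15432897, 0.53532814, 0.44463454]},
      {"l": 0, "exponents": [2.94124940, 0.68348310, 0.22228990],
       "coefficients": [-0.09996723, 0.39951283, 0.70011547]},
      {"l": 1, "exponents": [2.94124940, 0.68348310, 0.22228990],
       "coefficients": [0.15591627, 0.60768372, 0.39195739]}
    ],
    "N": [
      {"l": 0, "exponents": [99.10616900, 18.05231200, 4.88566020],
       "coefficients": [0.15432897, 0.53532814, 0.44463454]},
      {"l": 0, "exponents": [3.78045590, 0.87849660, 0.28571440],
       "coefficients": [-0.09996723, 0.39951283, 0.70011547]},
      {"l": 1, "exponents": [3.78045590, 0.87849660, 0.28571440],
       "coefficients": [0.15591627, 0.60768372, 0.39195739]}
    ]
  }
}
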