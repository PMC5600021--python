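{
  "name": "3-21G",
  "comment": "Split-valence 3-21G contractions (Binkley, Pople & Hehre) for the light elements shipped with the package; the CE-HF model uses this basis for every element.",
  "elements": {
    "H": [
      {"l": 0, "exponents": [5.4471780, 0.8245470], "coefficients": [0.1562850, 0.9046910]},
      {"l": 0, "exponents": [0.1831920], "coefficients": [1.0]}
    ],
    "He": [
      {"l": 0, "exponents": [13.6267000, 1.9993500], "coefficients": [0.1752300, 0.8934830]},
      {"l": 0, "exponents": [0.3829930], "coefficients": [1.0]}
    ],
    "Li": [
      {"l": 0, "exponents": [36.8382000, 5.4817200, 1.1132700],
       "coefficients": [0.0696686, 0.3813460, 0.6817020]},
      {"l": 0, "exponents": [0.5402050, 0.1022550], "coefficients": [-0.2631270, 1.1433900]},
      {"l": 1, "exponents": [0.5402050, 0.1022550], "coefficients": [0.1615460, 0.9156630]},
      {"l": 0, "exponents": [0.0285650], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.0285650], "coefficients": [1.0]}
    ],
    "C": [
      {"l": 0, "exponents": [172.2560000, 25.9109000, 5.5333500],
       "coefficients": [0.0617669, 0.3587940, 0.7007130]},
      {"l": 0, "exponents": [3.6649800, 0.7705450], "coefficients": [-0.3958970, 1.2158400]},
      {"l": 1, "exponents": [3.6649800, 0.7705450], "coefficients": [0.2364600, 0.8606190]},
      {"l": 0, "exponents": [0.1958570], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.1958570], "coefficients": [1.0]}
    ],
    "N": [
      {"l": 0, "exponents": [242.7660000, 36.4851000, 7.8144900],
       "coefficients": [0.0598657, 0.3529550, 0.7065130]},
      {"l": 0, "exponents": [5.4252200, 1.1491500], "coefficients": [-0.4133010, 1.2244200]},
      {"l": 1, "exponents": [5.4252200, 1.1491500], "coefficients": [0.2379720, 0.8589530]},
      {"l": 0, "exponents": [0.2832050], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.2832050], "coefficients": [1.0]}
    ],
    "O": [
      {"l": 0, "exponents": [322.0370000, 48.4308000, 10.4206000],
       "coefficients": [0.0592394, 0.3515000, 0.7076580]},
      {"l": 0, "exponents": [7.4029400, 1.5762000], "coefficients": [-0.4044530, 1.2215600]},
      {"l": 1, "exponents": [7.4029400, 1.5762000], "coefficients": [0.2445860, 0.8539550]},
      {"l": 0, "exponents": [0.3736840], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.3736840], "coefficients": [1.0]}
    ],
    "F": [
      {"l": 0, "exponents": [413.8010000, 62.2446000, 13.4340000],
       "coefficients": [0.0585483, 0.3493080, 0.7096320]},
      {"l": 0, "exponents": [9.7775900, 2.0861700], "coefficients": [-0.4073270, 1.2231400]},
      {"l": 1, "exponents": [9.7775900, 2.0861700], "coefficients": [0.2466800, 0.8523210]},
      {"l": 0, "exponents": [0.4823830], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.4823830], "coefficients": [1.0]}
    ]
  }
}
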