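{
  "name": "6-31G(d,p)",
  "comment": "Split-valence 6-31G with one set of Cartesian d polarization functions on heavy atoms and p functions on H (Hariharan & Pople) for the light elements shipped with the package; the CE-B3LYP model uses this basis for elements H-Kr.",
  "elements": {
    "H": [
      {"l": 0, "exponents": [18.7311370, 2.8253937, 0.6401217],
       "coefficients": [0.03349460, 0.23472695, 0.81375733]},
      {"l": 0, "exponents": [0.1612778], "coefficients": [1.0]},
      {"l": 1, "exponents": [1.1000000], "coefficients": [1.0]}
    ],
    "C": [
      {"l": 0, "exponents": [3047.5249000, 457.3695100, 103.9486900, 29.2101550, 9.2866630, 3.1639270],
       "coefficients": [0.0018347, 0.0140373, 0.0688426, 0.2321844, 0.4679413, 0.3623120]},
      {"l": 0, "exponents": [7.8682724, 1.8812885, 0.5442493],
       "coefficients": [-0.1193324, -0.1608542, 1.1434564]},
      {"l": 1, "exponents": [7.8682724, 1.8812885, 0.5442493],
       "coefficients": [0.0689991, 0.3164240, 0.7443083]},
      {"l": 0, "exponents": [0.1687144], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.1687144], "coefficients": [1.0]},
      {"l": 2, "exponents": [0.8000000], "coefficients": [1.0]}
    ],
    "N": [
      {"l": 0, "exponents": [4173.5110000, 627.4579000, 142.9021000, 40.2343300, 12.8202100, 4.3904370],
       "coefficients": [0.0018348, 0.0139950, 0.0685870, 0.2322410, 0.4690700, 0.3604550]},
      {"l": 0, "exponents": [11.6263580, 2.7162800, 0.7722180],
       "coefficients": [-0.1149610, -0.1691180, 1.1458520]},
      {"l": 1, "exponents": [11.6263580, 2.7162800, 0.7722180],
       "coefficients": [0.0675800, 0.3239070, 0.7408950]},
      {"l": 0, "exponents": [0.2120313], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.2120313], "coefficients": [1.0]},
      {"l": 2, "exponents": [0.8000000], "coefficients": [1.0]}
    ],
    "O": [
      {"l": 0, "exponents": [5484.6717000, 825.2349500, 188.0469600, 52.9645000, 16.8975700, 5.7996353],
       "coefficients": [0.0018311, 0.0139501, 0.0684451, 0.2327143, 0.4701930, 0.3585209]},
      {"l": 0, "exponents": [15.5396160, 3.5999336, 1.0137618],
       "coefficients": [-0.1107775, -0.1480263, 1.1307670]},
      {"l": 1, "exponents": [15.5396160, 3.5999336, 1.0137618],
       "coefficients": [0.0708743, 0.3397528, 0.7271586]},
      {"l": 0, "exponents": [0.2700058], "coefficients": [1.0]},
      {"l": 1, "exponents": [0.2700058], "coefficients": [1.0]},
      {"l": 2, "exponents": [0.8000000], "coefficients": [1.0]}
    ]
  }
}
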