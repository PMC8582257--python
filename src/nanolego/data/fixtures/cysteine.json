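{
 "atoms": [
  [
   "S1",
   "S"
  ],
  [
   "C2",
   "C"
  ],
  [
   "C3",
   "C"
  ],
  [
   "C4",
   "C"
  ],
  [
   "O5",
   "O"
  ],
  [
   "H6",
   "H"
  ],
  [
   "O7",
   "O"
  ],
  [
   "N8",
   "N"
  ],
  [
   "H9",
   "H"
  ],
  [
   "H10",
   "H"
  ],
  [
   "H11",
   "H"
  ],
  [
   "H12",
   "H"
  ],
  [
   "H13",
   "H"
  ],
  [
   "H14",
   "H"
  ]
 ],
 "columns": {
  "PW6B95": {
   "values": {
    "C2C3": 1.5254,
    "C2C3C4": 110.21,
    "C2C3C4O5": 148.82,
    "C2C4C3N8": -128.69,
    "C2H13": 1.0938,
    "C2H14": 1.0914,
    "C2S1H9": 95.65,
    "C3C2S1H9": 71.2,
    "C3C4": 1.5325,
    "C3C4O5": 113.86,
    "C3C4O5H6": -5.77,
    "C3C4O7": 122.96,
    "C3H12": 1.0984,
    "C3N8": 1.4567,
    "C3N8H10": 109.35,
    "C3N8H11": 111.87,
    "C3S1C2H13": 120.33,
    "C4C3H12": 104.77,
    "C4C3N8": 109.16,
    "C4C3N8H10": 88.82,
    "C4O5": 1.3307,
    "C4O5H6": 104.96,
    "C4O7": 1.2047,
    "H10C3N8H11": 119.5,
    "H13S1C2H14": 116.88,
    "N8C4C3H12": -115.27,
    "N8H10": 1.0173,
    "N8H11": 1.0114,
    "O5C4C3O7": -178.7,
    "O5H6": 0.9801,
    "S1C2": 1.8162,
    "S1C2C3": 112.94,
    "S1C2C3C4": -68.27,
    "S1C2H13": 105.87,
    "S1C2H14": 109.52,
    "S1H9": 1.3461
   }
  },
  "PW6B95-LRA": {
   "torsions_from": "PW6B95",
   "values": {
    "C2C3": 1.5257,
    "C2C3C4": 110.08,
    "C2H13": 1.0874,
    "C2H14": 1.085,
    "C2S1H9": 95.65,
    "C3C4": 1.5327,
    "C3C4O5": 113.8,
    "C3C4O7": 122.9,
    "C3H12": 1.0919,
    "C3N8": 1.4608,
    "C3N8H10": 109.36,
    "C3N8H11": 111.88,
    "C4C3H12": 104.75,
    "C4C3N8": 109.16,
    "C4O5": 1.3322,
    "C4O5H6": 105.11,
    "C4O7": 1.2041,
    "N8H10": 1.0139,
    "N8H11": 1.0081,
    "O5H6": 0.9818,
    "S1C2": 1.8145,
    "S1C2C3": 112.94,
    "S1C2H13": 105.76,
    "S1C2H14": 109.4,
    "S1H9": 1.3461
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "C2C3": 1.5289,
    "C2C3C4": 110.24,
    "C2C3C4O5": 146.94,
    "C2C4C3N8": -128.37,
    "C2H13": 1.0916,
    "C2H14": 1.0883,
    "C2S1H9": 95.96,
    "C3C2S1H9": 71.73,
    "C3C4": 1.5375,
    "C3C4O5": 114.01,
    "C3C4O5H6": -4.84,
    "C3C4O7": 122.9,
    "C3H12": 1.0959,
    "C3N8": 1.4625,
    "C3N8H10": 109.44,
    "C3N8H11": 111.45,
    "C3S1C2H13": 119.95,
    "C4C3H12": 104.97,
    "C4C3N8": 109.44,
    "C4C3N8H10": 88.47,
    "C4O5": 1.3361,
    "C4O5H6": 104.91,
    "C4O7": 1.2063,
    "H10C3N8H11": 119.38,
    "H13S1C2H14": 116.8,
    "N8C4C3H12": -115.45,
    "N8H10": 1.0171,
    "N8H11": 1.0118,
    "O5C4C3O7": -178.48,
    "O5H6": 0.9808,
    "S1C2": 1.8201,
    "S1C2C3": 113.0,
    "S1C2C3C4": -67.8,
    "S1C2H13": 105.54,
    "S1C2H14": 109.37,
    "S1H9": 1.3404
   }
  },
  "rev-DSDPBEP86-LRA": {
   "torsions_from": "rev-DSDPBEP86",
   "values": {
    "C2C3": 1.5261,
    "C2C3C4": 110.22,
    "C2H13": 1.0889,
    "C2H14": 1.0857,
    "C2S1H9": 95.96,
    "C3C4": 1.5347,
    "C3C4O5": 113.93,
    "C3C4O7": 122.82,
    "C3H12": 1.0933,
    "C3N8": 1.4591,
    "C3N8H10": 109.23,
    "C3N8H11": 111.23,
    "C4C3H12": 104.97,
    "C4C3N8": 109.44,
    "C4O5": 1.3322,
    "C4O5H6": 104.91,
    "C4O7": 1.2027,
    "N8H10": 1.0149,
    "N8H11": 1.0096,
    "O5H6": 0.9819,
    "S1C2": 1.8146,
    "S1C2C3": 113.0,
    "S1C2H13": 105.44,
    "S1C2H14": 109.27,
    "S1H9": 1.3404
   }
  }
 },
 "description": "cysteine conformer IIb",
 "dvib": {
  "A": -29.267,
  "B": -11.122,
  "C": -9.114
 },
 "experimental": {
  "A": 3071.437,
  "B": 1606.5366,
  "C": 1331.8019
 },
 "id": "cysteine",
 "placements": [
  {
   "atom": "C2",
   "bond_param": "S1C2",
   "bond_ref": "S1"
  },
  {
   "angle_param": "S1C2C3",
   "angle_ref": "S1",
   "atom": "C3",
   "bond_param": "C2C3",
   "bond_ref": "C2"
  },
  {
   "angle_param": "C2C3C4",
   "angle_ref": "C2",
   "atom": "C4",
   "bond_param": "C3C4",
   "bond_ref": "C3",
   "torsion_atoms": [
    "S1",
    "C2",
    "C3",
    "C4"
   ],
   "torsion_param": "S1C2C3C4"
  },
  {
   "angle_param": "C3C4O5",
   "angle_ref": "C3",
   "atom": "O5",
   "bond_param": "C4O5",
   "bond_ref": "C4",
   "torsion_atoms": [
    "C2",
    "C3",
    "C4",
    "O5"
   ],
   "torsion_param": "C2C3C4O5"
  },
  {
   "angle_param": "C4O5H6",
   "angle_ref": "C4",
   "atom": "H6",
   "bond_param": "O5H6",
   "bond_ref": "O5",
   "torsion_atoms": [
    "C3",
    "C4",
    "O5",
    "H6"
   ],
   "torsion_param": "C3C4O5H6"
  },
  {
   "angle_param": "C3C4O7",
   "angle_ref": "C3",
   "atom": "O7",
   "bond_param": "C4O7",
   "bond_ref": "C4",
   "torsion_atoms": [
    "O5",
    "C4",
    "C3",
    "O7"
   ],
   "torsion_param": "O5C4C3O7"
  },
  {
   "angle_param": "C4C3N8",
   "angle_ref": "C4",
   "atom": "N8",
   "bond_param": "C3N8",
   "bond_ref": "C3",
   "torsion_atoms": [
    "C2",
    "C4",
    "C3",
    "N8"
   ],
   "torsion_param": "C2C4C3N8"
  },
  {
   "angle_param": "C2S1H9",
   "angle_ref": "C2",
   "atom": "H9",
   "bond_param": "S1H9",
   "bond_ref": "S1",
   "torsion_atoms": [
    "C3",
    "C2",
    "S1",
    "H9"
   ],
   "torsion_param": "C3C2S1H9"
  },
  {
   "angle_param": "C3N8H10",
   "angle_ref": "C3",
   "atom": "H10",
   "bond_param": "N8H10",
   "bond_ref": "N8",
   "torsion_atoms": [
    "C4",
    "C3",
    "N8",
    "H10"
   ],
   "torsion_param": "C4C3N8H10"
  },
  {
   "angle_param": "C3N8H11",
   "angle_ref": "C3",
   "atom": "H11",
   "bond_param": "N8H11",
   "bond_ref": "N8",
   "torsion_atoms": [
    "H10",
    "C3",
    "N8",
    "H11"
   ],
   "torsion_param": "H10C3N8H11"
  },
  {
   "angle_param": "C4C3H12",
   "angle_ref": "C4",
   "atom": "H12",
   "bond_param": "C3H12",
   "bond_ref": "C3",
   "torsion_atoms": [
    "N8",
    "C4",
    "C3",
    "H12"
   ],
   "torsion_param": "N8C4C3H12"
  },
  {
   "angle_param": "S1C2H13",
   "angle_ref": "S1",
   "atom": "H13",
   "bond_param": "C2H13",
   "bond_ref": "C2",
   "torsion_atoms": [
    "C3",
    "S1",
    "C2",
    "H13"
   ],
   "torsion_param": "C3S1C2H13"
  },
  {
   "angle_param": "S1C2H14",
   "angle_ref": "S1",
   "atom": "H14",
   "bond_param": "C2H14",
   "bond_ref": "C2",
   "torsion_atoms": [
    "H13",
    "S1",
    "C2",
    "H14"
   ],
   "torsion_param": "H13S1C2H14"
  }
 ],
 "printed_constants": {
  "PW6B95": [
   3081.357,
   1606.108,
   1325.263
  ],
  "PW6B95-LRA": [
   3080.929,
   1615.949,
   1328.95
  ],
  "rev-DSDPBEP86": [
   3044.272,
   1599.21,
   1322.812
  ],
  "rev-DSDPBEP86-LRA": [
   3062.788,
   1616.886,
   1333.082
  ]
 },
 "printed_mad": {
  "PW6B95": 0.28,
  "PW6B95-LRA": 0.37,
  "rev-DSDPBEP86": 0.66,
  "rev-DSDPBEP86-LRA": 0.34
 },
 "uncorrected": {
  "PW6B95-LRA": [
   "S1H9",
   "C2S1H9"
  ],
  "rev-DSDPBEP86-LRA": [
   "S1H9",
   "C2S1H9"
  ]
 }
}
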