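{
 "atoms": [
  [
   "C3",
   "C"
  ],
  [
   "C4",
   "C"
  ],
  [
   "C1",
   "C"
  ],
  [
   "N2",
   "N"
  ],
  [
   "H7",
   "H"
  ],
  [
   "C5",
   "C"
  ],
  [
   "C6",
   "C"
  ],
  [
   "H8",
   "H"
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
  ]
 ],
 "checks": {
  "consistency": [
   "C5C6",
   "C4C5C6"
  ],
  "note": "C5C6 and C4C5C6 are printed but redundant under the assumed ring symmetry; the build realizes them only to within the printed rounding (~0.0015 A / 0.12 deg)"
 },
 "columns": {
  "PW6B95": {
   "values": {
    "C1C3": 1.4265,
    "C1C3C4": 121.81,
    "C1N2": 1.1592,
    "C3C4": 1.3276,
    "C3C4C5": 148.16,
    "C3C4C5H8": 71.97,
    "C3H7": 1.0872,
    "C4C3H7": 121.32,
    "C4C5": 1.458,
    "C4C5C6": 58.23,
    "C4C5C6H10": 107.52,
    "C4C5H8": 118.38,
    "C5C6": 1.532,
    "C5C6H10": 118.1,
    "C5H8": 1.0875,
    "C5H9": 1.0874
   }
  },
  "PW6B95-LRA": {
   "torsions_from": "PW6B95",
   "values": {
    "C1C3": 1.7272,
    "C1C3C4": 121.69,
    "C1N2": 1.1582,
    "C3C4": 1.3267,
    "C3C4C5": 148.01,
    "C3H7": 1.0809,
    "C4C3H7": 121.29,
    "C4C5": 1.4591,
    "C4C5C6": 58.17,
    "C4C5H8": 118.35,
    "C5C6": 1.5343,
    "C5C6H10": 118.07,
    "C5H8": 1.0811,
    "C5H9": 1.0811
   }
  },
  "PW6B95-TMA": {
   "torsions_from": "PW6B95",
   "values": {
    "C1C3": 1.43,
    "C1C3C4": 121.12,
    "C1N2": 1.1598,
    "C3C4": 1.3278,
    "C3C4C5": 148.01,
    "C3H7": 1.0801,
    "C4C3H7": 121.75,
    "C4C5": 1.4589,
    "C4C5C6": 58.17,
    "C4C5H8": 118.15,
    "C5C6": 1.5329,
    "C5C6H10": 117.87,
    "C5H8": 1.0807,
    "C5H9": 1.0806
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "C1C3": 1.4324,
    "C1C3C4": 121.41,
    "C1N2": 1.1633,
    "C3C4": 1.3273,
    "C3C4C5": 148.31,
    "C3C4C5H8": 73.31,
    "C3H7": 1.0833,
    "C4C3H7": 121.49,
    "C4C5": 1.4626,
    "C4C5C6": 58.19,
    "C4C5C6H10": 107.48,
    "C4C5H8": 118.22,
    "C5C6": 1.5388,
    "C5C6H10": 117.76,
    "C5H8": 1.0837,
    "C5H9": 1.0836
   }
  },
  "rev-DSDPBEP86-LRA": {
   "torsions_from": "rev-DSDPBEP86",
   "values": {
    "C1C3": 1.4296,
    "C1C3C4": 121.38,
    "C1N2": 1.1605,
    "C3C4": 1.3252,
    "C3C4C5": 148.28,
    "C3H7": 1.0809,
    "C4C3H7": 121.49,
    "C4C5": 1.4596,
    "C4C5C6": 58.18,
    "C4C5H8": 118.22,
    "C5C6": 1.5354,
    "C5C6H10": 117.76,
    "C5H8": 1.0811,
    "C5H9": 1.0811
   }
  },
  "rev-DSDPBEP86-TMA": {
   "torsions_from": "rev-DSDPBEP86",
   "values": {
    "C1C3": 1.4297,
    "C1C3C4": 121.14,
    "C1N2": 1.1591,
    "C3C4": 1.3255,
    "C3C4C5": 148.24,
    "C3H7": 1.0806,
    "C4C3H7": 121.77,
    "C4C5": 1.4589,
    "C4C5C6": 58.18,
    "C4C5H8": 118.17,
    "C5C6": 1.5351,
    "C5C6H10": 117.71,
    "C5H8": 1.081,
    "C5H9": 1.0809
   }
  }
 },
 "description": "(cyanomethylene)cyclopropane, Cs with planar heavy-atom skeleton; only the ring CH2 hydrogens lie out of plane",
 "dvib": {
  "A": -80.314,
  "B": -3.747,
  "C": -5.216
 },
 "experimental": {
  "A": 12644.003,
  "B": 2038.862,
  "C": 1797.043
 },
 "id": "cyanomethylenecyclopropane",
 "misprints": [
  {
   "note": "H7 is bonded to C3; printed row label is chemically inconsistent and read as the C4-C3-H7 angle",
   "param": "C4C3H7",
   "printed_label": "C3C4H7"
  },
  {
   "column": "PW6B95-LRA",
   "note": "physically implausible CC single-bond value; encoded as printed and flagged",
   "param": "C1C3",
   "plausible": 1.4272,
   "printed": 1.7272
  }
 ],
 "placements": [
  {
   "atom": "C4",
   "bond_param": "C3C4",
   "bond_ref": "C3"
  },
  {
   "angle_param": "C1C3C4",
   "angle_ref": "C4",
   "atom": "C1",
   "bond_param": "C1C3",
   "bond_ref": "C3"
  },
  {
   "angle_name": "N2C1C3",
   "angle_ref": "C3",
   "angle_value": 180.0,
   "atom": "N2",
   "bond_param": "C1N2",
   "bond_ref": "C1",
   "note": "linear nitrile completion"
  },
  {
   "angle_param": "C4C3H7",
   "angle_ref": "C4",
   "atom": "H7",
   "bond_param": "C3H7",
   "bond_ref": "C3",
   "note": "sp2 in-plane completion",
   "torsion_atoms": [
    "H7",
    "C3",
    "C4",
    "C1"
   ],
   "torsion_name": "H7C3C4C1",
   "torsion_value": 180.0
  },
  {
   "angle_param": "C3C4C5",
   "angle_ref": "C3",
   "atom": "C5",
   "bond_param": "C4C5",
   "bond_ref": "C4",
   "note": "ring carbon in heavy-atom plane, anti to the nitrile arm",
   "torsion_atoms": [
    "C5",
    "C4",
    "C3",
    "C1"
   ],
   "torsion_name": "C5C4C3C1",
   "torsion_value": 180.0
  },
  {
   "angle_name": "C3C4C6",
   "angle_param": "C3C4C5",
   "angle_ref": "C3",
   "atom": "C6",
   "bond_name": "C4C6",
   "bond_param": "C4C5",
   "bond_ref": "C4",
   "note": "ring carbon in heavy-atom plane, syn side; bond/angle assumed equal to the printed symmetry-unique C4C5/C3C4C5",
   "torsion_atoms": [
    "C6",
    "C4",
    "C3",
    "C1"
   ],
   "torsion_name": "C6C4C3C1",
   "torsion_value": 0.0
  },
  {
   "angle_param": "C4C5H8",
   "angle_ref": "C4",
   "atom": "H8",
   "bond_param": "C5H8",
   "bond_ref": "C5",
   "torsion_atoms": [
    "C3",
    "C4",
    "C5",
    "H8"
   ],
   "torsion_param": "C3C4C5H8"
  },
  {
   "atom": "H9",
   "mirror_plane": [
    "C3",
    "C4",
    "C1"
   ],
   "mirror_source": "H8"
  },
  {
   "angle_param": "C5C6H10",
   "angle_ref": "C5",
   "atom": "H10",
   "bond_name": "C6H10",
   "bond_param": "C5H9",
   "bond_ref": "C6",
   "torsion_atoms": [
    "C4",
    "C5",
    "C6",
    "H10"
   ],
   "torsion_param": "C4C5C6H10"
  },
  {
   "atom": "H11",
   "mirror_plane": [
    "C3",
    "C4",
    "C1"
   ],
   "mirror_source": "H10"
  }
 ],
 "printed_constants": {
  "PW6B95": [
   12778.564,
   2024.199,
   1788.412
  ],
  "PW6B95-LRA": [
   12699.661,
   2033.747,
   1793.615
  ],
  "PW6B95-TMA": [
   12628.917,
   2039.953,
   1797.156
  ],
  "rev-DSDPBEP86": [
   12657.507,
   2024.628,
   1786.367
  ],
  "rev-DSDPBEP86-LRA": [
   12647.603,
   2038.517,
   1796.792
  ],
  "rev-DSDPBEP86-TMA": [
   12620.703,
   2043.863,
   1800.438
  ]
 },
 "printed_mad": {
  "PW6B95": 0.75,
  "PW6B95-LRA": 0.29,
  "PW6B95-TMA": 0.06,
  "rev-DSDPBEP86": 0.47,
  "rev-DSDPBEP86-LRA": 0.02,
  "rev-DSDPBEP86-TMA": 0.21
 }
}
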