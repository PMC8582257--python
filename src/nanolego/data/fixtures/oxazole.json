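{
 "atoms": [
  [
   "O1",
   "O"
  ],
  [
   "C2",
   "C"
  ],
  [
   "N3",
   "N"
  ],
  [
   "C4",
   "C"
  ],
  [
   "C5",
   "C"
  ],
  [
   "H2",
   "H"
  ],
  [
   "H4",
   "H"
  ],
  [
   "H5",
   "H"
  ]
 ],
 "columns": {
  "PW6B95": {
   "values": {
    "C2H2": 1.08,
    "C2N3": 1.2897,
    "C4C5": 1.3528,
    "C4H4": 1.0804,
    "C4N3": 1.3848,
    "C5H5": 1.0785,
    "CCN": 109.06,
    "CNC": 104.13,
    "HCC": 135.21,
    "HCN": 122.06,
    "HCO": 116.88,
    "NCO": 114.65,
    "O1C2": 1.3487
   }
  },
  "SE": {
   "sigmas": {
    "C2H2": 0.00026,
    "C2N3": 0.00027,
    "C4C5": 0.0002,
    "C4H4": 0.00026,
    "C4N3": 0.0003,
    "C5H5": 0.00058,
    "CCN": 0.02,
    "CNC": 0.017,
    "HCC": 0.061,
    "HCN": 0.061,
    "HCO": 0.02,
    "NCO": 0.019,
    "O1C2": 0.0003
   },
   "values": {
    "C2H2": 1.07481,
    "C2N3": 1.28819,
    "C4C5": 1.34934,
    "C4H4": 1.07433,
    "C4N3": 1.39268,
    "C5H5": 1.073,
    "CCN": 109.003,
    "CNC": 103.884,
    "HCC": 135.145,
    "HCN": 121.867,
    "HCO": 116.832,
    "NCO": 115.076,
    "O1C2": 1.35097
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "C2H2": 1.0774,
    "C2N3": 1.2926,
    "C4C5": 1.3531,
    "C4H4": 1.0767,
    "C4N3": 1.3945,
    "C5H5": 1.0752,
    "CCN": 109.04,
    "CNC": 103.94,
    "HCC": 135.16,
    "HCN": 121.93,
    "HCO": 116.74,
    "NCO": 114.93,
    "O1C2": 1.3548
   }
  }
 },
 "description": "1,3-oxazole, planar",
 "id": "oxazole",
 "placements": [
  {
   "atom": "C2",
   "bond_param": "O1C2",
   "bond_ref": "O1"
  },
  {
   "angle_param": "NCO",
   "angle_ref": "O1",
   "atom": "N3",
   "bond_param": "C2N3",
   "bond_ref": "C2"
  },
  {
   "angle_param": "CNC",
   "angle_ref": "C2",
   "atom": "C4",
   "bond_param": "C4N3",
   "bond_ref": "N3",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C4",
    "N3",
    "C2",
    "O1"
   ],
   "torsion_name": "C4N3C2O1",
   "torsion_value": 0.0
  },
  {
   "angle_param": "CCN",
   "angle_ref": "N3",
   "atom": "C5",
   "bond_param": "C4C5",
   "bond_ref": "C4",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C5",
    "C4",
    "N3",
    "C2"
   ],
   "torsion_name": "C5C4N3C2",
   "torsion_value": 0.0
  },
  {
   "angle_param": "HCO",
   "angle_ref": "O1",
   "atom": "H2",
   "bond_param": "C2H2",
   "bond_ref": "C2",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H2",
    "C2",
    "O1",
    "C5"
   ],
   "torsion_name": "H2C2O1C5",
   "torsion_value": 180.0
  },
  {
   "angle_param": "HCN",
   "angle_ref": "N3",
   "atom": "H4",
   "bond_param": "C4H4",
   "bond_ref": "C4",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H4",
    "C4",
    "N3",
    "C2"
   ],
   "torsion_name": "H4C4N3C2",
   "torsion_value": 180.0
  },
  {
   "angle_param": "HCC",
   "angle_ref": "C4",
   "atom": "H5",
   "bond_param": "C5H5",
   "bond_ref": "C5",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H5",
    "C5",
    "C4",
    "N3"
   ],
   "torsion_name": "H5C5C4N3",
   "torsion_value": 180.0
  }
 ],
 "printed_mad": {}
}
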