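{
 "atoms": [
  [
   "C1",
   "C"
  ],
  [
   "N2",
   "N"
  ],
  [
   "O3",
   "O"
  ],
  [
   "H4",
   "H"
  ],
  [
   "H5",
   "H"
  ],
  [
   "H6",
   "H"
  ]
 ],
 "columns": {
  "PW6B95": {
   "values": {
    "CH1": 1.0918,
    "CH2": 1.0858,
    "CN": 1.2679,
    "CNO": 111.31,
    "H1CN": 122.54,
    "H2CN": 116.52,
    "H3ON": 103.41,
    "NO": 1.3867,
    "OH": 0.9607
   }
  },
  "SE": {
   "sigmas": {
    "CH1": 0.00047,
    "CH2": 0.00064,
    "CN": 0.00042,
    "CNO": 0.015,
    "H1CN": 0.043,
    "H2CN": 0.077,
    "H3ON": 0.11,
    "NO": 0.00035,
    "OH": 0.0012
   },
   "values": {
    "CH1": 1.08425,
    "CH2": 1.07952,
    "CN": 1.27112,
    "CNO": 110.548,
    "H1CN": 122.238,
    "H2CN": 116.223,
    "H3ON": 102.65,
    "NO": 1.39899,
    "OH": 0.9627
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "CH1": 1.0873,
    "CH2": 1.0814,
    "CN": 1.2728,
    "CNO": 110.87,
    "H1CN": 122.47,
    "H2CN": 116.33,
    "H3ON": 102.61,
    "NO": 1.4005,
    "OH": 0.9627
   }
  }
 },
 "description": "formaldoxime H2C=NOH, planar",
 "id": "formaldoxime",
 "placements": [
  {
   "atom": "N2",
   "bond_param": "CN",
   "bond_ref": "C1"
  },
  {
   "angle_param": "CNO",
   "angle_ref": "C1",
   "atom": "O3",
   "bond_param": "NO",
   "bond_ref": "N2"
  },
  {
   "angle_param": "H1CN",
   "angle_ref": "N2",
   "atom": "H4",
   "bond_param": "CH1",
   "bond_ref": "C1",
   "note": "planar completion, H1 anti to O",
   "torsion_atoms": [
    "H4",
    "C1",
    "N2",
    "O3"
   ],
   "torsion_name": "H1CNO",
   "torsion_value": 180.0
  },
  {
   "angle_param": "H2CN",
   "angle_ref": "N2",
   "atom": "H5",
   "bond_param": "CH2",
   "bond_ref": "C1",
   "note": "planar completion, H2 syn to O",
   "torsion_atoms": [
    "H5",
    "C1",
    "N2",
    "O3"
   ],
   "torsion_name": "H2CNO",
   "torsion_value": 0.0
  },
  {
   "angle_param": "H3ON",
   "angle_ref": "N2",
   "atom": "H6",
   "bond_param": "OH",
   "bond_ref": "O3",
   "note": "planar completion, OH anti to C",
   "torsion_atoms": [
    "H6",
    "O3",
    "N2",
    "C1"
   ],
   "torsion_name": "HONC",
   "torsion_value": 180.0
  }
 ],
 "printed_mad": {}
}
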