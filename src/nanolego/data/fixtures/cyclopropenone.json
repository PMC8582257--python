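{
 "atoms": [
  [
   "C2",
   "C"
  ],
  [
   "C3",
   "C"
  ],
  [
   "C1",
   "C"
  ],
  [
   "O4",
   "O"
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
    "C1C2": 1.518292,
    "C1C2C3": 61.91,
    "C2C3": 1.4298,
    "CCH": 153.86,
    "CCO": 151.91,
    "CH": 1.0862,
    "CO": 1.2024
   }
  },
  "SE": {
   "sigmas": {
    "C2C3": 0.00042,
    "CCH": 0.0064,
    "CCO": 0.0023,
    "CH": 5.4e-05,
    "CO": 0.00013
   },
   "values": {
    "C1C2": 1.518159,
    "C1C2C3": 61.9272,
    "C2C3": 1.42887,
    "CCH": 153.72,
    "CCO": 151.9272,
    "CH": 1.078173,
    "CO": 1.20043
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "C1C2": 1.524812,
    "C1C2C3": 61.93,
    "C2C3": 1.435,
    "CCH": 153.78,
    "CCO": 151.93,
    "CH": 1.0814,
    "CO": 1.2044
   }
  }
 },
 "description": "cyclopropenone, C2v planar",
 "id": "cyclopropenone",
 "placements": [
  {
   "atom": "C3",
   "bond_param": "C2C3",
   "bond_ref": "C2"
  },
  {
   "angle_param": "C1C2C3",
   "angle_ref": "C3",
   "atom": "C1",
   "bond_param": "C1C2",
   "bond_ref": "C2",
   "note": "C1C2 and C1C2C3 derived from the printed C2C3/CCO by the isoceles ring closure"
  },
  {
   "angle_param": "CCO",
   "angle_ref": "C2",
   "atom": "O4",
   "bond_param": "CO",
   "bond_ref": "C1",
   "note": "planarity completion",
   "torsion_atoms": [
    "O4",
    "C1",
    "C2",
    "C3"
   ],
   "torsion_name": "OC1C2C3",
   "torsion_value": 180.0
  },
  {
   "angle_param": "CCH",
   "angle_ref": "C3",
   "atom": "H5",
   "bond_param": "CH",
   "bond_ref": "C2",
   "note": "planarity completion",
   "torsion_atoms": [
    "H5",
    "C2",
    "C3",
    "C1"
   ],
   "torsion_name": "H5C2C3C1",
   "torsion_value": 180.0
  },
  {
   "angle_name": "CCH6",
   "angle_param": "CCH",
   "angle_ref": "C2",
   "atom": "H6",
   "bond_name": "C3H6",
   "bond_param": "CH",
   "bond_ref": "C3",
   "note": "planarity completion; C2v-equivalent CH reused",
   "torsion_atoms": [
    "H6",
    "C3",
    "C2",
    "C1"
   ],
   "torsion_name": "H6C3C2C1",
   "torsion_value": 180.0
  }
 ],
 "printed_mad": {}
}
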