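{
 "atoms": [
  [
   "B1",
   "B"
  ],
  [
   "H2",
   "H"
  ],
  [
   "F3",
   "F"
  ],
  [
   "O4",
   "O"
  ],
  [
   "H5",
   "H"
  ]
 ],
 "columns": {
  "PW6B95": {
   "values": {
    "BF": 1.339,
    "BH": 1.1973,
    "BO": 1.3478,
    "HBF": 119.14,
    "HBO": 124.38,
    "HOB": 113.07,
    "OH": 0.959
   }
  },
  "SE": {
   "sigmas": {
    "BF": 0.00015,
    "BH": 4.9e-05,
    "BO": 0.00015,
    "HBF": 0.044,
    "HBO": 0.044,
    "HOB": 0.018,
    "OH": 0.00016
   },
   "values": {
    "BF": 1.31961,
    "BH": 1.189385,
    "BO": 1.34626,
    "HBF": 119.381,
    "HBO": 123.459,
    "HOB": 112.714,
    "OH": 0.95735
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "BF": 1.3265,
    "BH": 1.1932,
    "BO": 1.3537,
    "HBF": 119.37,
    "HBO": 123.48,
    "HOB": 112.76,
    "OH": 0.9603
   }
  }
 },
 "description": "fluoro(hydroxy)borane, planar",
 "id": "bhfoh",
 "placements": [
  {
   "atom": "H2",
   "bond_param": "BH",
   "bond_ref": "B1"
  },
  {
   "angle_param": "HBF",
   "angle_ref": "H2",
   "atom": "F3",
   "bond_param": "BF",
   "bond_ref": "B1"
  },
  {
   "angle_param": "HBO",
   "angle_ref": "H2",
   "atom": "O4",
   "bond_param": "BO",
   "bond_ref": "B1",
   "note": "planarity completion",
   "torsion_atoms": [
    "F3",
    "H2",
    "B1",
    "O4"
   ],
   "torsion_name": "FHBO",
   "torsion_value": 180.0
  },
  {
   "angle_param": "HOB",
   "angle_ref": "B1",
   "atom": "H5",
   "bond_param": "OH",
   "bond_ref": "O4",
   "note": "planar conformer completion, OH anti to BH",
   "torsion_atoms": [
    "H5",
    "O4",
    "B1",
    "H2"
   ],
   "torsion_name": "HOBH",
   "torsion_value": 180.0
  }
 ],
 "printed_mad": {}
}
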