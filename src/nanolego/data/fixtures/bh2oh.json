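{
 "atoms": [
  [
   "B1",
   "B"
  ],
  [
   "O2",
   "O"
  ],
  [
   "H3",
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
    "BH1": 1.2044,
    "BH2": 1.1997,
    "BO": 1.3524,
    "HBH": 123.02,
    "HBO": 120.35,
    "HOB": 113.18,
    "OH": 0.96
   }
  },
  "SE": {
   "sigmas": {
    "BH1": 0.0016,
    "BH2": 0.0016,
    "BO": 0.00013,
    "HBH": 0.15,
    "HBO": 0.23,
    "HOB": 0.19,
    "OH": 0.0017
   },
   "values": {
    "BH1": 1.1957,
    "BH2": 1.1899,
    "BO": 1.34979,
    "HBH": 122.84,
    "HBO": 119.8,
    "HOB": 112.9,
    "OH": 0.9558
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "BH1": 1.1982,
    "BH2": 1.1926,
    "BO": 1.3569,
    "HBH": 122.77,
    "HBO": 120.49,
    "HOB": 112.94,
    "OH": 0.9614
   }
  }
 },
 "description": "borinic acid BH2OH, planar",
 "id": "bh2oh",
 "placements": [
  {
   "atom": "O2",
   "bond_param": "BO",
   "bond_ref": "B1"
  },
  {
   "angle_param": "HBO",
   "angle_ref": "O2",
   "atom": "H3",
   "bond_param": "BH1",
   "bond_ref": "B1"
  },
  {
   "angle_param": "HBH",
   "angle_ref": "H3",
   "atom": "H4",
   "bond_param": "BH2",
   "bond_ref": "B1",
   "note": "planarity completion",
   "torsion_atoms": [
    "O2",
    "H3",
    "B1",
    "H4"
   ],
   "torsion_name": "OHBH",
   "torsion_value": 180.0
  },
  {
   "angle_param": "HOB",
   "angle_ref": "B1",
   "atom": "H5",
   "bond_param": "OH",
   "bond_ref": "O2",
   "note": "planar completion, OH hydrogen syn to H1",
   "torsion_atoms": [
    "H5",
    "O2",
    "B1",
    "H3"
   ],
   "torsion_name": "HOBH1",
   "torsion_value": 0.0
  }
 ],
 "printed_mad": {}
}
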