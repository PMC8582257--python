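{
 "atoms": [
  [
   "B2",
   "B"
  ],
  [
   "H1",
   "H"
  ],
  [
   "O3",
   "O"
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
    "B2H1": 1.1986,
    "B2O3H5": 111.932,
    "B2O4H6": 116.52,
    "BO3": 1.3574,
    "BO4": 1.3674,
    "H1B2O3": 118.658,
    "O3B2O4": 118.877,
    "O3H5": 0.9621,
    "O4H6": 0.958
   }
  },
  "SE": {
   "sigmas": {
    "B2H1": 8e-05,
    "B2O3H5": 0.0059,
    "B2O4H6": 0.077,
    "BO3": 0.00019,
    "BO4": 0.00017,
    "H1B2O3": 0.094,
    "O3B2O4": 0.0041,
    "O3H5": 0.00015,
    "O4H6": 0.00024
   },
   "values": {
    "B2H1": 1.189723,
    "B2O3H5": 111.9132,
    "B2O4H6": 116.223,
    "BO3": 1.35353,
    "BO4": 1.36364,
    "H1B2O3": 118.527,
    "O3B2O4": 119.1251,
    "O3H5": 0.96034,
    "O4H6": 0.95625
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "B2H1": 1.1936,
    "B2O3H5": 111.956,
    "B2O4H6": 116.33,
    "BO3": 1.3608,
    "BO4": 1.3709,
    "H1B2O3": 118.534,
    "O3B2O4": 119.171,
    "O3H5": 0.9634,
    "O4H6": 0.9596
   }
  }
 },
 "description": "boronic acid BH(OH)2, planar",
 "id": "bhoh2",
 "placements": [
  {
   "atom": "H1",
   "bond_param": "B2H1",
   "bond_ref": "B2"
  },
  {
   "angle_param": "H1B2O3",
   "angle_ref": "H1",
   "atom": "O3",
   "bond_param": "BO3",
   "bond_ref": "B2"
  },
  {
   "angle_param": "O3B2O4",
   "angle_ref": "O3",
   "atom": "O4",
   "bond_param": "BO4",
   "bond_ref": "B2",
   "note": "planarity completion",
   "torsion_atoms": [
    "H1",
    "O3",
    "B2",
    "O4"
   ],
   "torsion_name": "H1O3B2O4",
   "torsion_value": 180.0
  },
  {
   "angle_param": "B2O3H5",
   "angle_ref": "B2",
   "atom": "H5",
   "bond_param": "O3H5",
   "bond_ref": "O3",
   "note": "planar completion, anti to BH",
   "torsion_atoms": [
    "H5",
    "O3",
    "B2",
    "H1"
   ],
   "torsion_name": "H5O3B2H1",
   "torsion_value": 180.0
  },
  {
   "angle_param": "B2O4H6",
   "angle_ref": "B2",
   "atom": "H6",
   "bond_param": "O4H6",
   "bond_ref": "O4",
   "note": "planar completion, syn to BH",
   "torsion_atoms": [
    "H6",
    "O4",
    "B2",
    "H1"
   ],
   "torsion_name": "H6O4B2H1",
   "torsion_value": 0.0
  }
 ],
 "printed_mad": {}
}
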