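{
  "_comment": "Atomic masses in unified amu from the 2020 atomic mass evaluation (AME2020). 'default' is the mass number of the most abundant isotope.",
  "H":  {"default": 1,  "isotopes": {"1": 1.00782503207, "2": 2.01410177812, "3": 3.01604927791}},
  "B":  {"default": 11, "isotopes": {"10": 10.01293695, "11": 11.00930536}},
  "C":  {"default": 12, "isotopes": {"12": 12.0, "13": 13.00335483507, "14": 14.0032419884}},
  "N":  {"default": 14, "isotopes": {"14": 14.00307400443, "15": 15.00010889888}},
  "O":  {"default": 16, "isotopes": {"16": 15.99491461957, "17": 16.99913175650, "18": 17.99915961286}},
  "F":  {"default": 19, "isotopes": {"19": 18.99840316273}},
  "P":  {"default": 31, "isotopes": {"31": 30.97376199842}},
  "S":  {"default": 32, "isotopes": {"32": 31.9720711744, "33": 32.9714589098, "34": 33.967867004, "36": 35.96708071}},
  "Cl": {"default": 35, "isotopes": {"35": 34.968852682, "37": 36.965902602}}
}
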