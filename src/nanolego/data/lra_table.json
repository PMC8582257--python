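{
  "_comment": "Published LRA parameters per parameter class and level of theory. A: dimensionless slope; B: intercept (Angstrom for bonds, degrees for angles); n: points in the fit; md/mad/neg/pos: residual statistics of the corrected values. intercept_fixed marks parameters constrained to zero in the published fit; entries where both A and B are zero (COH at the double-hybrid level) mean no correction was needed.",
  "entries": [
    {"kind": "bond", "elements": ["C", "C"], "level_tag": "rev-DSDPBEP86", "A": -0.00184, "B": 0.0, "n": 115, "md": -0.00002, "mad": 0.0013, "neg": -0.0072, "pos": 0.0056, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "C"], "level_tag": "PW6B95", "A": 0.00014, "B": 0.0, "n": 115, "md": -0.00006, "mad": 0.0018, "neg": -0.0062, "pos": 0.0073, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "H"], "level_tag": "rev-DSDPBEP86", "A": -0.00239, "B": 0.0, "n": 162, "md": -5e-06, "mad": 0.00059, "neg": -0.0044, "pos": 0.0028, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "H"], "level_tag": "PW6B95", "A": -0.00586, "B": 0.0, "n": 162, "md": -4e-06, "mad": 0.00084, "neg": -0.0042, "pos": 0.0030, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "O"], "level_tag": "rev-DSDPBEP86", "A": -0.00297, "B": 0.0, "n": 48, "md": 0.00004, "mad": 0.00070, "neg": -0.0031, "pos": 0.0022, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "O"], "level_tag": "PW6B95", "A": 0.01708, "B": -0.0212, "n": 48, "md": 0.00003, "mad": 0.0013, "neg": -0.0039, "pos": 0.0029},
    {"kind": "bond", "elements": ["C", "N"], "level_tag": "rev-DSDPBEP86", "A": -0.00234, "B": 0.0, "n": 39, "md": 0.00003, "mad": 0.0013, "neg": -0.0034, "pos": 0.0038, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "N"], "level_tag": "PW6B95", "A": 0.01705, "B": -0.02079, "n": 39, "md": 0.00013, "mad": 0.0019, "neg": -0.0056, "pos": 0.0056},
    {"kind": "bond", "elements": ["C", "S"], "level_tag": "rev-DSDPBEP86", "A": -0.01222, "B": 0.01672, "n": 18, "md": 2e-06, "mad": 0.0012, "neg": -0.0030, "pos": 0.0033},
    {"kind": "bond", "elements": ["C", "S"], "level_tag": "PW6B95", "A": -0.01296, "B": 0.02188, "n": 18, "md": 7e-06, "mad": 0.0017, "neg": -0.0041, "pos": 0.0060},
    {"kind": "bond", "elements": ["C", "F"], "level_tag": "rev-DSDPBEP86", "A": -0.00307, "B": 0.0, "n": 8, "md": 1e-06, "mad": 0.00067, "neg": -0.0012, "pos": 0.0011, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "F"], "level_tag": "PW6B95", "A": -0.00598, "B": 0.0, "n": 8, "md": -8e-06, "mad": 0.00091, "neg": -0.0017, "pos": 0.0013, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "Cl"], "level_tag": "rev-DSDPBEP86", "A": -0.0043, "B": 0.0, "n": 7, "md": -0.00001, "mad": 0.0010, "neg": -0.0028, "pos": 0.0015, "intercept_fixed": true},
    {"kind": "bond", "elements": ["C", "Cl"], "level_tag": "PW6B95", "A": -0.0014, "B": 0.0, "n": 7, "md": -7e-06, "mad": 0.00075, "neg": -0.0023, "pos": 0.0012, "intercept_fixed": true},
    {"kind": "bond", "elements": ["N", "H"], "level_tag": "rev-DSDPBEP86", "A": -0.00216, "B": 0.0, "n": 14, "md": 4e-06, "mad": 0.0011, "neg": -0.0042, "pos": 0.0026, "intercept_fixed": true},
    {"kind": "bond", "elements": ["N", "H"], "level_tag": "PW6B95", "A": -0.00331, "B": 0.0, "n": 14, "md": -8e-06, "mad": 0.0011, "neg": -0.0031, "pos": 0.0032, "intercept_fixed": true},
    {"kind": "bond", "elements": ["O", "H"], "level_tag": "rev-DSDPBEP86", "A": 0.24674, "B": -0.24091, "n": 9, "md": 3e-06, "mad": 0.00038, "neg": -0.00094, "pos": 0.00054},
    {"kind": "bond", "elements": ["O", "H"], "level_tag": "PW6B95", "A": 0.17529, "B": -0.17005, "n": 9, "md": -8e-06, "mad": 0.00030, "neg": -0.00098, "pos": 0.00069},
    {"kind": "angle", "elements": ["C", "C", "H"], "level_tag": "rev-DSDPBEP86", "A": -0.00001, "B": 0.0, "n": 159, "md": -6e-05, "mad": 0.16, "neg": -1.22, "pos": 1.48, "intercept_fixed": true},
    {"kind": "angle", "elements": ["C", "C", "H"], "level_tag": "PW6B95", "A": -0.00027, "B": 0.0, "n": 159, "md": -8e-04, "mad": 0.18, "neg": -1.24, "pos": 1.48, "intercept_fixed": true},
    {"kind": "angle", "elements": ["H", "C", "H"], "level_tag": "rev-DSDPBEP86", "A": 0.01695, "B": -1.77589, "n": 54, "md": 4e-04, "mad": 0.09, "neg": -0.39, "pos": 0.37},
    {"kind": "angle", "elements": ["H", "C", "H"], "level_tag": "PW6B95", "A": 0.02077, "B": -2.01637, "n": 54, "md": -2e-04, "mad": 0.22, "neg": -0.64, "pos": 0.70},
    {"kind": "angle", "elements": ["O", "C", "O"], "level_tag": "rev-DSDPBEP86", "A": -0.06709, "B": 8.1676, "n": 7, "md": -4e-04, "mad": 0.03, "neg": -0.05, "pos": 0.08},
    {"kind": "angle", "elements": ["O", "C", "O"], "level_tag": "PW6B95", "A": 0.00063, "B": 0.0, "n": 7, "md": -9e-05, "mad": 0.10, "neg": -0.22, "pos": 0.19, "intercept_fixed": true},
    {"kind": "angle", "elements": ["H", "C", "N"], "level_tag": "rev-DSDPBEP86", "A": -0.00003, "B": 0.0, "n": 31, "md": -9e-04, "mad": 0.16, "neg": -0.63, "pos": 0.33, "intercept_fixed": true},
    {"kind": "angle", "elements": ["H", "C", "N"], "level_tag": "PW6B95", "A": -0.0014, "B": 0.0, "n": 31, "md": -2e-04, "mad": 0.15, "neg": -0.57, "pos": 0.42, "intercept_fixed": true},
    {"kind": "angle", "elements": ["C", "O", "H"], "level_tag": "rev-DSDPBEP86", "A": 0.0, "B": 0.0, "n": 8, "md": -0.011, "mad": 0.09, "neg": -0.20, "pos": 0.12, "intercept_fixed": true},
    {"kind": "angle", "elements": ["C", "O", "H"], "level_tag": "PW6B95", "A": -0.16466, "B": 17.43968, "n": 8, "md": -4e-04, "mad": 0.09, "neg": -0.15, "pos": 0.23}
  ]
}
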