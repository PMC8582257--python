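# Methods

## Model and scope

The package treats molecules as semi-rigid rotors.  A structure is an
ordered list of atoms; every atom after the first is placed by a distance to
one previously placed atom, a valence angle with a second, and — from the
fourth atom on — a dihedral whose four-atom tuple may reference any three
previously placed atoms, as long as the placed atom sits at one end and the
two middle atoms coincide with the distance/angle references.  This
"improper-tolerant" placement is needed because published parameter tables
routinely define atoms through dihedrals like O5–C4–C3–O7 where the placed
atom is not bonded to the tuple's second atom.  Atoms can also be generated
by reflection through the plane of three placed atoms, which realizes
Cs-symmetric species whose tables list only symmetry-unique parameters.

Torsions follow the right-handed (IUPAC) sign convention: τ(p0,p1,p2,p3) is
positive when, looking from p1 to p2, the bond p2→p3 is rotated clockwise
from p1→p0.  Published tables do not state their convention; the contract
here is self-consistency (build ∘ measure is the identity to < 1e−8 on the
placement coordinates) and the bundled fixtures encode the printed signs,
which reproduce the experimental rotational constants and are therefore
consistent with this convention up to an overall enantiomer choice that
rotational constants cannot distinguish.

Electronic-structure computation is out of scope by design: optimized
geometries and vibrational contributions ΔB^vib are always inputs.

## Units and constants

Ångström, degrees, MHz and unified amu throughout; no unit options exist.
The conversion constant K = h/(8π²) ≈ 505379.0 MHz·amu·Å² is evaluated at
import time from CODATA values via `scipy.constants`, never typed in by
hand.  Isotope masses are bundled from the 2020 atomic-mass evaluation for
H, B, C, N, O, F, P, S and Cl; the most abundant isotope is the default and
isotopologues override masses per atom label.

## Corrections

LRA corrects an optimized bond or angle as r + (A·r + B).  The literature
formula is printed as a subtraction, but only the additive form reproduces
every published corrected column we can check (six independent entries
across four molecules); the additive convention is therefore used and
embedded in every report.  Lookup keys are canonical: unordered element
pairs for bonds, (end, vertex, end) with unordered ends for angles, so a
C–O–H angle never aliases an O–C–H one.  Missing classes are left
uncorrected and flagged — never extrapolated — and torsions are never
corrected (no linear model for them exists).  The bundled registry carries
the published classes (bonds CC, CH, CO, CN, CS, CF, CCl, NH, OH; angles
CCH, HCH, OCO, HCN, COH) for two model-chemistry tags; the full
supplementary set (ring CNC/CNH angle classes etc.) was not printed and is
not bundled, which is why angle corrections at the hybrid level are
incomplete relative to the published corrected columns (documented in the
relevant tests).  New classes can be fitted with `fit_lra_parameters`,
an OLS of (r_SE − r_opt) on r_opt with optional zero intercept; standard
errors and 95% two-sided t intervals come from the usual OLS formulas.

TMA is exact arithmetic: r + (r_SE(template) − r_opt(template)).  Template
choice is explicit user input (a `FragmentAssignment` partitioning the
bonds/angles); there is no automatic substructure matching.  Unmapped
parameters fall back to LRA when a class exists.

## Semi-experimental refinement

`StructureFit` minimizes

  Σ_i w_i (I_i^SE − I_i^calc)² + Σ_p (p − p_target)²/σ_p²

over the chosen free internal coordinates, with I^SE = K/B^SE.  Residuals
are formed in inertia-moment space (amu·Å²) by default, the space in which
fit quality is conventionally quoted; rotational-constant space (MHz) is an
option.  Default weights are 1/σ² from the propagated SE uncertainties
(σ_I = K·σ_B/B²), unit weights when no uncertainty is given, times optional
per-axis multipliers; `down_weight(obs, id, f)` scales an isotopologue's
effective σ by f, so f → ∞ removes it.  Predicates (theoretical parameter
values with a σ) enter as extra residuals — the mixed-regression device that
stabilizes under-determined fits; a predicate with σ → 0 is numerically
equivalent to fixing the parameter.

The optimizer is a damped Gauss–Newton (Levenberg) iteration with a
forward-difference Jacobian (relative step 1e−6 with absolute floors 1e−6 Å
and 1e−5°); the damping parameter decreases tenfold on accepted steps and
increases tenfold on rejected ones.  Convergence is declared when the
relative objective decrease falls below 1e−12 or the step norm below 1e−10.
Parameter covariance is s²(JᵀJ)⁻¹ with s² = cost/(n_eff − p), where n_eff
counts retained axes plus predicates (predicates are observations in the
mixed-regression convention); a singular JᵀJ marks the fit rank-deficient,
the symptom of strongly correlated parameters (e.g. all ring angles free at
once).  The reported `wrms` is the weighted root-mean-square of the
moment-space residuals, √(Σw r²/Σw).  The geometry is built once per
evaluation and reused across isotopologues, since geometry is
isotope-independent.

Staged protocols (releasing parameter groups step by step) are expressed as
ordinary sequences of fits, not a special engine mode.

## Bundled fixtures and their completions

Thirteen published equilibrium-geometry tables are bundled as JSON, pinned
by a sha256 manifest, with per-level columns (optimized, corrected, and
semi-experimental values with standard deviations where printed).  Printed
tables are minimal: they omit ring-closure torsions of planar rings, linear
group angles, and symmetry-redundant parameters.  Those completions are
explicit, flagged fixture data — exact 0/180° torsions by ring topology,
180° for nitrile groups, mirror generation for the out-of-plane CH₂
hydrogens of (cyanomethylene)cyclopropane — never load-time heuristics.
Known misprints are stored as printed together with a plausible value and a
note; tests exercise only unflagged values.

Two completions deserve mention.  (Cyanomethylene)cyclopropane has a planar
heavy-atom skeleton (the ring-fusion carbon is sp², and the experimental
planar moment Pc ≈ 3.3 amu·Å² is accounted for by the four CH₂ hydrogens
alone), so both ring carbons are placed in the heavy-atom plane reusing the
printed symmetry-unique bond/angle, and only the CH₂ hydrogens are
mirror-generated; the printed C5C6/C4C5C6 values are kept as consistency
checks, reproduced to ~0.0015 Å / 0.12° (the printed values are mutually
inconsistent at that rounding level).  Cyclopropenone's C1–C2 distance and
C1C2C3 angle are not printed; they are derived once from the printed base
and apex angle by the isosceles ring closure and stored as flagged values.

The synthetic generator emulates what the fixtures cannot: tree-connected
molecules with bonds in 0.9–1.9 Å, angles in 90–150°, uniform torsions,
hydrogens as leaves on a C/N/O backbone, deterministic per seed.  Synthetic
isotopologue studies add a stored vibrational contribution (0.1–1% of each
constant, negative) and Gaussian noise to the exact constants, so removing
the stored contribution inverts exactly at zero noise.  What passing
synthetic tests shows: the estimator recovers identifiable parameters,
its reported uncertainties are calibrated (3σ̂ coverage ≥ 95% at σ_B = 0.05
MHz over 200 replicates of an 8-isotopologue study), and limits (tight
predicates, infinite down-weighting) behave exactly.  What it does not
show: behaviour under model error — real vibrational corrections carry
correlated, state-dependent errors (large-amplitude motions especially),
real isotopologue sets are far from random, and real parameter sets are
often nearly unidentifiable, which is precisely why predicates exist.

## Numerical choices

Placement solves the dihedral constraint by a rotate-and-match step around
the distance/angle axis (exact up to floating point, verified to 1e−6° at
build time); collinear references raise immediately.  Valence angles of
exactly 180° are allowed in placements (linear groups) and skip the
azimuth.  Linear molecules report A as undefined with a flag rather than
infinity (moment threshold 1e−8 amu·Å²).  MAD% is the mean over the three
axes of 100·|calc − exp|/exp with the experimental constant in the
denominator, displayed to two decimals; display rounding elsewhere follows
the conventions of the source tables (4 decimals for Å, 2 for degrees, 3
for MHz).

## Known limitations

* Only the parameter classes printed in the main regression table are
  bundled; hybrid-level angle corrections are therefore incomplete
  (see above), and species outside H/B/C/N/O/F/P/S/Cl have no masses.
* The published SE fits of the small-molecule set cannot be reproduced here
  because their per-isotopologue experimental constants live in the cited
  primary literature; the refinement engine is validated on synthetic
  studies instead.
* Vibrational corrections are inputs; nothing here computes them, and
  large-amplitude motions are handled only to the extent the supplied
  corrections already account for them.
* The cysteine corrected-geometry constants printed in the source table are
  not consistent with the printed corrected geometry itself (rebuilding the
  printed column gives B about 9 MHz lower); the pipeline reproduces the
  bare-geometry columns to ~0.05% but scores ~0.20 MAD% for corrected
  cysteine where the table prints 0.34.
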