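# nanolego

Accurate equilibrium molecular structures from corrected DFT geometries and
semi-experimental rotational constants.

Rotational spectroscopy measures ground-state rotational constants
B<sub>α</sub><sup>0</sup> (α = a, b, c), which are inversely proportional to
the principal moments of inertia and therefore encode molecular geometry.
The *semi-experimental* (SE) route to an equilibrium structure r<sub>e</sub>
removes computed vibrational contributions,

&nbsp;&nbsp;&nbsp;&nbsp;B<sub>α</sub><sup>SE</sup> = B<sub>α</sub><sup>0</sup> − ΔB<sub>α</sub><sup>vib</sup>,&nbsp;&nbsp;&nbsp;&nbsp;ΔB<sup>vib</sup> ≡ B<sup>0</sup> − B<sup>e</sup>,

and refines the internal coordinates of the molecule by weighted nonlinear
least squares over a set of isotopologues.  For molecules too large for a
full set of isotopic substitutions, DFT-optimized geometries can instead be
*corrected* towards SE quality:

* **TMA** (template-molecule approach) transfers the SE-minus-optimized
  offset of a chemically similar fragment:
  r<sub>corr</sub> = r<sub>opt</sub> + [r<sub>e</sub><sup>SE</sup>(TM) − r<sub>opt</sub>(TM)];
* **LRA** (linear-regression approach) applies a per-parameter-class linear
  model fitted over a database of SE structures:
  r<sub>corr</sub> = r<sub>opt</sub> + (A·r<sub>opt</sub> + B),
  with (A, B) depending only on the atoms involved and the model chemistry.

This package implements the whole workflow for semi-rigid molecules:

* a Z-matrix-style internal-coordinate engine (improper dihedral references
  and mirror-plane symmetry completion included), Cartesian construction,
  isotopologue mass bookkeeping, inertia tensors, rotational constants and
  inertia defects;
* the LRA/TMA correction machinery with the published regression parameters
  for the `rev-DSDPBEP86` (double-hybrid) and `PW6B95` (hybrid) model
  chemistries bundled, plus an OLS fitter to parameterize new classes from
  (r_opt, r_SE) pairs;
* a statsmodels-style estimator (`sefit.StructureFit` →
  `StructureFitResults`) for SE refinements with per-axis weights,
  down-weighting, and predicate observations (mixed regression);
* bundled machine-readable fixtures of thirteen published equilibrium
  geometries (cysteine, guanine, benzofuran, 8-hydroxyquinoline,
  (cyanomethylene)cyclopropane, phenol, oxazole, isoxazole, formaldoxime,
  cyclopropenone and three boron acids), and synthetic molecule/isotopologue
  generators for offline validation;
* a `nanolego` command-line tool tying it together
  (`build`, `rotconst`, `correct`, `sefit`, `pipeline`, `fixtures`).

## Worked example

Predict the ground-state rotational constants of guanine (keto N7H) from its
double-hybrid geometry, after LRA correction, and score them against the
laser-ablation microwave measurements:

```sh
nanolego fixtures export guanine --column rev-DSDPBEP86 -o guanine.zmat
nanolego pipeline guanine.zmat --level rev-DSDPBEP86 \
    --dvib -11.662,-6.715,-4.227 \
    --exp 1922.155,1121.6840,709.0079
```

The report lists every parameter with its correction provenance, e.g.

```
parameter       kind          original   corrected  method
N1C2            distance        1.3615      1.3583  LRA (NC@rev-DSDPBEP86)
C4C5            distance        1.3889      1.3863  LRA (CC@rev-DSDPBEP86)
N1C2N3          angle           113.30      113.30  none  [uncorrected: no parameterization]
N1C2N3C4        torsion           0.00        0.00  none  [torsions are never LRA-corrected]
...
axis       B_e (MHz)      dvib      B_0 pred       B_0 exp   dev %
A           1932.668   -11.662      1921.006      1922.155   -0.06
B           1127.908    -6.715      1121.193      1121.684   -0.04
C            712.830    -4.227       708.603       709.008   -0.06
MAD% = 0.05
```

Reading: the corrected equilibrium constants B<sub>e</sub>, augmented by the
vibrational contributions, reproduce the experimental ground-state constants
to 0.05% on average — an order of magnitude better than the bare
double-hybrid geometry (0.53%), and competitive with coupled-cluster-based
composite schemes at a small fraction of their cost.

The same things are available as a library:

```python
from nanolego.fixtures import load_fixture
from nanolego.corrections import bundled_registry, correct_structure_lra
from nanolego.pipeline import ground_state_prediction

fx = load_fixture("guanine")
spec, report = correct_structure_lra(fx.structure("rev-DSDPBEP86"),
                                     bundled_registry(), "rev-DSDPBEP86")
rec = ground_state_prediction(spec, fx.dvib, fx.experimental)
print(rec.mad_percent)   # 0.05
```

and the SE refinement follows the usual model/results pattern:

```python
from nanolego.sefit import StructureFit
model = StructureFit(structure, observations, free=["S1C2", "S1C2C3"],
                     predicates=[...])
results = model.fit()
print(results.summary())   # refined values, std devs, weighted RMS
```

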