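"""Bundled case-study structures and synthetic molecule/study generators.

The bundled fixtures are machine-readable encodings of published equilibrium
geometry tables: per-level internal-coordinate columns (optimized,
regression-corrected, template-corrected and, where available,
semi-experimental values with their standard deviations), the vibrational
contributions to the rotational constants, and the experimental ground-state
constants.  Parameters that the printed tables leave implicit (ring-closure
torsions of planar rings, linear-group angles, symmetry completions) are
stored explicitly in the fixture files as flagged completions, never
rederived heuristically at load time.

The synthetic generators produce tree-connected semi-rigid molecules with
chemically plausible bond/angle ranges and isotopologue "studies" (noisy
ground-state constants plus stored vibrational contributions) for exercising
the refinement machinery offline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import (
    Atom,
    MirrorPlacement,
    Placement,
    StructureDefinition,
    build_cartesian,
    isotopologue_masses,
    rotational_constants,
)

__all__ = [
    "CaseStudyFixture",
    "SyntheticStudy",
    "available_fixtures",
    "load_fixture",
    "fixture_manifest",
    "synth_molecule",
    "synth_study",
]


def _fixture_dir():
    return resources.files("nanolego.data").joinpath("fixtures")


def fixture_manifest() -> dict:
    with _fixture_dir().joinpath("manifest.json").open() as fh:
        return json.load(fh)


def available_fixtures() -> list[str]:
    return sorted(fixture_manifest()["fixtures"])


@dataclass(frozen=True)
class CaseStudyFixture:
    """One bundled molecule: topology plus per-level parameter columns."""

    id: str
    source_table: str
    raw: dict = field(repr=False)

    @property
    def columns(self) -> list[str]:
        return list(self.raw["columns"])

    @property
    def atoms(self) -> list[Atom]:
        return [Atom(label, element) for label, element in self.raw["atoms"]]

    @property
    def dvib(self) -> dict | None:
        """Vibrational contributions (B0 - Be) per axis, MHz."""
        return self.raw.get("dvib")

    @property
    def experimental(self) -> dict | None:
        """Experimental ground-state constants per axis, MHz."""
        return self.raw.get("experimental")

    @property
    def printed_mad(self) -> dict:
        return self.raw.get("printed_mad", {})

    @property
    def misprints(self) -> list:
        return self.raw.get("misprints", [])

    @property
    def checks(self) -> dict:
        """Printed values that are consistency checks, not placement inputs."""
        return self.raw.get("checks", {})

    def params(self, column: str) -> dict:
        return dict(self.raw["columns"][column]["values"])

    def sigmas(self, column: str) -> dict:
        return dict(self.raw["columns"][column].get("sigmas", {}))

    def fixed_params(self, column: str) -> list:
        return list(self.raw["columns"][column].get("fixed_params", []))

    def _param_value(self, column: str, param: str, slot: str):
        col = self.raw["columns"][column]
        if param in col["values"]:
            return col["values"][param]
        base = col.get("torsions_from")
        if slot == "torsion" and base is not None:
            return self.raw["columns"][base]["values"][param]
        raise KeyError(
            f"{self.id}: column {column!r} has no value for parameter {param!r}")

    def structure(self, column: str) -> StructureDefinition:
        """Buildable structure definition for one level-of-theory column."""
        if column not in self.raw["columns"]:
            raise KeyError(f"{self.id}: unknown column {column!r}; have {self.columns}")
        placements = []
        for p in self.raw["placements"]:
            if "mirror_source" in p:
                placements.append(MirrorPlacement(
                    p["atom"], p["mirror_source"], tuple(p["mirror_plane"])))
                continue
            kw = {"atom": p["atom"]}
            names = {}
            for slot, ref_key in (("distance", "bond"), ("angle", "angle"),
                                  ("torsion", "torsion")):
                if f"{ref_key}_ref" not in p and f"{ref_key}_atoms" not in p:
                    continue
                if slot == "torsion":
                    kw["torsion_atoms"] = tuple(p["torsion_atoms"])
                else:
                    kw[f"{slot}_ref"] = p[f"{ref_key}_ref"]
                if f"{ref_key}_param" in p:
                    param = p[f"{ref_key}_param"]
                    kw[slot] = self._param_value(column, param, slot)
                    names[slot] = p.get(f"{ref_key}_name", param)
                else:
                    kw[slot] = p[f"{ref_key}_value"]
                    if f"{ref_key}_name" in p:
                        names[slot] = p[f"{ref_key}_name"]
            kw["names"] = names
            placements.append(Placement(**kw))
        return StructureDefinition(self.atoms, placements)

    def ground_state_constants(self, column: str) -> tuple[float, float, float]:
        """Equilibrium constants of the rebuilt column geometry plus dvib."""
        if self.dvib is None:
            raise ValueError(f"{self.id}: no vibrational contributions bundled")
        rc = rotational_constants(build_cartesian(self.structure(column)))
        return tuple(rc.constants()[i] + self.dvib[ax]
                     for i, ax in enumerate("ABC"))


_ALIASES = {
    "8hq": "8-hydroxyquinoline",
    "bh(oh)2": "bhoh2",
    "cmc": "cyanomethylenecyclopropane",
}


def load_fixture(fixture_id: str) -> CaseStudyFixture:
    key = fixture_id.strip().lower()
    key = _ALIASES.get(key, key)
    manifest = fixture_manifest()
    if key not in manifest["fixtures"]:
        raise KeyError(f"unknown fixture {fixture_id!r}; "
                       f"available: {sorted(manifest['fixtures'])}")
    entry = manifest["fixtures"][key]
    path = _fixture_dir().joinpath(entry["file"])
    data = path.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != entry["sha256"]:
        raise RuntimeError(f"fixture {key!r} does not match its pinned checksum")
    return CaseStudyFixture(id=key, source_table=entry["source"],
                            raw=json.loads(data))


# ---------------------------------------------------------------------------
# synthetic molecules and studies

_SYNTH_ELEMENTS = ["C", "C", "C", "N", "O"]  # heavy-atom draw, carbon-rich
_SUBSTITUTIONS = {"H": 2, "C": 13, "N": 15, "O": 18}


def synth_molecule(seed: int, n_atoms: int) -> StructureDefinition:
    """Random tree-connected, chemically plausible semi-rigid molecule.

    Heavy atoms (C/N/O) form the tree backbone and hydrogens are attached as
    leaves; bonds are drawn in 0.9-1.9 A, valence angles in 90-150 deg and
    torsions uniformly.  Deterministic for a given seed.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    n_heavy = max(2, int(np.ceil(n_atoms * 0.6)))
    n_heavy = min(n_heavy, n_atoms)
    elements = [str(rng.choice(_SYNTH_ELEMENTS)) for _ in range(n_heavy)]
    elements += ["H"] * (n_atoms - n_heavy)
    counts: dict[str, int] = {}
    atoms = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        atoms.append(Atom(f"{el}{counts[el]}", el))

    placements = []
    for i in range(1, n_atoms):
        at = atoms[i]
        # hydrogens attach to heavy atoms; heavy atoms to any previous heavy atom
        pool = [j for j in range(min(i, n_heavy))] or [0]
        a = int(rng.choice(pool))
        r = float(rng.uniform(0.9, 1.9)) if at.element != "H" \
            else float(rng.uniform(0.95, 1.2))
        kw = dict(atom=at.label, distance_ref=atoms[a].label, distance=r)
        if i >= 2:
            b = int(rng.choice([j for j in pool if j != a])) if len(pool) > 1 else (
                1 if a == 0 else 0)
            kw.update(angle_ref=atoms[b].label,
                      angle=float(rng.uniform(90.0, 150.0)))
        if i >= 3:
            others = [j for j in range(i) if atoms[j].label not in
                      (kw["distance_ref"], kw["angle_ref"])]
            c = int(rng.choice(others))
            kw.update(
                torsion_atoms=(at.label, kw["distance_ref"], kw["angle_ref"],
                               atoms[c].label),
                torsion=float(rng.uniform(-180.0, 180.0)))
        placements.append(Placement(**kw))
    return StructureDefinition(atoms, placements)


@dataclass
class SyntheticStudy:
    """Simulated isotopologue study with known ground truth."""

    structure: StructureDefinition
    seed: int
    noise_sigma: float
    isotopologues: list  # of dicts: overrides, b0 (per axis), dvib, sigma
    exact_constants: list  # noise-free equilibrium constants per isotopologue

    def observations(self):
        """(overrides, per-axis B0, per-axis dvib, sigma) rows."""
        return self.isotopologues


def synth_study(spec: StructureDefinition, n_iso: int, noise_sigma: float,
                seed: int) -> SyntheticStudy:
    """Simulate ground-state constants for random isotopologues of ``spec``.

    The parent species is always included.  Substituted species carry one or
    two substitutions among H->D, 12C->13C, 14N->15N, 16O->18O.  Ground-state
    constants are the exact equilibrium constants of the geometry plus a
    stored vibrational contribution (drawn once per isotopologue and axis,
    0.1-1% of the constant, negative) plus Gaussian noise of width
    ``noise_sigma`` (MHz), so that removing the stored contribution recovers
    the equilibrium constant up to the noise exactly.
    """
    if n_iso < 1:
        raise ValueError("need at least one isotopologue")
    rng = np.random.default_rng(seed)
    geom = build_cartesian(spec)
    subs = [a.label for a in spec.atoms if a.element in _SUBSTITUTIONS]
    if not subs and n_iso > 1:
        raise ValueError("no substitutable atoms in structure")
    amap = spec.atom_map()

    iso_specs: list[dict] = [{}]
    seen = {frozenset()}
    attempts = 0
    while len(iso_specs) < n_iso and attempts < 200 * n_iso:
        attempts += 1
        k = int(rng.integers(1, 3))
        chosen = tuple(sorted(rng.choice(subs, size=min(k, len(subs)),
                                         replace=False)))
        key = frozenset(chosen)
        if key in seen:
            continue
        seen.add(key)
        iso_specs.append({lab: _SUBSTITUTIONS[amap[lab].element] for lab in chosen})

    rows, exact = [], []
    for ov in iso_specs:
        rc = rotational_constants(geom, isotopologue_masses(spec, ov))
        be = np.array(rc.constants())
        dvib = -be * rng.uniform(0.001, 0.01, size=3)
        b0 = be + dvib + rng.normal(0.0, noise_sigma, size=3)
        rows.append({
            "overrides": ov,
            "b0": {ax: float(b0[i]) for i, ax in enumerate("abc")},
            "dvib": {ax: float(dvib[i]) for i, ax in enumerate("abc")},
            "sigma": float(noise_sigma),
        })
        exact.append(tuple(float(x) for x in be))
    return SyntheticStudy(structure=spec, seed=seed, noise_sigma=noise_sigma,
                          isotopologues=rows, exact_constants=exact)
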