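"""Internal-coordinate structure model and inertial analysis.

A molecule is described by an ordered list of atoms where every atom after
the first is placed by internal coordinates: a distance to one previously
placed atom, a valence angle with a second, and (from the fourth atom on) a
dihedral whose four-atom tuple may be "improper", i.e. reference any three
previously placed atoms as long as the placed atom sits at one end of the
tuple and the two middle atoms are the distance and angle references.
Atoms may alternatively be generated by reflection through a plane defined
by three placed atoms, which is how Cs-symmetric species whose parameter
tables list only symmetry-unique values are completed.

Dihedral sign convention: the standard right-handed (IUPAC) torsion, i.e.
``tau(p0,p1,p2,p3)`` is positive when, looking from ``p1`` towards ``p2``,
the far bond ``p2->p3`` is rotated clockwise from the near bond ``p1->p0``.
Building and re-measuring are mutually consistent under this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ROTATIONAL_K, isotope_mass

__all__ = [
    "Atom",
    "InternalCoordinate",
    "Placement",
    "MirrorPlacement",
    "StructureDefinition",
    "CartesianGeometry",
    "RotationalConstants",
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "measure_internal",
    "build_cartesian",
    "reflect_through_plane",
    "isotopologue_masses",
    "rotational_constants",
    "inertia_defect",
]

_COLLINEAR_TOL = 1e-10
#: moment (amu A^2) below which the molecule is treated as linear
_LINEAR_MOMENT_TOL = 1e-8


class GeometryError(ValueError):
    """Ill-defined construction frame or unresolvable reference."""


@dataclass(frozen=True)
class Atom:
    label: str
    element: str
    mass_number: int | None = None  # None -> most abundant isotope

    @property
    def mass(self) -> float:
        return isotope_mass(self.element, self.mass_number)


@dataclass(frozen=True)
class InternalCoordinate:
    """A measurable distance (A), angle (deg) or torsion (deg)."""

    kind: str  # distance | angle | torsion
    atoms: tuple[str, ...]
    value: float | None = None

    def __post_init__(self):
        n = {"distance": 2, "angle": 3, "torsion": 4}.get(self.kind)
        if n is None:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        if len(self.atoms) != n:
            raise ValueError(f"{self.kind} needs {n} atoms, got {self.atoms}")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"repeated atom label in {self.atoms}")
        if self.value is not None:
            if self.kind == "distance" and self.value <= 0:
                raise ValueError("distance must be positive")
            if self.kind == "angle" and not (0.0 < self.value <= 180.0):
                raise ValueError("angle must lie in (0, 180]")


@dataclass
class Placement:
    """Internal-coordinate placement of one atom.

    ``torsion_atoms`` is the full four-label tuple of the dihedral used to
    fix the azimuth; the placed atom must be first or last in it and the two
    middle labels must coincide with ``distance_ref`` and ``angle_ref``.
    Coordinate names default to the concatenated atom labels so they match
    the way parameters are referred to in spectroscopy tables.
    """

    atom: str
    distance_ref: str | None = None
    distance: float | None = None
    angle_ref: str | None = None
    angle: float | None = None
    torsion_atoms: tuple[str, str, str, str] | None = None
    torsion: float | None = None
    names: dict = field(default_factory=dict)  # slot -> coordinate name

    SLOTS = ("distance", "angle", "torsion")

    def name_of(self, slot: str) -> str | None:
        if getattr(self, slot) is None:
            return None
        if slot in self.names:
            return self.names[slot]
        if slot == "distance":
            return f"{self.distance_ref}{self.atom}"
        if slot == "angle":
            return f"{self.angle_ref}{self.distance_ref}{self.atom}"
        return "".join(self.torsion_atoms)


@dataclass
class MirrorPlacement:
    """Atom generated by reflecting ``source`` through the plane of three atoms."""

    atom: str
    source: str
    plane: tuple[str, str, str]


@dataclass
class StructureDefinition:
    """Ordered atoms plus the internal coordinates that place them."""

    atoms: list[Atom]
    placements: list  # Placement | MirrorPlacement, one per atom after the first... see __post_init__

    def __post_init__(self):
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate atom labels")
        if len(self.placements) != max(len(self.atoms) - 1, 0):
            raise ValueError("need exactly one placement per atom after the first")
        placed = {labels[0]}
        for i, pl in enumerate(self.placements):
            expect = labels[i + 1]
            if pl.atom != expect:
                raise ValueError(f"placement {i} is for {pl.atom!r}, expected {expect!r}")
            refs = self._refs(pl, n_placed=len(placed))
            missing = [r for r in refs if r not in placed]
            if missing:
                raise ValueError(f"placement of {pl.atom!r} references unplaced atom(s) {missing}")
            placed.add(pl.atom)

    @staticmethod
    def _refs(pl, n_placed: int) -> list[str]:
        if isinstance(pl, MirrorPlacement):
            return [pl.source, *pl.plane]
        refs = []
        if pl.distance_ref is None:
            raise ValueError(f"atom {pl.atom!r} lacks a distance reference")
        refs.append(pl.distance_ref)
        if n_placed >= 2:
            if pl.angle_ref is None:
                raise ValueError(f"atom {pl.atom!r} lacks an angle reference")
            refs.append(pl.angle_ref)
        if n_placed >= 3 and abs((pl.angle or 0.0) - 180.0) > 1e-12:
            if pl.torsion_atoms is None:
                raise ValueError(f"atom {pl.atom!r} lacks a torsion")
            t = pl.torsion_atoms
            if t[0] == pl.atom:
                mid, ref4 = {t[1], t[2]}, t[3]
            elif t[3] == pl.atom:
                mid, ref4 = {t[1], t[2]}, t[0]
            else:
                raise ValueError(
                    f"placed atom {pl.atom!r} must be first or last in torsion {t}")
            if mid != {pl.distance_ref, pl.angle_ref}:
                raise ValueError(
                    f"torsion {t} of {pl.atom!r} must pivot on the distance/angle references")
            refs += [x for x in t if x != pl.atom]
        return refs

    # -- parameter access ---------------------------------------------------

    def atom_map(self) -> dict[str, Atom]:
        return {a.label: a for a in self.atoms}

    def coordinates(self):
        """Yield (name, kind, atoms, value, placement, slot) for every placement coordinate."""
        for pl in self.placements:
            if isinstance(pl, MirrorPlacement):
                continue
            if pl.distance is not None:
                yield (pl.name_of("distance"), "distance",
                       (pl.distance_ref, pl.atom), pl.distance, pl, "distance")
            if pl.angle is not None:
                yield (pl.name_of("angle"), "angle",
                       (pl.angle_ref, pl.distance_ref, pl.atom), pl.angle, pl, "angle")
            if pl.torsion is not None:
                yield (pl.name_of("torsion"), "torsion",
                       pl.torsion_atoms, pl.torsion, pl, "torsion")

    def values(self) -> dict[str, float]:
        return {name: value for name, _, _, value, _, _ in self.coordinates()}

    def with_values(self, updates: dict[str, float]) -> "StructureDefinition":
        """Copy of the structure with named coordinates set to new values."""
        remaining = dict(updates)
        new_placements = []
        for pl in self.placements:
            if isinstance(pl, MirrorPlacement):
                new_placements.append(replace(pl))
                continue
            kw = {}
            for slot in Placement.SLOTS:
                name = pl.name_of(slot)
                if name is not None and name in remaining:
                    kw[slot] = remaining.pop(name)
            new_placements.append(replace(pl, **kw) if kw else replace(pl))
        if remaining:
            raise KeyError(f"unknown coordinate name(s): {sorted(remaining)}")
        return StructureDefinition(list(self.atoms), new_placements)

    def build(self) -> "CartesianGeometry":
        return build_cartesian(self)


@dataclass
class CartesianGeometry:
    labels: list[str]
    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    masses: np.ndarray  # amu

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def position(self, label: str) -> np.ndarray:
        try:
            return self.coords[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no atom labelled {label!r}") from None

    def with_masses(self, masses) -> "CartesianGeometry":
        return CartesianGeometry(self.labels, self.elements, self.coords.copy(),
                                 np.asarray(masses, dtype=float))


# ---------------------------------------------------------------------------
# measurement

def measure_distance(p0, p1) -> float:
    return float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))


def measure_angle(p0, p1, p2) -> float:
    """Angle at the middle atom p1, in degrees."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise GeometryError("coincident atoms in angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of the four points, degrees in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL or np.linalg.norm(n1) < _COLLINEAR_TOL \
            or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("undefined torsion: collinear reference atoms")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def measure_internal(geom: CartesianGeometry, coord: InternalCoordinate) -> float:
    pts = [geom.position(a) for a in coord.atoms]
    if coord.kind == "distance":
        return measure_distance(*pts)
    if coord.kind == "angle":
        return measure_angle(*pts)
    return measure_dihedral(*pts)


# ---------------------------------------------------------------------------
# construction

def reflect_through_plane(point, plane_points) -> np.ndarray:
    """Reflect ``point`` through the plane spanned by three points."""
    a, b, c = (np.asarray(p, dtype=float) for p in plane_points)
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise GeometryError("collinear plane definition")
    n = n / nn
    p = np.asarray(point, dtype=float)
    return p - 2.0 * np.dot(p - a, n) * n


def _wrap180(x: float) -> float:
    return (x + 180.0) % 360.0 - 180.0


def _place_on_cone(a, b, r, theta_deg, psi_deg, e1, e2):
    """Point at distance r from a, valence angle theta with b, azimuth psi."""
    u = (b - a) / np.linalg.norm(b - a)
    th = math.radians(theta_deg)
    ps = math.radians(psi_deg)
    d = math.cos(th) * u + math.sin(th) * (math.cos(ps) * e1 + math.sin(ps) * e2)
    return a + r * d


def build_cartesian(spec: StructureDefinition) -> CartesianGeometry:
    """Realize a structure definition in a canonical Cartesian frame.

    First atom at the origin, second on +z, third in the xz half-plane with
    x >= 0.  Round trip: re-measuring any placement coordinate on the output
    reproduces its input value to well below 1e-8.
    """
    if not spec.atoms:
        raise ValueError("empty structure")
    pos: dict[str, np.ndarray] = {spec.atoms[0].label: np.zeros(3)}

    for idx, pl in enumerate(spec.placements):
        n_placed = idx + 1
        if isinstance(pl, MirrorPlacement):
            pos[pl.atom] = reflect_through_plane(
                pos[pl.source], [pos[p] for p in pl.plane])
            continue
        a = pos[pl.distance_ref]
        r = pl.distance
        if r is None or r <= 0:
            raise GeometryError(f"atom {pl.atom!r}: invalid distance {r}")
        if n_placed == 1:
            pos[pl.atom] = a + np.array([0.0, 0.0, r])
            continue
        b = pos[pl.angle_ref]
        axis = b - a
        if np.linalg.norm(axis) < _COLLINEAR_TOL:
            raise GeometryError(f"atom {pl.atom!r}: coincident references")
        u = axis / np.linalg.norm(axis)
        theta = pl.angle
        if theta is None or not (0.0 < theta <= 180.0):
            raise GeometryError(f"atom {pl.atom!r}: invalid angle {theta}")
        if abs(theta - 180.0) <= 1e-12:
            # collinear placement; no azimuth needed
            pos[pl.atom] = a - r * u
            continue
        if n_placed == 2:
            # third atom: fix the frame by putting it in the xz plane, x >= 0
            e1 = np.array([1.0, 0.0, 0.0])
            e1 = e1 - np.dot(e1, u) * u
            if np.linalg.norm(e1) < _COLLINEAR_TOL:  # axis happens to be x
                e1 = np.array([0.0, 0.0, 1.0]) - u * u[2]
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            pos[pl.atom] = _place_on_cone(a, b, r, theta, 0.0, e1, e2)
            continue
        # general atom: azimuth from the dihedral tuple
        t = pl.torsion_atoms
        tau = pl.torsion
        if t is None or tau is None:
            raise GeometryError(f"atom {pl.atom!r}: missing torsion")
        if t[3] == pl.atom:
            t = tuple(reversed(t))  # dihedral invariant under full reversal
        ref4 = pos[t[3]]
        # azimuth basis perpendicular to the a-b axis, oriented by ref4
        v = ref4 - a
        e1 = v - np.dot(v, u) * u
        if np.linalg.norm(e1) < _COLLINEAR_TOL:
            raise GeometryError(
                f"atom {pl.atom!r}: torsion reference {t[3]!r} collinear with axis")
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)

        def dih_at(psi):
            p = _place_on_cone(a, b, r, theta, psi, e1, e2)
            pts = [p if lbl == pl.atom else pos[lbl] for lbl in t]
            return measure_dihedral(*pts)

        d0 = dih_at(0.0)
        sign = 1.0 if _wrap180(dih_at(90.0) - d0) > 0 else -1.0
        psi = sign * _wrap180(tau - d0)
        pos[pl.atom] = _place_on_cone(a, b, r, theta, psi, e1, e2)
        if abs(_wrap180(dih_at(psi) - tau)) > 1e-6:
            raise GeometryError(f"atom {pl.atom!r}: torsion placement failed")

    labels = [at.label for at in spec.atoms]
    return CartesianGeometry(
        labels=labels,
        elements=[at.element for at in spec.atoms],
        coords=np.array([pos[l] for l in labels]),
        masses=np.array([at.mass for at in spec.atoms]),
    )


# ---------------------------------------------------------------------------
# inertial analysis

def isotopologue_masses(spec: StructureDefinition, overrides: dict[str, int] | None = None
                        ) -> np.ndarray:
    """Per-atom masses with isotopic substitutions applied by atom label."""
    overrides = dict(overrides or {})
    masses = []
    for at in spec.atoms:
        mn = overrides.pop(at.label, at.mass_number)
        masses.append(isotope_mass(at.element, mn))
    if overrides:
        raise KeyError(f"unknown atom label(s) in isotopologue spec: {sorted(overrides)}")
    return np.array(masses)


@dataclass(frozen=True)
class RotationalConstants:
    """Principal moments (amu A^2, Ia <= Ib <= Ic) and constants A >= B >= C (MHz)."""

    A: float | None
    B: float
    C: float
    Ia: float
    Ib: float
    Ic: float
    linear: bool = False

    def constants(self) -> tuple[float, float, float]:
        if self.linear:
            raise ValueError("A is undefined for a linear molecule")
        return (self.A, self.B, self.C)

    def moments(self) -> tuple[float, float, float]:
        return (self.Ia, self.Ib, self.Ic)


def inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Inertia tensor about the centre of mass (amu A^2)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = masses @ coords / masses.sum()
    x = coords - com
    r2 = np.sum(x * x, axis=1)
    return np.einsum("i,ijk->jk",
                     masses,
                     r2[:, None, None] * np.eye(3) - np.einsum("ij,ik->ijk", x, x))


def rotational_constants(geom: CartesianGeometry, masses=None) -> RotationalConstants:
    """Principal moments and rotational constants of a rigid geometry.

    Invariant under rigid rotation/translation of the input; ``B_alpha *
    I_alpha = K`` identically for every non-degenerate axis.
    """
    if len(geom.labels) < 2:
        raise ValueError("need at least two atoms")
    m = geom.masses if masses is None else np.asarray(masses, dtype=float)
    tensor = inertia_tensor(geom.coords, m)
    Ia, Ib, Ic = np.linalg.eigvalsh(tensor)
    if Ic < _LINEAR_MOMENT_TOL:
        raise ValueError("all atoms coincident")
    linear = Ia < _LINEAR_MOMENT_TOL
    return RotationalConstants(
        A=None if linear else ROTATIONAL_K / Ia,
        B=ROTATIONAL_K / Ib,
        C=ROTATIONAL_K / Ic,
        Ia=float(Ia), Ib=float(Ib), Ic=float(Ic),
        linear=bool(linear),
    )


def inertia_defect(rc: RotationalConstants) -> float:
    """Planarity diagnostic Delta = Ic - Ia - Ib; 0 for a rigid planar geometry."""
    if rc.linear:
        raise ValueError("inertia defect undefined for a linear molecule")
    return rc.Ic - rc.Ia - rc.Ib
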