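"""File formats: XYZ, the internal-coordinate text dialect, and JSON schemas.

Units are fixed globally (Angstrom, degrees, MHz, amu); there are no unit
options, so files can never silently disagree with the library.

The internal-coordinate ("zmat") dialect is one atom per line::

    label element
    label element  ref distance
    label element  ref distance  ref2 angle
    label element  ref distance  ref2 angle  a,b,c,d torsion
    label element  MIRROR source PLANE a,b,c

where the torsion field names all four atoms of the dihedral (the placed
atom first or last; improper references allowed) so that printed parameter
tables can be transcribed verbatim.  Lines starting with ``#`` are comments.
Writing then reading a structure is lossless at 10 significant digits and a
second write is byte-identical (one-pass normalization).
"""

from __future__ import annotations

import json

import numpy as np

from .geometry import (
    Atom,
    CartesianGeometry,
    MirrorPlacement,
    Placement,
    StructureDefinition,
)

__all__ = [
    "read_xyz", "write_xyz",
    "read_zmat", "write_zmat",
    "structure_to_dict", "structure_from_dict",
    "read_structure_json", "write_structure_json",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path) -> CartesianGeometry:
    """Standard XYZ: count line, comment line, then ``element x y z`` rows."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty or missing count line")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed count line {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise FormatError(f"{path}: expected {n} atom records, file too short")
    elements, coords = [], []
    for i, line in enumerate(lines[2:2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed record on line {i + 3}: {line!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    counts: dict[str, int] = {}
    labels = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        labels.append(f"{el}{counts[el]}")
    masses = [Atom(lab, el).mass for lab, el in zip(labels, elements)]
    return CartesianGeometry(labels, elements, np.array(coords), np.array(masses))


def write_xyz(geom: CartesianGeometry, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(geom.labels)}\n{comment}\n")
        for el, xyz in zip(geom.elements, geom.coords):
            fh.write(f"{el:<3s} {xyz[0]:>17.10g} {xyz[1]:>17.10g} {xyz[2]:>17.10g}\n")


# ---------------------------------------------------------------------------
# internal-coordinate dialect

def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def write_zmat(spec: StructureDefinition, path) -> None:
    amap = spec.atom_map()
    lines = []
    first = spec.atoms[0]
    lines.append(f"{first.label} {first.element}")
    for pl in spec.placements:
        el = amap[pl.atom].element
        if isinstance(pl, MirrorPlacement):
            lines.append(f"{pl.atom} {el}  MIRROR {pl.source} "
                         f"PLANE {','.join(pl.plane)}")
            continue
        parts = [f"{pl.atom} {el}", f"{pl.distance_ref} {_fmt(pl.distance)}"]
        if pl.angle is not None:
            parts.append(f"{pl.angle_ref} {_fmt(pl.angle)}")
        if pl.torsion is not None:
            parts.append(f"{','.join(pl.torsion_atoms)} {_fmt(pl.torsion)}")
        lines.append("  ".join(parts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_zmat(path) -> StructureDefinition:
    atoms: list[Atom] = []
    placements = []
    seen: set[str] = set()
    with open(path) as fh:
        raw = fh.read().splitlines()
    lineno = 0
    for lineno, line in enumerate(raw, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) < 2:
            raise FormatError(f"{path}:{lineno}: malformed line {line!r}")
        label, element = tok[0], tok[1]
        if label in seen:
            raise FormatError(f"{path}:{lineno}: duplicate atom label {label!r}")
        if len(tok) > 2 and tok[2] == "MIRROR":
            if len(tok) != 6 or tok[4] != "PLANE":
                raise FormatError(f"{path}:{lineno}: malformed MIRROR line")
            source, plane = tok[3], tuple(tok[5].split(","))
            for ref in (source, *plane):
                if ref not in seen:
                    raise FormatError(
                        f"{path}:{lineno}: forward reference to {ref!r}")
            placements.append(MirrorPlacement(label, source, plane))
        elif atoms:
            if len(tok) < 4 or len(tok) % 2 != 0:
                raise FormatError(f"{path}:{lineno}: malformed record {line!r}")
            kw = {"atom": label}
            kw["distance_ref"] = tok[2]
            kw["distance"] = float(tok[3])
            refs = [tok[2]]
            if len(tok) >= 6:
                kw["angle_ref"] = tok[4]
                kw["angle"] = float(tok[5])
                refs.append(tok[4])
            if len(tok) >= 8:
                tup = tuple(tok[6].split(","))
                if len(tup) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: torsion needs 4 atoms, got {tok[6]!r}")
                kw["torsion_atoms"] = tup
                kw["torsion"] = float(tok[7])
                refs.extend(a for a in tup if a != label)
            for ref in refs:
                if ref not in seen:
                    raise FormatError(
                        f"{path}:{lineno}: forward reference to {ref!r}")
            placements.append(Placement(**kw))
        seen.add(label)
        atoms.append(Atom(label, element))
    if not atoms:
        raise FormatError(f"{path}: no atoms")
    try:
        return StructureDefinition(atoms, placements)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JSON schema

def structure_to_dict(spec: StructureDefinition) -> dict:
    pls = []
    for pl in spec.placements:
        if isinstance(pl, MirrorPlacement):
            pls.append({"atom": pl.atom, "mirror_source": pl.source,
                        "mirror_plane": list(pl.plane)})
            continue
        d = {"atom": pl.atom, "bond_ref": pl.distance_ref, "bond": pl.distance}
        if pl.angle is not None:
            d.update(angle_ref=pl.angle_ref, angle=pl.angle)
        if pl.torsion is not None:
            d.update(torsion_atoms=list(pl.torsion_atoms), torsion=pl.torsion)
        if pl.names:
            d["names"] = dict(pl.names)
        pls.append(d)
    return {"atoms": [[a.label, a.element, a.mass_number] for a in spec.atoms],
            "placements": pls}


def structure_from_dict(data: dict) -> StructureDefinition:
    atoms = [Atom(*row) for row in data["atoms"]]
    pls = []
    for d in data["placements"]:
        if "mirror_source" in d:
            pls.append(MirrorPlacement(d["atom"], d["mirror_source"],
                                       tuple(d["mirror_plane"])))
            continue
        pls.append(Placement(
            atom=d["atom"], distance_ref=d["bond_ref"], distance=d["bond"],
            angle_ref=d.get("angle_ref"), angle=d.get("angle"),
            torsion_atoms=tuple(d["torsion_atoms"]) if "torsion_atoms" in d else None,
            torsion=d.get("torsion"), names=d.get("names", {})))
    return StructureDefinition(atoms, pls)


def read_structure_json(path) -> StructureDefinition:
    with open(path) as fh:
        return structure_from_dict(json.load(fh))


def write_structure_json(spec: StructureDefinition, path) -> None:
    with open(path, "w") as fh:
        json.dump(structure_to_dict(spec), fh, indent=1)
        fh.write("\n")
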