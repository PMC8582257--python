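"""Physical constants and the bundled atomic-mass table.

The rotational constant of a rigid rotor about principal axis alpha is
``B_alpha = K / I_alpha`` with ``I_alpha`` in amu * Angstrom**2 and
``B_alpha`` in MHz.  ``K = h / (8 pi**2)`` expressed in those units is
derived here from CODATA fundamental constants (via :mod:`scipy.constants`)
rather than typed in, so it carries full double precision.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import scipy.constants as _sc

#: h / (8 pi^2) in MHz * amu * Angstrom^2  (~5.05379e5)
ROTATIONAL_K = _sc.h / (8.0 * _sc.pi**2 * _sc.atomic_mass * 1e-20) / 1e6


@lru_cache(maxsize=1)
def mass_table() -> dict:
    """Bundled isotopic masses (unified amu) keyed by element symbol.

    Each entry carries the mass number of the most abundant isotope
    (``default``) and a map of mass number -> atomic mass.
    """
    with resources.files("nanolego.data").joinpath("atomic_masses.json").open() as fh:
        return json.load(fh)


def isotope_mass(element: str, mass_number: int | None = None) -> float:
    """Mass in amu of ``element``; most abundant isotope if unspecified."""
    table = mass_table()
    if element not in table:
        raise KeyError(f"element {element!r} not in bundled mass table")
    entry = table[element]
    if mass_number is None:
        mass_number = entry["default"]
    key = str(mass_number)
    if key not in entry["isotopes"]:
        raise KeyError(f"no bundled mass for {element}-{mass_number}")
    return entry["isotopes"][key]
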