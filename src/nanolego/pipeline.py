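"""End-to-end structure correction and rotational-constant prediction.

Workflow: dissect a target structure into fragments, correct each fragment's
parameters by template transfer (TMA), correct the remaining inter-fragment
bonds/angles by linear regression (LRA), rebuild Cartesians, compute
equilibrium rotational constants, add externally supplied vibrational
contributions, and score the predicted ground-state constants against
experiment as a mean absolute percentage deviation (MAD%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .corrections import (
    CorrectionReport,
    LRARegistry,
    TemplateMapping,
    correct_structure_lra,
    correct_structure_tma,
)
from .geometry import StructureDefinition, build_cartesian, rotational_constants

__all__ = [
    "FragmentAssignment",
    "PredictionRecord",
    "run_nanolego",
    "ground_state_prediction",
    "mad_percent",
    "report",
]


@dataclass
class FragmentAssignment:
    """Partition of a structure's bonds/angles into template fragments.

    ``fragments`` maps fragment id -> list of parameter names; each fragment
    has a template molecule id in ``templates``.  Parameters assigned to no
    fragment are "leftover" (inter-fragment) and handled by LRA.
    """

    fragments: dict  # fragment id -> list of parameter names
    templates: dict  # fragment id -> template molecule id

    def validate(self, spec: StructureDefinition) -> None:
        seen: dict[str, str] = {}
        names = {name for name, kind, *_ in spec.coordinates()
                 if kind in ("distance", "angle")}
        for fid, params in self.fragments.items():
            if fid not in self.templates:
                raise ValueError(f"fragment {fid!r} has no template")
            for prm in params:
                if prm in seen:
                    raise ValueError(
                        f"parameter {prm!r} assigned to both {seen[prm]!r} and {fid!r}")
                if prm not in names:
                    raise ValueError(f"parameter {prm!r} not a bond/angle of the structure")
                seen[prm] = fid

    def mapping(self, coord_map: dict) -> TemplateMapping:
        """Flatten to a TemplateMapping given parameter -> template coord names."""
        pairs = {}
        for fid, params in self.fragments.items():
            for prm in params:
                pairs[prm] = (self.templates[fid], coord_map.get(prm, prm))
        return TemplateMapping(pairs)


def run_nanolego(spec: StructureDefinition, assignment: FragmentAssignment | None,
                 template_library: dict, registry: LRARegistry, level_tag: str,
                 coord_map: dict | None = None, se_tag: str = "SE"
                 ) -> tuple[StructureDefinition, CorrectionReport]:
    """Fragment parameters by TMA, leftovers by LRA, torsions untouched."""
    if assignment is None or not assignment.fragments:
        return correct_structure_lra(spec, registry, level_tag)
    assignment.validate(spec)
    mapping = assignment.mapping(coord_map or {})
    return correct_structure_tma(spec, mapping, template_library, level_tag,
                                 lra_fallback=registry, se_tag=se_tag)


@dataclass
class PredictionRecord:
    """Per-axis equilibrium constants, vibrational contributions, ground-state
    predictions and (optionally) the comparison with experiment."""

    equilibrium: dict  # axis -> MHz
    dvib: dict
    ground_state: dict
    experimental: dict | None = None
    percent_deviation: dict | None = None
    mad_percent: float | None = None

    def to_dict(self):
        return asdict(self)


def ground_state_prediction(spec: StructureDefinition, dvib: dict,
                            experimental: dict | None = None) -> PredictionRecord:
    """Equilibrium constants of the built structure plus dvib per axis.

    ``dvib`` follows the convention dB^vib = B^0 - B^e, so the ground-state
    prediction is ``B^e + dvib`` (the usual printed contributions are
    negative).  Keys may be upper or lower case axis letters.
    """
    dv = {k.upper(): float(v) for k, v in dvib.items()}
    if set(dv) != {"A", "B", "C"}:
        raise ValueError("dvib must provide the three axes A, B, C")
    rc = rotational_constants(build_cartesian(spec))
    eq = dict(zip("ABC", rc.constants()))
    gs = {ax: eq[ax] + dv[ax] for ax in "ABC"}
    rec = PredictionRecord(equilibrium=eq, dvib=dv, ground_state=gs)
    if experimental is not None:
        exp = {k.upper(): float(v) for k, v in experimental.items()}
        rec.experimental = exp
        rec.percent_deviation = {
            ax: 100.0 * (gs[ax] - exp[ax]) / exp[ax] for ax in "ABC"}
        rec.mad_percent = mad_percent([gs[ax] for ax in "ABC"],
                                      [exp[ax] for ax in "ABC"])
    return rec


def mad_percent(calc, exp) -> float:
    """Mean over axes of 100 |calc - exp| / exp, rounded to two decimals."""
    calc = np.asarray(calc, float)
    exp = np.asarray(exp, float)
    if np.any(exp <= 0):
        raise ValueError("experimental constants must be positive")
    return round(float(np.mean(100.0 * np.abs(calc - exp) / exp)), 2)


def report(corrected: StructureDefinition, record: PredictionRecord | None,
           correction_report: CorrectionReport) -> dict:
    """Machine-readable run report (json.dumps-able)."""
    params = []
    rep = correction_report.by_name()
    for name, kind, atoms, value, _, _ in corrected.coordinates():
        entry = rep.get(name)
        params.append({
            "name": name, "kind": kind, "value": value,
            "original": entry.original if entry else value,
            "method": entry.method if entry else "none",
            "detail": entry.detail if entry else "",
            "flags": entry.flags if entry else [],
        })
    out = {
        "convention": "corrected = optimized + (A*optimized + B); "
                      "template: corrected = optimized + (SE(tm) - opt(tm)); "
                      "torsions never corrected",
        "parameters": params,
        "correction_counts": correction_report.counts(),
    }
    if record is not None:
        out["constants"] = record.to_dict()
    return out


def format_report(rep: dict) -> str:
    """Human-readable rendering of a report() dict."""
    lines = ["nano-LEGO correction report",
             f"convention: {rep['convention']}", "-" * 64,
             f"{'parameter':<16s}{'kind':<10s}{'original':>12s}{'corrected':>12s}  method"]
    for p in rep["parameters"]:
        prec = 4 if p["kind"] == "distance" else 2
        flag = f"  [{'; '.join(p['flags'])}]" if p["flags"] else ""
        lines.append(f"{p['name']:<16s}{p['kind']:<10s}"
                     f"{p['original']:>12.{prec}f}{p['value']:>12.{prec}f}  "
                     f"{p['method']}{p['detail'] and ' (' + p['detail'] + ')'}{flag}")
    if "constants" in rep:
        c = rep["constants"]
        lines.append("-" * 64)
        lines.append(f"{'axis':<6s}{'B_e (MHz)':>14s}{'dvib':>10s}{'B_0 pred':>14s}"
                     + (f"{'B_0 exp':>14s}{'dev %':>8s}" if c.get("experimental") else ""))
        for ax in "ABC":
            row = (f"{ax:<6s}{c['equilibrium'][ax]:>14.3f}{c['dvib'][ax]:>10.3f}"
                   f"{c['ground_state'][ax]:>14.3f}")
            if c.get("experimental"):
                row += (f"{c['experimental'][ax]:>14.3f}"
                        f"{c['percent_deviation'][ax]:>8.2f}")
            lines.append(row)
        if c.get("mad_percent") is not None:
            lines.append(f"MAD% = {c['mad_percent']:.2f}")
    return "\n".join(lines)


def dump_report(rep: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(rep, fh, indent=1, sort_keys=True)
        fh.write("\n")
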