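"""Linear-regression (LRA) and template-molecule (TMA) corrections.

Both schemes correct systematic errors of DFT-optimized internal coordinates
towards semi-experimental quality:

* TMA transfers the offset of a chemically similar template fragment whose
  semi-experimental geometry is known::

      r_corr = r_opt(target) + [r_se(template) - r_opt(template)]

* LRA replaces the template offset by a per-parameter-class linear model
  fitted over a database of (optimized, semi-experimental) pairs::

      r_corr = r_opt + (A * r_opt + B)

  The bundled registry carries the published A/B parameters and residual
  statistics for two model chemistries (a double-hybrid and a hybrid
  functional, tags ``rev-DSDPBEP86`` and ``PW6B95``) for bond classes
  CC, CH, CO, CN, CS, CF, CCl, NH, OH and angle classes CCH, HCH, OCO,
  HCN, COH.

Torsions are never corrected (no reliable linear model exists for them);
parameters whose class is not in the registry are left unchanged and
flagged, never extrapolated across element classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from scipy import stats

from .geometry import InternalCoordinate, StructureDefinition

__all__ = [
    "LRAKey",
    "LRAEntry",
    "LRARegistry",
    "TemplateMapping",
    "CorrectionReport",
    "bundled_registry",
    "apply_lra_value",
    "lookup_lra",
    "correct_structure_lra",
    "apply_tma_value",
    "correct_structure_tma",
    "fit_lra_parameters",
]


@dataclass(frozen=True)
class LRAKey:
    """Canonical (parameter class, level of theory) key.

    Bonds are unordered element pairs; angles are (end, vertex, end) with the
    ends unordered but the vertex kept distinct, so that e.g. C-O-H and
    O-C-H parameterizations never alias.
    """

    kind: str  # "bond" | "angle"
    elements: tuple[str, ...]
    level_tag: str

    @staticmethod
    def bond(e1: str, e2: str, level_tag: str) -> "LRAKey":
        return LRAKey("bond", tuple(sorted((e1, e2))), level_tag)

    @staticmethod
    def angle(end1: str, vertex: str, end2: str, level_tag: str) -> "LRAKey":
        lo, hi = sorted((end1, end2))
        return LRAKey("angle", (lo, vertex, hi), level_tag)

    @property
    def label(self) -> str:
        return "".join(self.elements)


@dataclass(frozen=True)
class LRAEntry:
    """Slope/intercept of one linear correction plus residual statistics."""

    A: float
    B: float
    n_points: int | None = None
    md: float | None = None
    mad: float | None = None
    neg: float | None = None
    pos: float | None = None
    A_stderr: float | None = None
    B_stderr: float | None = None
    A_ci95: tuple[float, float] | None = None
    B_ci95: tuple[float, float] | None = None
    intercept_fixed: bool = False


class LRARegistry:
    """Deterministic lookup table LRAKey -> LRAEntry."""

    def __init__(self, entries: dict[LRAKey, LRAEntry] | None = None):
        self._entries = dict(entries or {})

    def add(self, key: LRAKey, entry: LRAEntry) -> None:
        self._entries[key] = entry

    def get(self, key: LRAKey) -> LRAEntry | None:
        return self._entries.get(key)

    def __len__(self):
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.items())

    @property
    def level_tags(self) -> set[str]:
        return {k.level_tag for k in self._entries}

    @classmethod
    def from_records(cls, records: list[dict]) -> "LRARegistry":
        reg = cls()
        for rec in records:
            els = rec["elements"]
            if rec["kind"] == "bond":
                key = LRAKey.bond(els[0], els[1], rec["level_tag"])
            else:
                key = LRAKey.angle(els[0], els[1], els[2], rec["level_tag"])
            reg.add(key, LRAEntry(
                A=rec["A"], B=rec["B"], n_points=rec.get("n"),
                md=rec.get("md"), mad=rec.get("mad"),
                neg=rec.get("neg"), pos=rec.get("pos"),
                intercept_fixed=bool(rec.get("intercept_fixed", False))))
        return reg

    @classmethod
    def from_json(cls, path) -> "LRARegistry":
        with open(path) as fh:
            return cls.from_records(json.load(fh)["entries"])


def bundled_registry() -> LRARegistry:
    """The published LRA parameter table for both bundled level tags."""
    with resources.files("nanolego.data").joinpath("lra_table.json").open() as fh:
        return LRARegistry.from_records(json.load(fh)["entries"])


# ---------------------------------------------------------------------------
# application

def apply_lra_value(r_opt: float, entry: LRAEntry) -> float:
    """Correct one optimized value: r_opt + (A * r_opt + B)."""
    return r_opt + (entry.A * r_opt + entry.B)


def lookup_lra(registry: LRARegistry, coord: InternalCoordinate,
               elements: tuple[str, ...], level_tag: str) -> LRAEntry | None:
    """Exact canonical-key lookup; ``None`` (never a fallback) when absent."""
    if coord.kind == "distance":
        key = LRAKey.bond(elements[0], elements[1], level_tag)
    elif coord.kind == "angle":
        key = LRAKey.angle(elements[0], elements[1], elements[2], level_tag)
    else:
        return None
    return registry.get(key)


@dataclass
class ParameterCorrection:
    name: str
    kind: str
    original: float
    corrected: float
    method: str  # "LRA" | "TMA" | "none"
    detail: str = ""
    flags: list = field(default_factory=list)


@dataclass
class CorrectionReport:
    """Per-parameter provenance of a corrected structure."""

    entries: list[ParameterCorrection]

    def by_name(self) -> dict[str, ParameterCorrection]:
        return {e.name: e for e in self.entries}

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.method] = out.get(e.method, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {"entries": [asdict(e) for e in self.entries],
                "counts": self.counts()}


def _element_tuple(spec: StructureDefinition, atoms: tuple[str, ...]):
    amap = spec.atom_map()
    return tuple(amap[a].element for a in atoms)


def correct_structure_lra(spec: StructureDefinition, registry: LRARegistry,
                          level_tag: str
                          ) -> tuple[StructureDefinition, CorrectionReport]:
    """LRA-correct every bond and angle with a registry entry.

    Torsions are never touched; parameters without an entry are left
    unchanged and flagged ``uncorrected: no parameterization``.
    """
    updates: dict[str, float] = {}
    entries: list[ParameterCorrection] = []
    for name, kind, atoms, value, _, _ in spec.coordinates():
        if kind == "torsion":
            entries.append(ParameterCorrection(
                name, kind, value, value, "none",
                flags=["torsions are never LRA-corrected"]))
            continue
        coord = InternalCoordinate(kind, atoms)
        els = _element_tuple(spec, atoms)
        # angle atoms are stored (end, vertex, end)... geometry yields
        # (angle_ref, vertex=distance_ref, placed)
        entry = lookup_lra(registry, coord, els, level_tag)
        if entry is None:
            entries.append(ParameterCorrection(
                name, kind, value, value, "none",
                flags=["uncorrected: no parameterization"]))
            continue
        corrected = apply_lra_value(value, entry)
        key_label = "".join(els)
        updates[name] = corrected
        entries.append(ParameterCorrection(
            name, kind, value, corrected, "LRA",
            detail=f"{key_label}@{level_tag}"))
    return spec.with_values(updates), CorrectionReport(entries)


def apply_tma_value(r_opt_target: float, r_opt_template: float,
                    r_se_template: float) -> float:
    """Transfer the template's SE-minus-optimized offset onto the target."""
    return r_opt_target + (r_se_template - r_opt_template)


@dataclass
class TemplateMapping:
    """target parameter name -> (template id, template parameter name)."""

    pairs: dict[str, tuple[str, str]]

    @classmethod
    def from_json(cls, path) -> "TemplateMapping":
        with open(path) as fh:
            data = json.load(fh)
        return cls({d["target"]: (d["template_id"], d["template_coord"])
                    for d in data})


def correct_structure_tma(spec: StructureDefinition, mapping: TemplateMapping,
                          template_library: dict, level_tag: str,
                          lra_fallback: LRARegistry | None = None,
                          se_tag: str = "SE"
                          ) -> tuple[StructureDefinition, CorrectionReport]:
    """TMA-correct mapped parameters; LRA the unmapped bonds/angles.

    ``template_library`` maps template id -> {level tag -> {param: value}};
    each template must provide the parameter both at ``level_tag``
    (optimized) and at ``se_tag`` (semi-experimental).
    """
    updates: dict[str, float] = {}
    entries: list[ParameterCorrection] = []
    for name, kind, atoms, value, _, _ in spec.coordinates():
        if kind == "torsion":
            entries.append(ParameterCorrection(
                name, kind, value, value, "none",
                flags=["torsions are never corrected"]))
            continue
        if name in mapping.pairs:
            tmpl_id, tmpl_coord = mapping.pairs[name]
            try:
                tmpl = template_library[tmpl_id]
                r_opt_t = tmpl[level_tag][tmpl_coord]
                r_se_t = tmpl[se_tag][tmpl_coord]
            except KeyError as exc:
                raise KeyError(
                    f"template parameter {tmpl_id}/{tmpl_coord} missing at "
                    f"{level_tag!r} or {se_tag!r}") from exc
            corrected = apply_tma_value(value, r_opt_t, r_se_t)
            updates[name] = corrected
            entries.append(ParameterCorrection(
                name, kind, value, corrected, "TMA",
                detail=f"{tmpl_id}:{tmpl_coord}"))
            continue
        if lra_fallback is not None:
            coord = InternalCoordinate(kind, atoms)
            entry = lookup_lra(lra_fallback, coord,
                               _element_tuple(spec, atoms), level_tag)
            if entry is not None:
                corrected = apply_lra_value(value, entry)
                updates[name] = corrected
                entries.append(ParameterCorrection(
                    name, kind, value, corrected, "LRA",
                    detail=f"{''.join(_element_tuple(spec, atoms))}@{level_tag}"))
                continue
        entries.append(ParameterCorrection(
            name, kind, value, value, "none",
            flags=["uncorrected: no template mapping or parameterization"]))
    return spec.with_values(updates), CorrectionReport(entries)


# ---------------------------------------------------------------------------
# fitting

def fit_lra_parameters(pairs, fix_intercept: bool = False) -> LRAEntry:
    """Fit the linear correction by OLS of (r_se - r_opt) on r_opt.

    With ``fix_intercept`` the model is forced through B = 0 and A minimizes
    the squared residuals.  Returns slope/intercept with standard errors and
    two-sided 95% confidence intervals, plus the residual statistics (mean
    deviation, mean absolute deviation, extreme errors) of the corrected
    values against the reference values.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): columns r_opt, r_se")
    n = arr.shape[0]
    min_n = 1 if fix_intercept else 2
    if n < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    x, y = arr[:, 0], arr[:, 1]
    d = y - x
    if fix_intercept:
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise ValueError("degenerate design: all r_opt zero")
        A = float(np.dot(x, d) / sxx)
        B = 0.0
        dof = n - 1
        resid = d - A * x
        s2 = float(np.dot(resid, resid)) / dof if dof > 0 else float("nan")
        A_se = math.sqrt(s2 / sxx) if dof > 0 else None
        B_se = None
    else:
        if np.ptp(x) == 0.0:
            raise ValueError("degenerate design: all r_opt equal with free intercept")
        X = np.column_stack([x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        A, B = (float(c) for c in coef)
        dof = n - 2
        resid = d - (A * x + B)
        if dof > 0:
            s2 = float(np.dot(resid, resid)) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            A_se, B_se = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        else:
            A_se = B_se = None
    corrected = x + (A * x + B)
    err = corrected - y
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
    return LRAEntry(
        A=A, B=B, n_points=n,
        md=float(np.mean(err)), mad=float(np.mean(np.abs(err))),
        neg=float(np.min(err)), pos=float(np.max(err)),
        A_stderr=A_se, B_stderr=B_se,
        A_ci95=(A - tcrit * A_se, A + tcrit * A_se) if A_se is not None else None,
        B_ci95=(B - tcrit * B_se, B + tcrit * B_se) if B_se is not None else None,
        intercept_fixed=fix_intercept,
    )
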