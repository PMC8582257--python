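"""Semi-experimental rotational constants and structural refinement.

The semi-experimental (SE) equilibrium constant of isotopologue *i* about
principal axis alpha is obtained from the measured ground-state constant by
removing the computed vibrational contribution::

    B_alpha^SE = B_alpha^0 - dB_alpha^vib        (dB^vib := B^0 - B^e)

Structural parameters are then refined by weighted nonlinear least squares
over a set of isotopologues.  Residuals are formed in inertia-moment space
(amu A^2) by default, which is how fit quality is conventionally quoted;
rotational-constant space (MHz) is available as an option.  Theoretical
parameter values can be added as *predicate observations* (mixed regression):
extra residuals ``(p - p_target)/sigma_p`` that stabilize otherwise
under-determined fits.

The estimator follows the statsmodels convention: build a
:class:`StructureFit` model from data, call :meth:`StructureFit.fit`, and
read estimates, standard errors, correlations and diagnostics off the
returned :class:`StructureFitResults` (``summary()`` prints a table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ROTATIONAL_K
from .geometry import (
    StructureDefinition,
    build_cartesian,
    isotopologue_masses,
    rotational_constants,
)

__all__ = [
    "GroundStateConstant",
    "VibrationalCorrection",
    "SEConstant",
    "se_constant",
    "IsotopologueObservation",
    "Predicate",
    "down_weight",
    "predict_observables",
    "StructureFit",
    "StructureFitResults",
    "fit_structure",
]

_AXES = ("a", "b", "c")


@dataclass(frozen=True)
class GroundStateConstant:
    axis: str
    value: float  # MHz
    uncertainty: float = 0.0

    def __post_init__(self):
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}")
        if self.value <= 0:
            raise ValueError("ground-state constant must be positive")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass(frozen=True)
class VibrationalCorrection:
    """dB^vib = B^0 - B^e per axis, MHz."""

    axis: str
    value: float

    def __post_init__(self):
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}")
        if not math.isfinite(self.value):
            raise ValueError("vibrational correction must be finite")


@dataclass(frozen=True)
class SEConstant:
    axis: str
    value: float  # MHz
    uncertainty: float = 0.0


def se_constant(b0: GroundStateConstant, dv: VibrationalCorrection) -> SEConstant:
    """B^SE = B^0 - dB^vib, with the B^0 uncertainty propagated unchanged."""
    if b0.axis != dv.axis:
        raise ValueError(f"axis mismatch: {b0.axis!r} vs {dv.axis!r}")
    return SEConstant(b0.axis, b0.value - dv.value, b0.uncertainty)


@dataclass
class IsotopologueObservation:
    """SE constants of one isotopologue with per-axis weights.

    ``weights`` multiply the statistical weight of an axis; setting an axis
    weight to 0 (or omitting the axis from ``constants``) drops it, which is
    how fits that use e.g. only the B and C constants are expressed.
    """

    id: str
    overrides: dict = field(default_factory=dict)  # atom label -> mass number
    constants: dict = field(default_factory=dict)  # axis -> SEConstant
    weights: dict = field(default_factory=dict)  # axis -> multiplier

    def __post_init__(self):
        retained = [ax for ax in self.constants
                    if self.weights.get(ax, 1.0) > 0.0]
        if not retained:
            raise ValueError(f"isotopologue {self.id!r} retains no axis")

    def retained_axes(self) -> list[str]:
        return [ax for ax in _AXES
                if ax in self.constants and self.weights.get(ax, 1.0) > 0.0]


def down_weight(observations, iso_id: str, factor: float):
    """Scale one isotopologue's uncertainties up by ``factor``.

    The statistical weight of each retained axis drops by ``factor**2``;
    ``factor -> inf`` removes the isotopologue from the fit.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if not any(o.id == iso_id for o in observations):
        raise KeyError(f"unknown isotopologue id {iso_id!r}")
    out = []
    for o in observations:
        if o.id == iso_id:
            w = {ax: o.weights.get(ax, 1.0) / factor**2
                 for ax in o.constants}
            out.append(replace(o, weights=w))
        else:
            out.append(o)
    return out


@dataclass(frozen=True)
class Predicate:
    """Theoretical parameter value used as an observation with weight 1/sigma^2."""

    parameter: str
    value: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("predicate sigma must be positive")


def predict_observables(spec: StructureDefinition, observations):
    """Forward model: per-isotopologue constants and moments.

    The Cartesian geometry is built once (it is isotope-independent) and the
    mass-dependent inertial analysis is repeated per isotopologue.  Returns
    ``{iso id: {axis: (constant MHz, moment amu A^2)}}`` over retained axes.
    """
    geom = build_cartesian(spec)
    out = {}
    for obs in observations:
        masses = isotopologue_masses(spec, obs.overrides)
        rc = rotational_constants(geom, masses)
        vals = dict(zip(_AXES, zip(rc.constants(), rc.moments())))
        out[obs.id] = {ax: vals[ax] for ax in obs.retained_axes()}
    return out


# ---------------------------------------------------------------------------
# the model

class StructureFit:
    """Weighted nonlinear least-squares refinement of internal coordinates.

    Parameters
    ----------
    structure : StructureDefinition
        Initial guess; its named coordinates are the parameter space.
    observations : list of IsotopologueObservation
    free : list of parameter names to refine.  Every other coordinate is
        held fixed at its value in ``structure``.
    predicates : optional list of Predicate on free parameters.
    residual_space : "moments" (default, amu A^2) or "constants" (MHz).
    """

    def __init__(self, structure: StructureDefinition, observations,
                 free, predicates=(), residual_space: str = "moments"):
        if residual_space not in ("moments", "constants"):
            raise ValueError("residual_space must be 'moments' or 'constants'")
        self.structure = structure
        self.observations = list(observations)
        self.free = list(free)
        self.predicates = list(predicates)
        self.residual_space = residual_space

        values = structure.values()
        unknown = [p for p in self.free if p not in values]
        if unknown:
            raise ValueError(f"free parameters not in structure: {unknown}")
        if len(set(self.free)) != len(self.free):
            raise ValueError("duplicate free parameter")
        for p in self.predicates:
            if p.parameter not in values:
                raise ValueError(f"predicate on unknown parameter {p.parameter!r}")
        self._kinds = {name: kind for name, kind, *_ in structure.coordinates()}
        self.n_obs = sum(len(o.retained_axes()) for o in self.observations) \
            + len(self.predicates)
        if self.n_obs < len(self.free):
            raise ValueError(
                f"{self.n_obs} effective observations for {len(self.free)} "
                "free parameters: underdetermined")

    # residual bookkeeping -------------------------------------------------
    def _targets(self):
        """Per-row (weight^0.5 factor, observed value) and moment weights."""
        rows = []
        for obs in self.observations:
            for ax in obs.retained_axes():
                se = obs.constants[ax]
                wmult = obs.weights.get(ax, 1.0)
                if self.residual_space == "moments":
                    observed = ROTATIONAL_K / se.value
                    # sigma_I = K sigma_B / B^2
                    sig = ROTATIONAL_K * se.uncertainty / se.value**2 \
                        if se.uncertainty > 0 else 1.0
                else:
                    observed = se.value
                    sig = se.uncertainty if se.uncertainty > 0 else 1.0
                rows.append((obs, ax, observed, math.sqrt(wmult) / sig, wmult / sig**2))
        return rows

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        spec = self.structure.with_values(dict(zip(self.free, x)))
        geom = build_cartesian(spec)
        res = []
        ax_index = {ax: i for i, ax in enumerate(_AXES)}
        for obs, ax, observed, sqw, _ in self._rows:
            masses = isotopologue_masses(spec, obs.overrides)
            rc = rotational_constants(geom, masses)
            calc = rc.moments()[ax_index[ax]] if self.residual_space == "moments" \
                else rc.constants()[ax_index[ax]]
            res.append(sqw * (observed - calc))
        vals = dict(zip(self.free, x))
        for p in self.predicates:
            res.append((vals[p.parameter] - p.value) / p.sigma)
        return np.array(res)

    def _residuals_cached_masses(self, x):
        # same as _residuals but reuses per-isotopologue mass vectors
        spec = self.structure.with_values(dict(zip(self.free, x)))
        geom = build_cartesian(spec)
        res = []
        ax_index = {ax: i for i, ax in enumerate(_AXES)}
        rc_cache = {}
        for obs, ax, observed, sqw, _ in self._rows:
            if obs.id not in rc_cache:
                rc_cache[obs.id] = rotational_constants(geom, self._masses[obs.id])
            rc = rc_cache[obs.id]
            calc = rc.moments()[ax_index[ax]] if self.residual_space == "moments" \
                else rc.constants()[ax_index[ax]]
            res.append(sqw * (observed - calc))
        vals = dict(zip(self.free, x))
        for p in self.predicates:
            res.append((vals[p.parameter] - p.value) / p.sigma)
        return np.array(res)

    def _fd_steps(self, x: np.ndarray) -> np.ndarray:
        steps = np.empty_like(x)
        for i, name in enumerate(self.free):
            floor = 1e-6 if self._kinds[name] == "distance" else 1e-5
            steps[i] = max(1e-6 * abs(x[i]), floor)
        return steps

    def fit(self, maxiter: int = 100, lam0: float = 1e-3,
            ftol: float = 1e-12, xtol: float = 1e-10) -> "StructureFitResults":
        """Damped Gauss-Newton (Levenberg) iteration with numerical Jacobian.

        Convergence when the relative objective decrease falls below ``ftol``
        or the step norm below ``xtol``.
        """
        self._rows = self._targets()
        self._masses = {o.id: isotopologue_masses(self.structure, o.overrides)
                        for o in self.observations}
        x = np.array([self.structure.values()[p] for p in self.free], float)
        r = self._residuals_cached_masses(x)
        cost = float(r @ r)
        lam = lam0
        converged = False
        message = "maximum iterations reached"
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            J = self._jacobian(x)
            g = J.T @ r
            JTJ = J.T @ J
            d = np.diag(JTJ).copy()
            d[d <= 0] = 1.0
            step_accepted = False
            for _ in range(30):
                try:
                    delta = np.linalg.solve(JTJ + lam * np.diag(d), -g)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                x_new = x + delta
                try:
                    r_new = self._residuals_cached_masses(x_new)
                except Exception:
                    lam *= 10
                    continue
                cost_new = float(r_new @ r_new)
                if cost_new <= cost:
                    step_accepted = True
                    break
                lam *= 10
            if not step_accepted:
                # at a (local) minimum to within numerical precision
                converged = True
                message = "stalled: no downhill step found"
                break
            rel_decrease = (cost - cost_new) / max(cost, 1e-300)
            step_norm = float(np.linalg.norm(delta))
            x, r, cost = x_new, r_new, cost_new
            lam = max(lam / 10, 1e-12)
            if rel_decrease < ftol or step_norm < xtol:
                converged = True
                message = "converged"
                break
        J = self._jacobian(x)
        return self._build_results(x, r, J, cost, converged, n_iter, message)

    def _jacobian(self, x: np.ndarray) -> np.ndarray:
        steps = self._fd_steps(x)
        r0 = self._residuals_cached_masses(x)
        J = np.empty((r0.size, x.size))
        for i in range(x.size):
            xp = x.copy()
            xp[i] += steps[i]
            J[:, i] = (self._residuals_cached_masses(xp) - r0) / steps[i]
        return J

    def _build_results(self, x, r, J, cost, converged, n_iter, message):
        n, p = self.n_obs, len(self.free)
        dof = max(n - p, 1)
        s2 = cost / dof
        JTJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JTJ)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = cov / np.outer(bse, bse)
            np.fill_diagonal(corr, 1.0)
            rank_deficient = False
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            bse = np.full(p, np.nan)
            corr = np.full((p, p), np.nan)
            rank_deficient = True
        # weighted RMS of the physical (moment/constant) residuals
        phys = r[: n - len(self.predicates)]
        wsum = sum(w for *_, w in self._rows)
        wrms = math.sqrt(float(phys @ phys) / wsum) if wsum > 0 else float("nan")
        refined = self.structure.with_values(dict(zip(self.free, x)))
        return StructureFitResults(
            model=self, params=dict(zip(self.free, x)), bse=dict(zip(self.free, bse)),
            cov=cov, corr=corr, cost=cost, wrms=wrms, dof=dof,
            converged=converged, n_iter=n_iter, message=message,
            rank_deficient=rank_deficient, structure=refined,
        )


@dataclass
class StructureFitResults:
    """Refined parameters, uncertainties and diagnostics of a StructureFit."""

    model: StructureFit
    params: dict
    bse: dict
    cov: np.ndarray
    corr: np.ndarray
    cost: float
    wrms: float  # weighted RMS of the inertial residuals (amu A^2 by default)
    dof: int
    converged: bool
    n_iter: int
    message: str
    rank_deficient: bool
    structure: StructureDefinition

    def summary(self) -> str:
        unit = "amu A^2" if self.model.residual_space == "moments" else "MHz"
        lines = [
            "Semi-experimental structure refinement",
            "=" * 54,
            f"observations (axes + predicates): {self.model.n_obs}",
            f"free parameters:                  {len(self.model.free)}",
            f"iterations: {self.n_iter}   status: {self.message}",
            f"weighted RMS residual: {self.wrms:.3e} {unit}",
            "-" * 54,
            f"{'parameter':<16s} {'initial':>12s} {'refined':>12s} {'std dev':>10s}",
        ]
        init = self.model.structure.values()
        for name in self.model.free:
            lines.append(f"{name:<16s} {init[name]:>12.6f} "
                         f"{self.params[name]:>12.6f} {self.bse[name]:>10.2e}")
        fixed = [n for n in init if n not in self.model.free]
        if fixed:
            lines.append(f"fixed: {len(fixed)} parameters")
        return "\n".join(lines)


def fit_structure(structure, observations, free, predicates=(),
                  residual_space="moments", **fit_kw) -> StructureFitResults:
    """Convenience wrapper: build a StructureFit and fit it."""
    return StructureFit(structure, observations, free, predicates,
                        residual_space).fit(**fit_kw)
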