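"""Species-level calibration of the grayscale-to-modulus conversion factor.

Within a species, specimens are split into a calibration group and a
validation group.  On the calibration group the conversion factor ``alpha``
of the modulus law ``E = alpha * GS`` is found by Brent scalar minimization
of the normalized stiffness RMSE

    rmse = sqrt( mean_i ((k_sim_i - k_exp_i) / k_exp_i)^2 )

between the experimental apparent stiffness of each specimen and the
finite-element stiffness of its model evaluated at the probed ``alpha``.
The converged ``alpha`` is then applied unchanged to the validation group
and its predictive RMSE reported.

When a specimen model contains no fixed-modulus cement (all-bone, or cement
treated as rigid), the simulated stiffness is exactly proportional to
``alpha`` and the optimum has the closed form ``alpha* = sum(r) / sum(r^2)``
with ``r_i = k_unit_i / k_exp_i``; this serves as an independent oracle for
the optimizer and as a fast path for Monte-Carlo studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from vertefem.fe_solver import LoadCase, assemble, solve_compression
from vertefem.image_ops import ImageVolume
from vertefem.meshing import HexMesh, assign_materials

_GOLD = 0.3819660112501051  # 2 - golden ratio, the golden-section fraction


def rmse_normalized(k_exp, k_sim) -> float:
    """Root-mean-square of the per-specimen relative stiffness errors."""
    k_exp = np.asarray(k_exp, dtype=float)
    k_sim = np.asarray(k_sim, dtype=float)
    if k_exp.shape != k_sim.shape or k_exp.ndim != 1 or k_exp.size < 1:
        raise ValueError("k_exp and k_sim must be equal-length non-empty 1-D sequences")
    if np.any(k_exp <= 0):
        raise ValueError("experimental stiffness values must be positive")
    rel = (k_sim - k_exp) / k_exp
    return float(np.sqrt(np.mean(rel**2)))


def closed_form_alpha(k_exp, k_unit) -> float:
    """Analytic minimizer of the normalized RMSE when k_sim = alpha * k_unit.

    With ``r_i = k_unit_i / k_exp_i`` the objective is
    ``sqrt(mean (alpha r_i - 1)^2)``, minimized at
    ``alpha* = sum(r) / sum(r^2)``.
    """
    k_exp = np.asarray(k_exp, dtype=float)
    k_unit = np.asarray(k_unit, dtype=float)
    if k_exp.shape != k_unit.shape or k_exp.size < 1:
        raise ValueError("k_exp and k_unit must be equal-length non-empty sequences")
    if np.any(k_exp <= 0) or np.any(k_unit <= 0):
        raise ValueError("stiffness values must be positive")
    r = k_unit / k_exp
    denom = float(np.sum(r**2))
    if denom == 0:
        raise ZeroDivisionError("degenerate unit stiffnesses")
    return float(np.sum(r)) / denom


@dataclass
class SpecimenRecord:
    """One specimen's model inputs and experimental stiffness.

    Either (``mesh``, ``gray``) for full FE evaluation at each probed
    alpha, or a precomputed ``k_unit`` (stiffness at alpha = 1 for a model
    where K is proportional to alpha) for the fast path.
    """

    id: str
    k_exp: float  # kN/mm
    group: str = "calibration"  # or "validation"
    mesh: HexMesh | None = None
    gray: ImageVolume | None = None
    k_unit: float | None = None
    loadcase: LoadCase = field(default_factory=LoadCase)
    E_cement: float = 2.45
    nu: float = 0.3
    E_floor: float = 0.001

    def __post_init__(self):
        if self.k_exp <= 0:
            raise ValueError(f"specimen {self.id}: experimental stiffness must be positive")
        if self.k_unit is None and (self.mesh is None or self.gray is None):
            raise ValueError(f"specimen {self.id}: need mesh+gray or k_unit")

    def simulated_stiffness(self, alpha: float, cache: dict | None = None) -> float:
        if self.k_unit is not None:
            return alpha * self.k_unit
        key = (self.id, round(float(alpha), 15))
        if cache is not None and key in cache:
            return cache[key]
        mats = assign_materials(
            self.mesh, self.gray, alpha=alpha,
            E_cement=self.E_cement, nu=self.nu, E_floor=self.E_floor,
        )
        # warm-start the iterative solver from the previous probed alpha:
        # the displacement field varies smoothly with the moduli
        res = solve_compression(
            assemble(self.mesh, mats), self.loadcase,
            x0=getattr(self, "_warm_start", None),
        )
        self._warm_start = res.reduced_solution
        k = res.apparent_stiffness
        if cache is not None:
            cache[key] = k
        return k


@dataclass
class CalibrationResult:
    alpha: float  # GPa per grayscale unit
    rmse: float  # dimensionless fraction
    pairs: dict[str, tuple[float, float]]  # id -> (k_exp, k_sim) at alpha
    iterations: int
    termination: str
    trace: list[tuple[float, float]] = field(default_factory=list)  # (alpha, rmse) probes


@dataclass
class ValidationResult:
    alpha: float
    rmse: float
    relative_errors: dict[str, float]  # id -> (k_sim - k_exp) / k_exp
    max_abs_relative_error: float
    pairs: dict[str, tuple[float, float]]


def _brent_bounded(
    func: Callable[[float], float],
    a: float,
    b: float,
    xtol_rel: float,
    rmse_stop: float | None,
    rel_change_stop: float | None,
    max_iter: int,
):
    """Brent's method on [a, b] (golden-section with parabolic acceleration)
    with the calibration's extra stopping rules.

    Returns (x_best, f_best, n_evals, termination_reason).
    """
    x = w = v = a + _GOLD * (b - a)
    fx = fw = fv = func(x)
    nfev = 1
    d = e = 0.0
    termination = "max_iter"
    prev_best = fx
    for _ in range(max_iter):
        xm = 0.5 * (a + b)
        tol1 = xtol_rel * abs(x) + 1e-12
        tol2 = 2.0 * tol1
        if abs(x - xm) <= tol2 - 0.5 * (b - a):
            termination = "xtol"
            break
        if rmse_stop is not None and fx <= rmse_stop:
            termination = "objective_threshold"
            break
        use_golden = True
        if abs(e) > tol1:
            # parabolic fit through (x, w, v)
            r = (x - w) * (fx - fv)
            q = (x - v) * (fx - fw)
            p = (x - v) * q - (x - w) * r
            q = 2.0 * (q - r)
            if q > 0:
                p = -p
            q = abs(q)
            etemp = e
            e = d
            if abs(p) < abs(0.5 * q * etemp) and q * (a - x) < p < q * (b - x):
                d = p / q
                u = x + d
                if (u - a) < tol2 or (b - u) < tol2:
                    d = np.copysign(tol1, xm - x)
                use_golden = False
        if use_golden:
            e = (b if x < xm else a) - x
            d = _GOLD * e
        u = x + (d if abs(d) >= tol1 else np.copysign(tol1, d))
        fu = func(u)
        nfev += 1
        if fu <= fx:
            if u >= x:
                a = x
            else:
                b = x
            v, w, x = w, x, u
            fv, fw, fx = fw, fx, fu
            if rel_change_stop is not None and prev_best > 0:
                if abs(prev_best - fx) <= rel_change_stop * max(fx, 1e-30) and abs(
                    prev_best - fx
                ) > 0:
                    prev_best = fx
                    termination = "objective_variation"
                    break
            prev_best = fx
        else:
            if u < x:
                a = u
            else:
                b = u
            if fu <= fw or w == x:
                v, w = w, u
                fv, fw = fw, fu
            elif fu <= fv or v == x or v == w:
                v, fv = u, fu
    return x, fx, nfev, termination


def calibrate_alpha(
    records: list[SpecimenRecord],
    bracket: tuple[float, float] = (1e-5, 0.1),
    rmse_stop: float | None = None,
    rel_change_stop: float | None = None,
    xtol_rel: float = 1e-5,
    max_iter: int = 200,
    cache: dict | None = None,
) -> CalibrationResult:
    """Brent scalar minimization of the normalized stiffness RMSE over alpha.

    Each objective evaluation runs the compression solve for every
    calibration specimen at the probed alpha (cached per (specimen, alpha)).
    Optional early stops: ``rmse_stop`` halts once the objective falls at or
    below a threshold; ``rel_change_stop`` halts when the best objective's
    relative change between accepted iterates falls below a fraction.  Both
    are off by default so the optimizer converges to the x-tolerance; the
    termination reason is recorded in the result.

    If the optimum lands at a bracket end, the bracket is expanded once
    (a decade outward) before giving up.
    """
    cal = [r for r in records if r.group == "calibration"]
    if not cal:
        raise ValueError("no calibration records")
    if cache is None:
        cache = {}
    k_exp = np.array([r.k_exp for r in cal])
    trace: list[tuple[float, float]] = []

    def objective(alpha: float) -> float:
        k_sim = np.array([r.simulated_stiffness(alpha, cache) for r in cal])
        f = rmse_normalized(k_exp, k_sim)
        trace.append((float(alpha), f))
        return f

    a, b = float(bracket[0]), float(bracket[1])
    if not (0 < a < b):
        raise ValueError("bracket must satisfy 0 < a < b")
    for end in (a, b):
        if not np.isfinite(objective(end)):
            raise ValueError(f"objective not finite at bracket end alpha={end}")

    expanded = False
    while True:
        x, fx, nfev, termination = _brent_bounded(
            objective, a, b, xtol_rel, rmse_stop, rel_change_stop, max_iter
        )
        edge_tol = 2 * (xtol_rel * abs(x) + 1e-12)
        at_edge = (x - a) <= edge_tol or (b - x) <= edge_tol
        if at_edge and termination == "xtol":
            if expanded:
                raise ValueError(
                    f"optimum at bracket end alpha={x:.3g} even after expansion"
                )
            a, b = a / 10.0, b * 10.0
            expanded = True
            continue
        break

    # report the best probed point (Brent keeps it, but the trace is the
    # authoritative record)
    best_alpha, best_f = min(trace, key=lambda t: t[1])
    if best_f < fx:
        x, fx = best_alpha, best_f
    pairs = {
        r.id: (r.k_exp, r.simulated_stiffness(x, cache)) for r in cal
    }
    return CalibrationResult(
        alpha=float(x),
        rmse=float(fx),
        pairs=pairs,
        iterations=len(trace),
        termination=termination,
        trace=trace,
    )


def validate_alpha(
    alpha: float,
    records: list[SpecimenRecord],
    cache: dict | None = None,
) -> ValidationResult:
    """Evaluate a fixed alpha on a validation set.

    Reports the normalized RMSE, the per-specimen relative stiffness errors
    ``(k_sim - k_exp) / k_exp`` and the worst absolute relative error.
    """
    if not records:
        raise ValueError("no validation records")
    if cache is None:
        cache = {}
    pairs = {r.id: (r.k_exp, r.simulated_stiffness(alpha, cache)) for r in records}
    k_exp = np.array([v[0] for v in pairs.values()])
    k_sim = np.array([v[1] for v in pairs.values()])
    rel = (k_sim - k_exp) / k_exp
    return ValidationResult(
        alpha=float(alpha),
        rmse=rmse_normalized(k_exp, k_sim),
        relative_errors={sid: float(e) for sid, e in zip(pairs, rel)},
        max_abs_relative_error=float(np.max(np.abs(rel))),
        pairs=pairs,
    )


def split_records(records: list[SpecimenRecord]):
    """Partition records into (calibration, validation), asserting the two
    groups share no specimen ids."""
    cal = [r for r in records if r.group == "calibration"]
    val = [r for r in records if r.group == "validation"]
    overlap = {r.id for r in cal} & {r.id for r in val}
    if overlap:
        raise ValueError(f"specimens in both groups: {sorted(overlap)}")
    return cal, val
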