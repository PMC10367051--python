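"""Eyring rates and microkinetic simulation of the two-step hydrolysis cascade.

Transition-state theory converts an activation free energy into a first-order
rate constant, k = κ·(k_B·T/h)·exp(−ΔG‡/RT).  The cascade model is this
package's own exploratory construction: the published study reports the
sequential hydrolysis (substrate 8 → intermediate 6 → product 4, with
difluoroacetate released in the second cleavage) and its stall/burst
phenomenology, but defines no rate equations.  The model assumes
rapid-equilibrium competitive binding of 8, 6 and 4 to the free enzyme
(dissociation constants taken from IC₅₀ measurements), first-order chemistry
of the bound species, an optional processive channel (a bound ring-opened
intermediate hydrolyzed before release with probability *p*), and a dead-end
enzyme·4 complex providing product inhibition.  Processivity and product
inhibition are the two switchable hypotheses for the wild-type stall and the
Y745F burst.

Concentrations are µM, times minutes, rate constants s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .constants import K_B, PLANCK, R_KCAL
from .records import TimeCourse, ValidationError

__all__ = [
    "KineticScheme",
    "AssayConditions",
    "FitResult",
    "eyring_rate",
    "inverse_eyring",
    "build_cascade_scheme",
    "simulate_time_course",
    "time_to_fraction",
    "fit_rate_constants",
    "ki_from_ic50",
    "SPECIES",
]

#: Free-ligand species integrated by the cascade ODE.  Difluoroacetate is
#: not tracked: it is released 1:1 with compound 4.
SPECIES = ("cpd8", "cpd6", "cpd4")

#: Default seed for stochastic fitting restarts.
DEFAULT_SEED = 20230703

_RTOL = 1e-8
_ATOL = 1e-10  # µM


def eyring_rate(delta_g_act: float, T: float, kappa: float = 1.0) -> float:
    """TST rate constant k = κ·(k_B·T/h)·exp(−ΔG‡/RT) in s⁻¹."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(kappa * K_B * T / PLANCK * math.exp(-delta_g_act / (R_KCAL * T)))


def inverse_eyring(k: float, T: float, kappa: float = 1.0) -> float:
    """Activation free energy (kcal/mol) reproducing rate *k* at *T*."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(-R_KCAL * T * math.log(k * PLANCK / (kappa * K_B * T)))


@dataclass(frozen=True)
class KineticScheme:
    """Cascade parameters: competitive Kd's (µM), catalytic rates (s⁻¹),
    processivity fraction and temperature."""

    kd8: float
    kd6: float
    kd4: float
    kcat1: float
    kcat2: float
    processivity_p: float = 0.0
    temperature: float = 303.15

    def __post_init__(self) -> None:
        for name in ("kd8", "kd6", "kd4"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0 (µM); use math.inf "
                                      "for a non-binding species")
        if self.kcat1 < 0 or self.kcat2 < 0:
            raise ValidationError("catalytic rate constants must be ≥ 0")
        if not 0.0 <= self.processivity_p <= 1.0:
            raise ValidationError("processivity must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")

    def occupancies(self, c8: float, c6: float, c4: float) -> tuple[float, float, float]:
        """Fractional enzyme occupancies (θ8, θ6, θ4) at the given free
        ligand concentrations, from rapid-equilibrium competitive binding."""
        x8 = c8 / self.kd8
        x6 = c6 / self.kd6
        x4 = c4 / self.kd4
        denom = 1.0 + x8 + x6 + x4
        return x8 / denom, x6 / denom, x4 / denom


@dataclass(frozen=True)
class AssayConditions:
    """Initial substrate and enzyme concentrations (µM) and temperature (K)."""

    s0: float
    e0: float
    T: float = 303.15

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.e0 <= 0:
            raise ValidationError("s0 and e0 must be positive")
        if self.T <= 0:
            raise ValidationError("temperature must be positive")


def build_cascade_scheme(kd8: float, kd6: float, kd4: float,
                         kcat1: float, kcat2: float, p: float = 0.0,
                         T: float = 303.15) -> KineticScheme:
    """Validated cascade scheme.

    Bound substrate converts at *kcat1*; a fraction *p* of conversions
    proceeds processively to the final product without releasing the
    intermediate, the rest (1−p) releases the intermediate, which rebinds
    competitively and converts at *kcat2*.  The final product binds as a
    dead-end complex.  Infinite Kd values switch a species' binding off.
    """
    return KineticScheme(kd8, kd6, kd4, kcat1, kcat2, p, T)


def _rhs(scheme: KineticScheme, e0: float):
    k1 = scheme.kcat1 * 60.0  # s⁻¹ → min⁻¹
    k2 = scheme.kcat2 * 60.0
    p = scheme.processivity_p

    def rhs(t, y):
        c8, c6, c4 = y
        th8, th6, _ = scheme.occupancies(max(c8, 0.0), max(c6, 0.0), max(c4, 0.0))
        v1 = k1 * e0 * th8
        v2 = k2 * e0 * th6
        return (-v1, (1.0 - p) * v1 - v2, p * v1 + v2)

    return rhs


def simulate_time_course(scheme: KineticScheme, cond: AssayConditions,
                         t_grid) -> TimeCourse:
    """Integrate the cascade ODEs on *t_grid* (minutes) with a stiff-safe
    solver; enforces mass balance to 1e-6 µM and non-negativity."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing with ≥ 2 points")
    y0 = (cond.s0, 0.0, 0.0)
    sol = solve_ivp(
        _rhs(scheme, cond.e0), (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        method="LSODA", rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise RuntimeError("cascade integration produced non-finite values")
    balance = np.abs(y.sum(axis=0) - cond.s0)
    if balance.max() > 1e-6:
        raise RuntimeError(
            f"mass balance violated by {balance.max():.3g} µM during integration"
        )
    y = np.clip(y, 0.0, None)
    return TimeCourse(t_grid, dict(zip(SPECIES, y)))


def time_to_fraction(tc: TimeCourse, species: str, fraction_remaining: float):
    """First time (minutes) at which *species* falls to the given fraction of
    its initial value, linearly interpolated; ``None`` if never reached."""
    series = np.asarray(tc.concentrations[species], dtype=float)
    threshold = fraction_remaining * series[0]
    if series[0] <= threshold:
        return float(tc.times[0])
    below = np.nonzero(series <= threshold)[0]
    if below.size == 0:
        return None
    j = int(below[0])
    t0, t1 = tc.times[j - 1], tc.times[j]
    c0, c1 = series[j - 1], series[j]
    if c1 == c0:
        return float(t1)
    return float(t0 + (c0 - threshold) / (c0 - c1) * (t1 - t0))


@dataclass(frozen=True)
class FitResult:
    params: dict[str, float]
    residuals: np.ndarray
    cost: float
    converged: bool
    message: str


_FITTABLE = ("kd8", "kd6", "kd4", "kcat1", "kcat2", "processivity_p")


def fit_rate_constants(tc_observed: TimeCourse, scheme_template: KineticScheme,
                       cond: AssayConditions, free_params,
                       bounds: dict | None = None,
                       seed: int = DEFAULT_SEED) -> FitResult:
    """Least-squares fit of selected scheme parameters to a time course.

    Positive parameters are fitted in log space for scale robustness.  The
    result is deterministic for a given seed and starting point (the
    template values); non-convergence is flagged, never silent.
    """
    free_params = list(free_params)
    for name in free_params:
        if name not in _FITTABLE:
            raise ValidationError(f"unknown fit parameter {name!r}")
    observed = {
        s: np.asarray(v, float)
        for s, v in tc_observed.concentrations.items()
        if s in SPECIES
    }
    if not observed:
        raise ValidationError("observed time course shares no species with the scheme")
    n_data = sum(v.size for v in observed.values())
    if n_data < max(len(free_params), 1):
        raise ValidationError("fewer data points than free parameters")

    t_grid = np.asarray(tc_observed.times, float)
    if t_grid[0] > 0.0:
        t_grid = np.concatenate([[0.0], t_grid])
        skip_first = True
    else:
        skip_first = False

    bounds = bounds or {}
    rng = np.random.default_rng(seed)  # reserved for restart jitter
    del rng

    def pack(scheme: KineticScheme) -> np.ndarray:
        return np.array([math.log10(getattr(scheme, n)) if n != "processivity_p"
                         else getattr(scheme, n) for n in free_params])

    def unpack(x: np.ndarray) -> KineticScheme:
        updates = {}
        for name, val in zip(free_params, x):
            updates[name] = float(val) if name == "processivity_p" else 10.0 ** float(val)
        return replace(scheme_template, **updates)

    def residual(x: np.ndarray) -> np.ndarray:
        scheme = unpack(x)
        sim = simulate_time_course(scheme, cond, t_grid)
        res = []
        for sname, obs in observed.items():
            model = sim.concentrations[sname]
            if skip_first:
                model = model[1:]
            res.append(model - obs)
        return np.concatenate(res)

    if free_params:
        lo, hi = [], []
        for name in free_params:
            b = bounds.get(name, (1e-6, 1e6) if name != "processivity_p" else (0.0, 1.0))
            if name == "processivity_p":
                lo.append(b[0]); hi.append(b[1])
            else:
                lo.append(math.log10(b[0])); hi.append(math.log10(b[1]))
        out = least_squares(residual, pack(scheme_template), bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        fitted = unpack(out.x)
        params = {n: getattr(fitted, n) for n in free_params}
        return FitResult(params, out.fun, float(out.cost), bool(out.success),
                         out.message)
    res = residual(np.empty(0))
    return FitResult({}, res, float(0.5 * res @ res), True,
                     "no free parameters; template residuals reported")


def ki_from_ic50(ic50: float, mode: str = "identity",
                 s: float | None = None, km: float | None = None) -> float:
    """Convert an IC₅₀ (µM) to an inhibition constant Ki (µM).

    ``identity`` returns the IC₅₀ unchanged (substrate near Km in the source
    assays); ``competitive`` applies the Cheng–Prusoff relation
    Ki = IC₅₀ / (1 + S/Km).
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if mode == "identity":
        return float(ic50)
    if mode == "competitive":
        if s is None or km is None or s <= 0 or km <= 0:
            raise ValueError("competitive mode needs positive S and Km")
        return float(ic50 / (1.0 + s / km))
    raise ValueError(f"unknown mode {mode!r}")
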