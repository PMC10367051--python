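"""Ideal-gas quasi-RRHO thermochemistry from frequencies and geometries.

The Gibbs correction assembled here is the standard ideal-gas expression

    G_corr = E_ZPVE + E_thermal + RT − T·S ,

where ``E_thermal`` collects translational, rotational and thermal
vibrational internal energy, ``RT`` is the pV term of the enthalpy and ``S``
the total entropy.  Vibrational entropy uses the quasi-RRHO treatment: below
a crossover wavenumber (default 100 cm⁻¹) the harmonic-oscillator mode
entropy is smoothly replaced by a free-rotor entropy through the damping
function w(ν) = 1/(1 + (ν₀/ν)^α).

Frequency sets are "cleaned" before use: spurious small imaginary modes —
numerical noise of constrained-site frequency calculations — are flipped to
positive values; for a transition state the single genuine reactive
imaginary mode is removed from the thermochemical mode list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import (
    AMU, ATM, C_CM, CM1_TO_KCAL, K_B, MOLAR_VOLUME_298, N_A, PLANCK, R_KCAL,
)
from .records import (
    FrequencySet, MoleculeGeometry, StationaryPointRecord,
    MINIMUM, TRANSITION_STATE, ValidationError,
)

__all__ = [
    "ThermalCorrection",
    "clean_frequencies",
    "zpve",
    "partition_translational",
    "partition_rotational",
    "vibrational_entropy_qrrho",
    "gibbs_correction",
    "standard_state_correction",
]

#: quasi-RRHO defaults: crossover wavenumber (cm⁻¹), damping exponent, and
#: the averaged molecular moment of inertia (kg·m²) blended into the
#: free-rotor effective moment.
NU0_DEFAULT = 100.0
ALPHA_DEFAULT = 4.0
B_AV_DEFAULT = 1.0e-44

_EXP_CAP = 700.0  # beyond this θ/T the Boltzmann factors underflow to 0


@dataclass(frozen=True)
class ThermalCorrection:
    """ZPVE plus thermal/entropic Gibbs correction at one temperature.

    ``g_corr = zpve + g_thermal`` exactly; ``components`` records the
    partition-function pieces that entered the assembly.
    """

    temperature: float
    zpve: float
    g_thermal: float
    components: Mapping[str, float]

    @property
    def g_corr(self) -> float:
        return self.zpve + self.g_thermal


def clean_frequencies(fs: FrequencySet) -> FrequencySet:
    """Flip spurious imaginary modes; drop the reactive mode of a TS.

    For a minimum every negative entry is replaced by its absolute value.
    For a transition state the largest-magnitude imaginary entry is removed
    as the reactive mode and the remaining imaginaries are flipped.  A
    transition-state set without any imaginary entry is invalid.
    """
    wn = list(fs.wavenumbers)
    if fs.role == TRANSITION_STATE:
        imag = [w for w in wn if w < 0]
        if not imag:
            raise ValidationError(
                "transition-state frequency set has no imaginary (reactive) mode"
            )
        wn.remove(min(imag))  # most negative = largest-magnitude imaginary
    cleaned = tuple(abs(w) for w in wn)
    return FrequencySet(cleaned, role=fs.role, cleaned=True)


def _require_cleaned(fs: FrequencySet) -> np.ndarray:
    if not fs.cleaned:
        if fs.n_imaginary:
            raise ValidationError(
                "frequency set contains imaginary modes; apply clean_frequencies first"
            )
        fs = FrequencySet(fs.wavenumbers, role=fs.role, cleaned=True)
    return np.asarray(fs.wavenumbers, dtype=float)


def zpve(fs: FrequencySet) -> float:
    """Zero-point vibrational energy Σ ½hcν̃ in kcal/mol (cleaned set)."""
    wn = _require_cleaned(fs)
    return float(0.5 * CM1_TO_KCAL * wn.sum())


def partition_translational(total_mass: float, T: float,
                            standard_state: str = "1 atm") -> float:
    """Ideal-gas translational partition function q_trans = Λ⁻³·V.

    *total_mass* is in amu; *standard_state* selects the per-molecule volume:
    ``"1 atm"`` uses V = k_B·T/p°, ``"1 M"`` uses one litre per millimole of
    molecules (1 mol/L).
    """
    if total_mass <= 0 or T <= 0:
        raise ValueError("mass and temperature must be positive")
    if standard_state == "1 atm":
        volume = K_B * T / ATM
    elif standard_state == "1 M":
        volume = 1.0e-3 / N_A
    else:
        raise ValueError(f"unknown standard state {standard_state!r}")
    m = total_mass * AMU
    lam3 = (2.0 * math.pi * m * K_B * T / PLANCK**2) ** 1.5
    return float(lam3 * volume)


def _inertia_moments(geom: MoleculeGeometry) -> np.ndarray:
    """Principal moments of inertia in kg·m², ascending."""
    masses = np.asarray(geom.masses) * AMU
    coords = geom.coords * 1.0e-10  # Å → m
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = (masses * (y**2 + z**2)).sum()
    iyy = (masses * (x**2 + z**2)).sum()
    izz = (masses * (x**2 + y**2)).sum()
    ixy = -(masses * x * y).sum()
    ixz = -(masses * x * z).sum()
    iyz = -(masses * y * z).sum()
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def _is_linear(moments: np.ndarray) -> bool:
    return moments[0] < 1.0e-4 * moments[2]


def partition_rotational(geom: MoleculeGeometry, T: float, sigma: int = 1) -> float:
    """Rigid-rotor rotational partition function.

    Uses the classical linear-rotor formula when one principal moment
    vanishes (two equal, one ≈ 0) and the asymmetric-top formula otherwise.
    A single atom has q_rot = 1 by definition; a fully degenerate geometry
    (all atoms coincident) is an error.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if sigma < 1:
        raise ValueError("symmetry number must be a positive integer")
    if geom.n_atoms == 1:
        return 1.0
    moments = _inertia_moments(geom)
    if moments[2] <= 0:
        raise ValidationError("degenerate geometry: all atoms coincide")
    if _is_linear(moments):
        i_b = moments[2]
        return float(8.0 * math.pi**2 * i_b * K_B * T / (sigma * PLANCK**2))
    pref = math.sqrt(math.pi) / sigma
    term = (8.0 * math.pi**2 * K_B * T / PLANCK**2) ** 1.5
    return float(pref * term * math.sqrt(moments[0] * moments[1] * moments[2]))


def _theta_over_t(wn: np.ndarray, T: float) -> np.ndarray:
    theta = PLANCK * C_CM * wn / K_B  # vibrational temperatures, K
    return np.minimum(theta / T, _EXP_CAP)


def _s_harmonic(wn: np.ndarray, T: float) -> np.ndarray:
    """Per-mode harmonic-oscillator entropy, kcal/mol/K."""
    x = _theta_over_t(wn, T)
    with np.errstate(over="ignore"):
        s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return R_KCAL * s


def _s_free_rotor(wn: np.ndarray, T: float, b_av: float) -> np.ndarray:
    """Per-mode free-rotor entropy with the mode-derived effective moment."""
    mu = PLANCK / (8.0 * math.pi**2 * C_CM * wn)
    mu_eff = mu * b_av / (mu + b_av)
    arg = 8.0 * math.pi**3 * mu_eff * K_B * T / PLANCK**2
    return R_KCAL * (0.5 + np.log(np.sqrt(arg)))


def qrrho_weight(wn, nu0: float = NU0_DEFAULT, alpha: float = ALPHA_DEFAULT):
    """Head-Gordon damping function w(ν) = 1/(1 + (ν₀/ν)^α)."""
    wn = np.asarray(wn, dtype=float)
    if nu0 <= 0:
        return np.ones_like(wn)
    return 1.0 / (1.0 + (nu0 / wn) ** alpha)


def vibrational_entropy_qrrho(fs: FrequencySet, T: float,
                              nu0: float = NU0_DEFAULT,
                              alpha: float = ALPHA_DEFAULT,
                              b_av: float = B_AV_DEFAULT) -> float:
    """Quasi-RRHO vibrational entropy in kcal/mol/K.

    Per mode S = w·S_HO + (1−w)·S_FR with w(ν) = 1/(1+(ν₀/ν)^α); the
    free-rotor branch uses an effective moment combining the mode-derived
    moment with *b_av*.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    wn = _require_cleaned(fs)
    if wn.size == 0:
        return 0.0
    if np.any(wn <= 0):
        raise ValueError("cleaned wavenumbers must be positive")
    w = qrrho_weight(wn, nu0, alpha)
    s = w * _s_harmonic(wn, T) + (1.0 - w) * _s_free_rotor(wn, T, b_av)
    return float(s.sum())


def _e_vib_thermal(wn: np.ndarray, T: float) -> float:
    """Thermal vibrational internal energy beyond ZPVE, kcal/mol."""
    if wn.size == 0:
        return 0.0
    x = _theta_over_t(wn, T)
    with np.errstate(over="ignore"):
        e = x / np.expm1(x)
    return float(R_KCAL * T * e.sum())


def gibbs_correction(rec: StationaryPointRecord, T: float,
                     nu0: float = NU0_DEFAULT,
                     alpha: float = ALPHA_DEFAULT,
                     b_av: float = B_AV_DEFAULT,
                     standard_state: str = "1 atm") -> ThermalCorrection:
    """Assemble the quasi-RRHO Gibbs correction for one stationary point.

    Requires frequencies on the record (cleaned automatically according to
    the record role).  Translational and rotational contributions are
    included when a geometry is present; without one the correction is
    vibration-only, which is the appropriate treatment for site fragments
    whose translation/rotation is quenched by the surrounding protein.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if rec.frequencies is None:
        raise ValidationError(
            f"record {rec.label!r} has no frequencies; supply them or skip "
            "thermal corrections (electronic-only protocol)"
        )
    fs = rec.frequencies if rec.frequencies.cleaned else clean_frequencies(rec.frequencies)
    wn = np.asarray(fs.wavenumbers, dtype=float)

    e_zpve = zpve(fs)
    s_vib = vibrational_entropy_qrrho(fs, T, nu0=nu0, alpha=alpha, b_av=b_av)
    e_thermal = _e_vib_thermal(wn, T)
    entropy = s_vib
    components: dict[str, float] = {"s_vib_qrrho": s_vib}
    # harmonic-part bookkeeping for diagnostics
    components["q_vib_harmonic_part"] = float(
        np.sum(-np.log1p(-np.exp(-_theta_over_t(wn, T)))) if wn.size else 0.0
    )

    if rec.geometry is not None:
        q_trans = partition_translational(rec.geometry.total_mass, T, standard_state)
        q_rot = partition_rotational(rec.geometry, T, sigma=rec.symmetry_number)
        components["q_trans"] = q_trans
        components["q_rot"] = q_rot
        s_trans = R_KCAL * (math.log(q_trans) + 2.5)
        e_thermal += 1.5 * R_KCAL * T
        if rec.geometry.n_atoms == 1:
            s_rot = 0.0
        else:
            linear = _is_linear(_inertia_moments(rec.geometry))
            s_rot = R_KCAL * (math.log(q_rot) + (1.0 if linear else 1.5))
            e_thermal += (1.0 if linear else 1.5) * R_KCAL * T
        entropy += s_trans + s_rot
        g_thermal = e_thermal + R_KCAL * T - T * entropy  # +RT: pV term of H
    else:
        components["q_trans"] = 1.0
        components["q_rot"] = 1.0
        g_thermal = e_thermal - T * entropy

    return ThermalCorrection(
        temperature=T, zpve=e_zpve, g_thermal=g_thermal, components=components
    )


def standard_state_correction(delta_n: int, T: float = 298.15) -> float:
    """Free-energy change for converting Δn moles between 1 atm gas and 1 M.

    Returns RT·ln(24.465·(T/298.15))·Δn in kcal/mol, ≈ 1.9·Δn at 298.15 K.
    """
    if delta_n == 0:
        return 0.0
    ratio = MOLAR_VOLUME_298 * (T / 298.15)
    return float(R_KCAL * T * math.log(ratio) * delta_n)
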