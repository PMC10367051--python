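"""Energy-combination schemes and composite free energies.

Implements the subtractive QM/MM combination

    E = E_QM-pchg + E_MM123 − E_MM1 ,

the COSMO-RS free-energy assembly E_COSMO(ε=∞) + ΔE_diel + μ, the
protocol-tagged composite free energies (single-point energy on the QM/MM
geometry plus the quasi-RRHO Gibbs correction), the empirical ~3 kcal/mol
water-dissociation correction for the COSMO-RS protocol, and the
transition-state destabilization analysis comparing a substituted warhead
against its parent compound.
"""

from __future__ import annotations

import enum
from typing import Mapping

from .records import EnergyComponents, StationaryPointRecord, TRANSITION_STATE, ValidationError
from .thermochem import gibbs_correction

__all__ = [
    "ProtocolTag",
    "CorrectedEnergy",
    "qmmm_energy",
    "composite_free_energy",
    "cosmo_rs_free_energy",
    "water_dissociation_correction",
    "substitution_shift",
    "WATER_CORRECTION_DEFAULT",
]

#: Default empirical penalty (kcal/mol) against the artificial preference of
#: COSMO-RS for water dissociation from a cluster or active site.
WATER_CORRECTION_DEFAULT = 3.0


class ProtocolTag(enum.Enum):
    """Closed enumeration of the single-point protocols.

    ``E_TPSS`` is the electronic-only column (no entropic corrections); all
    ``G_*`` protocols add the quasi-RRHO Gibbs correction.
    """

    G_TPSS = "G_TPSS"
    G_B3LYP = "G_B3LYP"
    G_BP86_CRS = "G_BP86_CRS"
    G_BP86_CRS_noWat = "G_BP86_CRS_noWat"
    E_TPSS = "E_TPSS"

    @property
    def includes_entropy(self) -> bool:
        return self is not ProtocolTag.E_TPSS


def qmmm_energy(c: EnergyComponents) -> float:
    """Subtractive QM/MM total energy E_QM-pchg + E_MM123 − E_MM1 (kcal/mol)."""
    for name in ("e_qm_pchg", "e_mm123", "e_mm1"):
        if getattr(c, name) is None:
            raise ValidationError(f"QM/MM combination requires field {name!r}")
    return float(c.e_qm_pchg + c.e_mm123 - c.e_mm1)


def cosmo_rs_free_energy(c: EnergyComponents) -> float:
    """COSMO-RS free energy E_COSMO(ε=∞) + ΔE_diel + μ (kcal/mol).

    Thermal corrections are added separately via :func:`composite_free_energy`.
    """
    for name in ("e_cosmo_inf", "delta_e_diel", "mu_chem"):
        if getattr(c, name) is None:
            raise ValidationError(f"COSMO-RS assembly requires field {name!r}")
    return float(c.e_cosmo_inf + c.delta_e_diel + c.mu_chem)


def composite_free_energy(rec: StationaryPointRecord, tag: ProtocolTag,
                          T: float = 298.15, **qrrho_kwargs) -> float:
    """Protocol composite energy of one stationary point, kcal/mol.

    For entropy-carrying protocols this is the tagged single-point energy
    plus the quasi-RRHO Gibbs correction at *T*; for the electronic-only
    protocol it is the bare single point.
    """
    if not isinstance(tag, ProtocolTag):
        tag = ProtocolTag(tag)
    try:
        sp = float(rec.energies.single_point[tag.value])
    except KeyError:
        raise ValidationError(
            f"record {rec.label!r} has no single-point energy for protocol {tag.value}"
        ) from None
    if not tag.includes_entropy:
        return sp
    corr = gibbs_correction(rec, T, **qrrho_kwargs)
    return sp + corr.g_corr


class CorrectedEnergy(float):
    """A free energy that already carries the empirical water correction."""

    corrected = True


def water_dissociation_correction(delta_g_raw: float,
                                  direction: str = "dissociation",
                                  correction: float = WATER_CORRECTION_DEFAULT) -> CorrectedEnergy:
    """Apply the empirical COSMO-RS water-dissociation penalty.

    The raw dissociation free energy is shifted by +*correction* (default
    3.0 kcal/mol), disfavouring the artificially favoured release of a water
    molecule; for the association direction the sign is inverted.  Applying
    the correction twice is rejected.  Intended for explicit water
    association/dissociation events only — never for solute (e.g.
    difluoroacetate) dissociation.
    """
    if isinstance(delta_g_raw, CorrectedEnergy):
        raise ValidationError("water correction already applied to this value")
    if direction == "dissociation":
        return CorrectedEnergy(float(delta_g_raw) + correction)
    if direction == "association":
        return CorrectedEnergy(float(delta_g_raw) - correction)
    raise ValueError(f"unknown direction {direction!r}")


def substitution_shift(profile_sub, profile_parent) -> dict[str, float]:
    """Transition-state destabilization of a substituted warhead vs its parent.

    Both profiles must list identical stationary-point labels in the same
    order, each referenced to its own Michaelis complex (use
    ``ReactionProfile.re_reference`` for the second hydrolytic step, whose
    natural reference is MC_S2′).  Returns ``{TS label: ΔΔG}`` in kcal/mol.
    """
    sub_pts = list(profile_sub.points)
    par_pts = list(profile_parent.points)
    if [(p.label, p.role) for p in sub_pts] != [(p.label, p.role) for p in par_pts]:
        raise ValidationError(
            "profiles cannot be aligned: stationary-point labels/roles differ"
        )
    return {
        s.label: float(s.g - p.g)
        for s, p in zip(sub_pts, par_pts)
        if s.role == TRANSITION_STATE
    }
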