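"""Published reference values consumed as model inputs.

These are the printed inputs of the HDAC6 oxadiazole-hydrolysis study this
package models: composite free-energy profiles of the two-step hydrolysis of
the difluoromethyl-oxadiazole inhibitor (compound 8 → 6 → 4) under five
single-point protocols, the electronic-energy profile of the non-fluorinated
methyl analogue (compound 10), the association/dissociation free energies
that join the two hydrolytic steps onto one absolute scale, inhibition
constants (IC₅₀) used as binding parameters, the in vitro assay conditions,
and the acid pKa values behind the substituent descriptor.

Everything here is an input to the pipeline, not a result it computes.
"""

from __future__ import annotations

from .records import MINIMUM, TRANSITION_STATE

#: Stationary-point labels of the full two-step profile, in reaction order.
#: ``MC_S2gm`` is the global-minimum water-bound complex opening step 2;
#: ``MC_S2p`` (MC_S2′) is the rearranged, catalytically competent complex.
PROFILE_LABELS: tuple[str, ...] = (
    "MC_S1", "TS1_S1", "TI_S1", "TS2_S1", "P_S1",
    "MC_S2gm", "MC_S2p", "TS1_S2", "TI_S2", "TS2_S2", "P_S2",
)

PROFILE_ROLES: tuple[str, ...] = (
    MINIMUM, TRANSITION_STATE, MINIMUM, TRANSITION_STATE, MINIMUM,
    MINIMUM, MINIMUM, TRANSITION_STATE, MINIMUM, TRANSITION_STATE, MINIMUM,
)

#: Composite free energies (kcal/mol, relative to MC_S1) per protocol.
#: ``E_TPSS`` carries no entropic corrections.  The final product row after
#: difluoroacetate dissociation (P_FIN) is never tabulated here; it is
#: computed as P_S2 + DIFLUOROACETATE_DISSOCIATION_DG.
COMPOSITE_PROFILES: dict[str, tuple[float, ...]] = {
    "G_TPSS":           (0.0, 4.4, -2.7, 18.3, -15.0, -16.0, -3.7, 2.2, -3.4, 5.9, -8.3),
    "G_B3LYP":          (0.0, 8.5, -0.6, 21.0, -18.3, -15.7, -3.7, 4.5, -2.5, 9.3, -6.7),
    "G_BP86_CRS":       (0.0, 4.8, -2.9, 19.4, -14.4, -16.8, -3.7, 4.3, -2.1, 5.2, -9.8),
    "G_BP86_CRS_noWat": (0.0, 6.0, -3.1, 15.5, -15.1, -13.0, -3.7, 4.4, -3.6, 5.3, -6.9),
    "E_TPSS":           (0.0, 5.1, -4.0, 20.7, -16.8, -16.0, -1.4, 4.6, -3.3, 10.7, -7.0),
}

#: Binding free energy of the second catalytic water, P_S1 + H₂O → MC_S2gm
#: (kcal/mol; COSMO-RS protocol, includes the empirical water correction and
#: the standard-state term).
WATER_BINDING_DG: float = -1.0

#: Free energy of difluoroacetate dissociation from the active site,
#: P_S2 → P_FIN (kcal/mol).
DIFLUOROACETATE_DISSOCIATION_DG: float = -12.0

#: Step-wise label blocks.
STEP1_LABELS = PROFILE_LABELS[:5]
STEP1_ROLES = PROFILE_ROLES[:5]
STEP2_LABELS = PROFILE_LABELS[6:]          # MC_S2p … P_S2
STEP2_ROLES = PROFILE_ROLES[6:]

#: Electronic-only profile of the CH₃ (compound 10) analogue obtained by
#: single-point substitution on the compound-8 geometries: step 1 relative to
#: MC_S1, step 2 relative to MC_S2′.
METHYL_ANALOG_STEP1: tuple[float, ...] = (0.0, 9.3, 4.3, 28.2, -11.4)
METHYL_ANALOG_STEP2: tuple[float, ...] = (0.0, 8.7, 7.4, 18.3, 3.8)

#: IC₅₀ values in nM, used as surrogate dissociation constants.  ``None``
#: marks "not tested"; censored values (">X") are entered at their floor.
IC50_NM: dict[str, dict[str, float]] = {
    "hHDAC6": {
        "cpd7": 14.6, "cpd8": 2.06, "cpd9": 85.0, "cpd10": 100_000.0,
        "cpd4": 2160.0, "cpd5": 10_800.0, "cpd6": 14_450.0,
    },
    "zHDAC6_WT": {"cpd4": 3866.0, "cpd6": 41_736.0},
    "zHDAC6_Y745F": {
        "cpd7": 311.0, "cpd8": 75.0, "cpd4": 50_000.0, "cpd6": 50_000.0,
    },
}

#: In vitro hydrolysis assay conditions: 20 µM compound 8, 2 µM enzyme, 30 °C.
ASSAY_S0_UM: float = 20.0
ASSAY_E0_UM: float = 2.0
ASSAY_TEMPERATURE_K: float = 303.15

#: Aqueous pKa values of acetic and difluoroacetic acid (substituent
#: descriptor inputs).
PKA_ACETIC: float = 4.76
PKA_DIFLUOROACETIC: float = 1.34
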