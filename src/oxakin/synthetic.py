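"""Deterministic synthetic fixtures for every pipeline stage.

The generators emulate the study's data without any external inputs:

* frequency sets with controlled low-frequency content and small spurious
  imaginary modes (numerical noise of constrained-site normal-mode
  analyses), plus one large reactive imaginary for transition states;
* toy molecular geometries for partition-function code paths;
* stationary-point record collections whose protocol composite free
  energies reproduce a given profile template *through* the thermochemistry
  layer — single-point energies are back-solved from the generated Gibbs
  corrections, so the template is recovered end-to-end, not by arithmetic
  shortcut;
* noisy cascade time courses with known ground-truth rate constants
  (multiplicative lognormal noise, as LC–MS/MS quantification error scales
  with concentration).

All outputs are bit-reproducible for a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .energy_model import ProtocolTag, composite_free_energy
from .kinetics import AssayConditions, KineticScheme, simulate_time_course
from .records import (
    ATOMIC_MASSES, FrequencySet, MoleculeGeometry, StationaryPointRecord,
    EnergyComponents, TimeCourse, MINIMUM, TRANSITION_STATE, ValidationError,
)
from . import reference

__all__ = [
    "GeneratorSpec",
    "make_frequency_set",
    "make_toy_geometry",
    "make_profile_records",
    "make_time_course",
]

_TOY_ELEMENTS = ("H", "C", "N", "O", "F", "S", "Zn")


def _default_template() -> dict[str, float]:
    return dict(zip(reference.PROFILE_LABELS,
                    reference.COMPOSITE_PROFILES["G_TPSS"]))


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the synthetic generators; identical spec ⇒ identical output.

    ``profile_template`` maps stationary-point labels to target relative
    free energies (kcal/mol); it defaults to the published two-step
    composite profile.  ``true_params`` holds the ground-truth kinetic
    constants used for time-course generation.
    """

    seed: int = 0
    n_modes: int = 30
    low_mode_fraction: float = 0.15
    n_spurious_imag: int = 2
    profile_template: Mapping[str, float] = field(default_factory=_default_template)
    noise_cv: float = 0.05
    true_params: Mapping[str, float] = field(
        default_factory=lambda: {"kcat1": 4.6e-3, "kcat2": 1.0e-3}
    )

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValidationError("n_modes must be ≥ 1")
        if not 0.0 <= self.low_mode_fraction <= 1.0:
            raise ValidationError("low_mode_fraction must lie in [0, 1]")
        if self.n_spurious_imag < 0:
            raise ValidationError("n_spurious_imag must be ≥ 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be ≥ 0")


def make_frequency_set(spec: GeneratorSpec, role: str = MINIMUM) -> FrequencySet:
    """Draw a frequency set matching the spec's composition.

    Of the ``n_modes`` entries: ``round(low_mode_fraction·n_modes)`` real
    modes in (50, 100) cm⁻¹, ``n_spurious_imag`` small imaginaries with
    |ν| < 50 cm⁻¹, the rest in (100, 3500) cm⁻¹.  A transition state
    additionally replaces one regular mode with a large reactive imaginary
    in (300, 1500)i cm⁻¹.
    """
    rng = np.random.default_rng(spec.seed)
    n_low = int(round(spec.low_mode_fraction * spec.n_modes))
    n_reactive = 1 if role == TRANSITION_STATE else 0
    n_rest = spec.n_modes - n_low - spec.n_spurious_imag - n_reactive
    if n_rest < 0:
        raise ValidationError(
            "infeasible composition: low + spurious (+ reactive) modes exceed n_modes"
        )
    low = rng.uniform(50.0, 100.0, n_low)
    spurious = -rng.uniform(5.0, 50.0, spec.n_spurious_imag)
    rest = rng.uniform(100.0, 3500.0, n_rest)
    parts = [low, spurious, rest]
    if n_reactive:
        parts.append(-rng.uniform(300.0, 1500.0, 1))
    wn = np.concatenate(parts)
    rng.shuffle(wn)
    return FrequencySet(tuple(float(w) for w in wn), role=role)


def make_toy_geometry(n_atoms: int, seed: int, collinear: bool = False) -> MoleculeGeometry:
    """Random non-degenerate geometry in a 5 Å box, minimum separation 0.7 Å.

    ``collinear`` places all atoms on a line (exercising the linear-rotor
    branch).  Element symbols are drawn from {H, C, N, O, F, S, Zn}.
    """
    if n_atoms < 1:
        raise ValidationError("n_atoms must be ≥ 1")
    rng = np.random.default_rng(seed)
    symbols = [str(rng.choice(_TOY_ELEMENTS)) for _ in range(n_atoms)]
    if collinear:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords = np.outer(np.arange(n_atoms) * 1.2, direction)
    else:
        coords_list: list[np.ndarray] = []
        for _ in range(n_atoms):
            for _attempt in range(1000):
                candidate = rng.uniform(0.0, 5.0, 3)
                if all(np.linalg.norm(candidate - c) >= 0.7 for c in coords_list):
                    coords_list.append(candidate)
                    break
            else:
                raise RuntimeError("rejection sampling failed to place an atom")
        coords = np.vstack(coords_list)
    return MoleculeGeometry.from_symbols(symbols, coords)


def make_profile_records(spec: GeneratorSpec,
                         roles: Mapping[str, str] | None = None,
                         tag: ProtocolTag = ProtocolTag.G_TPSS,
                         T: float = 298.15) -> list[StationaryPointRecord]:
    """Records whose composite energies reproduce the profile template.

    Each label receives a generated frequency set (role-appropriate) and
    the single-point energy is back-solved so that
    ``composite_free_energy(record) − composite_free_energy(reference)``
    equals the template value exactly.  The first template entry is the
    reference (must map to 0).
    """
    template = dict(spec.profile_template)
    if not template:
        raise ValidationError("empty profile template")
    labels = list(template)
    if roles is None:
        if tuple(labels) == reference.PROFILE_LABELS:
            roles = dict(zip(reference.PROFILE_LABELS, reference.PROFILE_ROLES))
        else:
            raise ValidationError(
                "roles must be supplied for a non-default template"
            )
    prev_role = None
    for lab in labels:
        if roles[lab] == TRANSITION_STATE and prev_role == TRANSITION_STATE:
            raise ValidationError("template has two consecutive transition states")
        prev_role = roles[lab]
    if roles[labels[0]] != MINIMUM or abs(template[labels[0]]) > 1e-12:
        raise ValidationError("template must start at a minimum with value 0")

    from .thermochem import gibbs_correction  # local import avoids cycle at module load

    records: list[StationaryPointRecord] = []
    sp_reference = -1000.0  # arbitrary absolute anchor for the reference point
    composite_ref: float | None = None
    for i, lab in enumerate(labels):
        role = roles[lab]
        sub_seed = (spec.seed * 100003 + i * 7919) % (2**31)
        fs = make_frequency_set(
            GeneratorSpec(seed=sub_seed, n_modes=spec.n_modes,
                          low_mode_fraction=spec.low_mode_fraction,
                          n_spurious_imag=spec.n_spurious_imag),
            role=role,
        )
        probe = StationaryPointRecord(
            label=lab, role=role,
            energies=EnergyComponents(single_point={tag.value: 0.0}),
            frequencies=fs,
        )
        g_corr = gibbs_correction(probe, T).g_corr if tag.includes_entropy else 0.0
        if composite_ref is None:
            sp = sp_reference
            composite_ref = sp + g_corr
        else:
            sp = template[lab] + composite_ref - g_corr
        records.append(StationaryPointRecord(
            label=lab, role=role,
            energies=EnergyComponents(single_point={tag.value: sp}),
            frequencies=fs,
        ))
    return records


def make_time_course(scheme: KineticScheme, cond: AssayConditions,
                     noise_cv: float, n_points: int, seed: int,
                     t_end: float = 240.0) -> TimeCourse:
    """Simulated cascade time course with multiplicative lognormal noise.

    ``noise_cv`` is the fractional coefficient of variation; 0 returns the
    exact simulation.  Values are clipped at 0 (lognormal noise is already
    non-negative).  Sampling emulates discrete assay aliquots on a uniform
    grid from 0 to *t_end* minutes.
    """
    if n_points < 2:
        raise ValidationError("need at least 2 sampling points")
    t_grid = np.linspace(0.0, t_end, n_points)
    tc = simulate_time_course(scheme, cond, t_grid)
    if noise_cv == 0:
        return tc
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noisy = {}
    for name, series in tc.concentrations.items():
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                size=series.shape)
        noisy[name] = np.clip(series * factors, 0.0, None)
    return TimeCourse(tc.times, noisy)
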