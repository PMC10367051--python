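# oxakin

Desk-scale free-energy bookkeeping and microkinetics for the enzymatic
hydrolysis of oxadiazole-based HDAC6 inhibitors.

HDAC6-selective inhibitors built on a fluoromethyl-1,3,4-oxadiazole
zinc-binding warhead are hydrolyzed by the enzyme itself in two steps:
the parent oxadiazole (compound **8**) is ring-opened to a
difluoroacetylated hydrazide intermediate (**6**), which is then cleaved to
the final acylhydrazide (**4**) with release of difluoroacetate. `oxakin`
implements the analysis layer that connects the computed free-energy
landscape of that double hydrolysis with the observed solution kinetics:

* **records** — stationary-point records (energies, XYZ geometries, signed
  harmonic wavenumbers), time-course tables, and their plain-text formats;
* **thermochem** — ZPVE, translational/rotational/vibrational partition
  functions, and quasi-RRHO Gibbs corrections
  `G_corr = E_ZPVE + E_thermal + RT − T·S`, with a free-rotor treatment of
  modes below 100 cm⁻¹ blended by the damping function
  `w(ν) = 1/(1 + (ν₀/ν)⁴)`, plus the `RT·ln(24.465·T/298.15)·Δn`
  standard-state conversion (≈ 1.9·Δn kcal/mol);
* **energy_model** — the subtractive QM/MM combination
  `E = E_QM-pchg + E_MM123 − E_MM1`, the COSMO-RS assembly
  `E_COSMO + ΔE + μ`, protocol-tagged composite free energies, the
  empirical ~3 kcal/mol water-dissociation correction, and
  transition-state destabilization between substituent analogues;
* **profiles** — reaction profiles with minima/transition-state alternation,
  stitching of per-step profiles onto one absolute scale through
  association/dissociation free energies, elementary barriers
  `ΔG‡ = G(TS) − G(preceding minimum)`, and the rate-determining step;
* **kinetics** — Eyring rates `k = (k_B·T/h)·exp(−ΔG‡/RT)`, a microkinetic
  ODE cascade for the sequential hydrolysis with rapid-equilibrium
  competitive binding, processivity and product inhibition, and
  least-squares recovery of rate constants from time courses;
* **descriptors** — the pKa-based substituent descriptor
  `ΔΔG = ΔpKa·RT·ln 10` and a reactive/unreactive classification;
* **synthetic** — seeded generators for every fixture: frequency sets with
  spurious imaginary modes, toy geometries, back-solved stationary-point
  records, and noisy cascade time courses with known ground truth.

## Worked example

```python
import numpy as np
from oxakin import reference as ref
from oxakin.profiles import ReactionProfile, rate_determining_step
from oxakin.kinetics import (AssayConditions, build_cascade_scheme,
                             eyring_rate, simulate_time_course,
                             time_to_fraction)

profile = ReactionProfile.from_values(
    ref.PROFILE_LABELS, ref.PROFILE_ROLES, ref.COMPOSITE_PROFILES["G_TPSS"])
rds = rate_determining_step(profile)
print(f"RDS: {rds.from_minimum} -> {rds.ts}, {rds.delta_g_act:.1f} kcal/mol")

k = eyring_rate(rds.delta_g_act, ref.ASSAY_TEMPERATURE_K)
print(f"k(TST) = {k:.2e} s^-1 at 30 C")

scheme = build_cascade_scheme(kd8=1e-4, kd6=1e6, kd4=1e6,
                              kcat1=k, kcat2=1e-3, p=0.5, T=303.15)
cond = AssayConditions(s0=20.0, e0=2.0, T=303.15)
tc = simulate_time_course(scheme, cond, np.linspace(0, 240, 2401))
print(f"99% depletion of compound 8 after {time_to_fraction(tc, 'cpd8', 0.01):.1f} min")
```

prints

```
RDS: TI_S1 -> TS2_S1, 21.0 kcal/mol
k(TST) = 4.58e-03 s^-1 at 30 C
99% depletion of compound 8 after 36.0 min
```

The rate-determining step of the whole cascade is the ring-opening of the
first tetrahedral intermediate (TI_S1 → TS2_S1, 18.3 − (−2.7) = 21.0
kcal/mol); its transition-state-theory rate at the assay temperature is in
the 10⁻³ s⁻¹ range, and a saturated-enzyme simulation at 20 µM substrate /
2 µM enzyme consumes >99% of the parent compound in ~36 minutes — well
inside the <180 min window observed in vitro.

The same stages are exposed on the command line
(`oxakin synth | thermo | energies | profile | simulate | fit | descriptor`;
see `oxakin --help`).

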