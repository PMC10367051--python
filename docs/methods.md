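# Methods

## Scope and model system

`oxakin` operates downstream of electronic-structure work: stationary-point
energies, geometries and harmonic wavenumbers are *inputs*, extracted from
quantum-chemistry runs or generated synthetically. The package's job is the
bookkeeping and inference built on top of them — thermochemical corrections,
composite free energies, profile assembly, transition-state-theory rates and
microkinetic simulation — for the two-step hydrolysis of a
difluoromethyl-1,3,4-oxadiazole HDAC6 inhibitor (compound 8 → intermediate
6 → acylhydrazide 4, with difluoroacetate released in the second step).

Internal units are fixed: kcal/mol for energies (hartree accepted on input
at 627.509 kcal/mol per hartree), Å, amu, cm⁻¹, K, µM and minutes (s⁻¹ for
rate constants). No alternative unit dialects are supported.

## Thermochemistry

The Gibbs correction added to a single-point energy is the standard
ideal-gas expression

    G_corr = E_ZPVE + E_thermal + RT − T·S,

with `E_thermal` the translational, rotational and thermal vibrational
internal energy and `RT` the pV term of the enthalpy. The source protocol
writes this correction in the shorthand "E_ZPVE + RT ln Q + RT"; because
that notation leaves the sign bookkeeping of the entropic term ambiguous,
the implementation pins the standard thermodynamic form and the tests pin it
against independently evaluated closed forms (Sackur–Tetrode-type
translational entropy, harmonic-oscillator mode entropy, rigid-rotor
moments computed by hand for known geometries).

Vibrational entropy uses the quasi-RRHO (free-rotor interpolation)
treatment: per mode,

    S(ν) = w(ν)·S_HO(ν) + (1 − w(ν))·S_FR(ν),
    w(ν) = 1 / (1 + (ν₀/ν)^α),

with the free-rotor entropy evaluated from an effective moment
μ′ = μB/(μ+B), μ = h/(8π²cν̃). Defaults: ν₀ = 100 cm⁻¹ (the crossover the
protocol states), α = 4 and B = 10⁻⁴⁴ kg·m² (the published values of the
interpolation method, which the protocol does not restate); all three are
keyword-configurable. Thermal vibrational energy stays harmonic — only the
entropy is interpolated.

Frequency cleaning reflects how constrained-site normal-mode analyses
behave: small imaginary modes are numerical noise and are flipped to
positive values regardless of magnitude (minima), while a transition state
must contain at least one imaginary mode, whose largest-magnitude member is
removed from the thermochemical list as the reactive mode.

Translation/rotation contributions are included only when a record carries a
geometry; enzyme-site fragments, whose translation and rotation are quenched
by the protein, are treated vibration-only. Default symmetry number is 1
(site fragments have no symmetry; overridable per record) and electronic
degeneracy is 1 (closed-shell species throughout).

The standard-state conversion for association/dissociation events is
`RT·ln(24.465·(T/298.15))·Δn`, ≈ 1.9·Δn kcal/mol at 298.15 K, with Δn the
molar change.

## Energy combination and protocols

The subtractive QM/MM total energy is `E = E_QM-pchg + E_MM123 − E_MM1`
(QM region embedded in point charges; MM energy of the whole system with
region-1 charges zeroed; minus the double-counted MM energy of region 1).
The COSMO-RS free energy is `E_COSMO(ε=∞) + ΔE_diel + μ`. Both are exact
linear forms and are validated as such.

Composite free energies are tagged by a closed protocol enumeration
(`G_TPSS`, `G_B3LYP`, `G_BP86_CRS`, `G_BP86_CRS_noWat`, `E_TPSS`); the
closed set prevents silent mixing of incompatible single points. `E_TPSS`
is electronic-only; all `G_*` protocols add `G_corr`.

COSMO-RS slightly over-favours the dissociation of a water molecule from a
cluster or active site; the package applies a configurable empirical
penalty (default +3.0 kcal/mol on the dissociation direction, the sign
inverted for association) and only to explicit water events, never to
solute dissociation. A corrected value carries a flag so the correction
cannot be applied twice. The exact magnitude used upstream is only known to
be "about 3", hence the parameter.

## Profile assembly

Within a segment, minima and transition states alternate; two adjacent
minima are a segment break (e.g. the rearrangement of the water-bound
global-minimum complex MC_S2gm into the catalytically competent MC_S2′,
which is a minimum→minimum free-energy cost, not a barrier). Per-step
profiles are stitched onto one absolute scale by placing the downstream
reference at `G(upstream terminal minimum) + ΔG_link`; the two links of the
cascade are the water association (−1 kcal/mol) and the difluoroacetate
dissociation (−12.0 kcal/mol). Stitching is associative, and a
standard-state term can be folded into a link on request (off by default —
tabulated link values normally already include it).

Elementary barriers are measured from the nearest preceding minimum, so the
first step-2 barrier is referenced to MC_S2′; the alternative reference
from MC_S2gm (18.2 kcal/mol in the default protocol) is exposed through
`barrier_between`. The rate-determining step is the maximal elementary
barrier, ties broken by earliest position with all tied barriers reported.
The tabulated final-product row of the source table re-references P_FIN to
zero in every column; the package never ingests that row and instead
computes P_FIN as P_S2 plus the dissociation link (−20.3 kcal/mol on the
default protocol's absolute scale).

## Kinetics

Eyring TST, `k = κ·(k_B·T/h)·exp(−ΔG‡/RT)` with κ = 1 (bare TST), converts
barriers to rate constants; the closed-form inverse is provided.

The cascade ODE model is this package's own exploratory construction — the
source study reports time courses but defines no rate equations. Design:

* rapid-equilibrium competitive binding of 8, 6 and 4 to free enzyme, with
  algebraic occupancies θᵢ = (cᵢ/Kdᵢ)/(1 + Σⱼ cⱼ/Kdⱼ); no on/off rates are
  available, and explicit binding kinetics would add unidentifiable
  parameters;
* bound 8 converts at k_cat1, a fraction *p* (processivity) proceeding to 4
  without releasing 6; bound 6 converts at k_cat2; bound 4 is a dead-end
  complex (product inhibition). Processivity and product inhibition are the
  two switchable hypotheses for the wild-type stall and the Y745F-mutant
  burst; the data do not discriminate them from enzyme inactivation, which
  is out of scope;
* binding parameters default to IC₅₀ values used as Ki surrogates (substrate
  near Km in the source assays); the Cheng–Prusoff competitive correction is
  available but off by default;
* difluoroacetate is not integrated as a state: it is produced 1:1 with
  compound 4 under this scheme;
* under the rapid-equilibrium treatment the ligand pools are free pools and
  the right-hand side conserves [8]+[6]+[4] exactly; the integrator (LSODA,
  rtol 1e-8, atol 1e-10 µM) preserves linear invariants, so the 1e-6 µM
  mass-balance check holds to roundoff. Every simulation verifies mass
  balance and finiteness and fails loudly rather than returning NaNs.

Assay defaults are 20 µM substrate, 2 µM enzyme, 303.15 K (the kinetics
figure's 30 °C governs over a 25 °C autosampler mentioned elsewhere; both
are exposed). Fitting is deterministic least squares on log-scaled positive
parameters (bounds 1e-6–1e6, seeded at 20230703 for any restart logic),
with convergence always reported.

## Substituent descriptor

The highest barriers of both steps pass through negatively charged species
whose charge sits β to the warhead substituent, mirroring the deprotonation
of substituted acetic acids. The descriptor is
ΔΔG = (pKa_ref − pKa_sub)·RT·ln 10, evaluated exactly (1.364 kcal/mol per
pKa unit at 298.15 K rather than the rounded 1.36; the printed 4.7 kcal/mol
for CH₃ vs CF₂H is still recovered after rounding). Classification adds the
descriptor to the parent rate-determining barrier and compares the Eyring
rate with a floor of 1e-4 s⁻¹ — one order below the observed ~1e-3 s⁻¹
conversion of the parent compound, a package convention since no
quantitative boundary is published — with a tenfold marginal band below it.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible.
Frequency sets draw from the harmonic range 50–3500 cm⁻¹ with a requested
fraction of sub-100 cm⁻¹ modes and a requested count of small (<50 cm⁻¹)
spurious imaginaries; transition states receive one large reactive
imaginary (300–1500i cm⁻¹). Profile fixtures are *back-solved*: single-point
energies are chosen so that the composite free energies, after passing
through the full thermochemistry layer, reproduce a target profile template
(default: the tabulated two-step composite profile). This guarantees the
end-to-end pipeline is exercised, not just profile arithmetic. Time-course
noise is multiplicative lognormal (unit mean), since LC–MS/MS quantification
error scales with concentration.

What the generators do not emulate: correlated residuals between species
measured from the same aliquot, baseline/limit-of-detection censoring,
systematic calibration drift, and any structure in the frequency spectra
beyond composition counts. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated noise model, not
robustness to real instrument pathologies.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as comfortably
sufficient for the quantities measured: cascade grids of 241–2401 points
over 4–10 h of simulated time, 25-point sampled time courses for fitting,
20 noisy replicates for median-recovery statistics, and 1000 random
profiles for the rate-determining-step cross-check. Temperature continuity
of `G_corr` is checked numerically on a 10–1000 K grid. Exponential
overflow in Boltzmann factors is capped at θ/T = 700, where the affected
terms are identically zero to double precision.

## Known limitations

* No hindered-rotor scans, anharmonic corrections or frequency scaling.
* No parsing of native quantum-chemistry outputs; records are extracted
  upstream.
* The cascade model deliberately omits slow binding, enzyme inactivation
  and depletion of free enzyme by ligand sequestration (occupancies are
  computed from total ligand); at the study's concentrations (ligand ≫
  enzyme for most of the reaction) the approximation is standard, but it
  will distort the earliest time points when a tight binder is
  sub-stoichiometric.
* IC₅₀-as-Ki is a surrogate, adequate for qualitative phenotype work
  (stall/burst), not for absolute affinity claims.
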