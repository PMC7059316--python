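# Methods

This note records the models implemented in `cspfrag`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open.

## Hybrid many-body fragment energy

The crystal electronic energy per unit cell is partitioned into 1-body
(intramolecular), short-range pairwise 2-body, long-range 2-body, and
collective many-body terms:

    U_el = Σ_i E_i^high + Σ_{d ∈ SR} m_d ΔE_d^high + E2_LR^low + E_MB^low,

where ΔE_d = E(dimer) − E(monomer a) − E(monomer b) and m_d is the per-cell
multiplicity of the symmetry/translation-unique dimer class d. The premise is
the standard fragment-method one: monomer and near-contact dimer energies
dominate the polymorph energy differences and deserve the accurate (and
expensive) level, while everything long-ranged and collective is adequately
described by a periodic mean-field level.

Design choices:

- **Dimer separation metric** is the closest interatomic contact, not the
  centroid distance, so the cutoff is meaningful for elongated molecules.
  The short-range cutoff defaults to 9 Å and is configurable.
- **Canonical fragment keys.** Monomers and dimers are identified by the
  element multiset plus the distance spectrum quantized at 1e-4 Å (dimers
  additionally by the intermolecular spectrum, invariant to the ordering of
  the two monomers). Symmetry-equivalent fragments therefore collapse to one
  ledger entry with a multiplicity. This distance-spectrum equivalence is
  cheaper and more robust to float noise than explicit space-group orbit
  tracking; a `deduplicate=False` flag re-enumerates every instance for
  verification, and a dedicated test asserts both paths assemble to the same
  total within 1e-10 Eh. A known limitation: enantiomeric dimers share a
  distance spectrum; for a pairwise-additive surrogate their energies are
  identical by construction, and for real chiral fragments the flag disables
  merging.
- **Low-level remainder by difference.** The partition above is a statement,
  not an algorithm; the remainder E2_LR + E_MB is computed robustly as
  E_periodic^low − ΣE1^low − ΣE2_SR^low, and split into its two parts only
  when the job set carries explicit long-range dimers with low-level
  energies (`assemble_hmbi(..., sr_cutoff=...)` with an enumeration cutoff
  beyond the SR one). The identity total = e1 + e2sr + e2lr + emb holds
  exactly by construction in either mode.
- **Units.** Energies are held in Hartree internally and reported in
  kJ mol⁻¹ (1 Eh = 2625.4996 kJ mol⁻¹); lengths in Å; fractional coordinates
  wrapped to [0, 1); atom indexing 0-based.

## Structure handling

CIF parsing, symmetry-operator algebra and element data go through gemmi.
Both `_symmetry_equiv_pos_as_xyz` and `_space_group_symop_operation_xyz` are
accepted; a bare space-group name or number is resolved through gemmi's
tables; with no symmetry information at all, P1 is assumed and a warning
logged. Expanded sites are deduplicated at 1e-3 fractional (minimum image).

Molecules are perceived as connected components of a covalent bond graph:
atoms are bonded when their minimum-image distance is at most 1.2 × the sum
of tabulated covalent radii (the standard cheminformatics heuristic; the
scale is a parameter). Components are unwrapped across periodic boundaries
by accumulating integer lattice shifts along bonds; an atom bonding to its
own image, or an inconsistent unwrap, means a covalent network rather than a
molecular crystal and raises an error. Supercell construction replicates
sites with rescaled fractional coordinates — its purpose here is Z
equalization, e.g. doubling along the shortest axis so all polymorphs share
Z = 4 before per-cell vibrational comparisons.

Gas-phase fragment jobs for periodic codes are prepared by `embed_in_vacuum`,
which returns the smallest axis-aligned P1 box keeping every fragment atom at
least 15 Å (default) from all periodic images; the 15 vs 18 Å spacing
difference is worth ≲0.15 kJ mol⁻¹ in gas-phase energies, so 15 Å is treated
as converged.

A net cell dipole (estimated from optional per-atom point charges) is
detected and warned about — fragment lattice sums converge conditionally for
polar cells — but not corrected.

Dihedrals follow the IUPAC sign convention with range (−180°, 180°], and a
scan-grid helper reproduces the 16-point 0–150°/10° grid used for torsional
conformational profiles.

## Dispersion correction

Coordination numbers use the logistic counting function
CN_a = Σ_b 1/(1 + exp(−k1·(k2·(r_a+r_b)/R_ab − 1))) with k1 = 16,
k2 = 4/3. Reference C6 values are interpolated with Gaussian weights
exp(−k3·[(CN_a−CN_a,ref)² + (CN_b−CN_b,ref)²]), k3 = 4 by default; the
interpolant is a convex combination, so C6 always lies within the reference
range. C8 = 3·C6·√(Q_a·Q_b).

The damping family is selectable: Tang–Toennies
f_n(R) = 1 − e^{−bR}·Σ_{k≤n}(bR)^k/k! by default (evaluated through its
tail-series form below bR = 1 to avoid catastrophic cancellation), or a
rational Becke–Johnson-style form with R0 = √(C8/C6). Both satisfy the
required limits (→ 1 at large R; finite, and zero for Tang–Toennies, at
R → 0). The model's global empirical parameters — the damping vector and the
R⁻⁸ scaling — live in a structured data file rather than in code; the file
shipped with the package (`data/synthetic_dispersion_params.yaml`) is a
synthetic table for testing, clearly labelled as such, with invented
coefficients chosen only to exercise the interpolation, recursion and
damping code paths. Fitted physical parameter sets plug into the same
schema. Coefficient "flavors" are arbitrary labels; an MP2D-style correction
is the difference of the accurate-response and MP2-implicit-response sums,
reported with its exact intra/inter partition, and the engine equally serves
plain single-flavor D3-style sums.

No three-body (Axilrod–Teller) term and no analytic gradients are provided.

## Composite energetics

Two-point CBS extrapolation assumes E_corr(X) = E_CBS + A·X⁻³ and solves the
two-cardinal system exactly; the mean-field energy is not extrapolated but
taken at the larger basis. The exponent is fixed at 3 (overridable). The
delta-CCSD(T) composite adds a small-basis CCSD(T) − MP2 difference to
MP2/CBS; being additive it commutes with fragment assembly, which is tested.

Stability decompositions are reported relative to an explicitly named
reference polymorph, never an inferred one. ΔE_intra is the per-molecule
1-body difference; ΔE_inter collects pairwise 2-body plus the low-level
remainder, so ΔE_intra + ΔE_inter = ΔE_lattice exactly; when the many-body
term is available separately it is reported in its own column *and* left
folded into ΔE_inter, since published decomposition tables conventionally
fold everything intermolecular together. Error statistics against a
reference level report rms and mean signed deviation with the convention
that interaction energies more negative than the reference count as
overbound (negative mean).

## Harmonic thermochemistry

Standard harmonic-oscillator statistical mechanics per Γ-point mode,
normalized per molecule by Z: ZPE = Σ hcν̃/2, U_vib = Σ hcν̃/(e^x − 1),
S_vib = R·Σ[x/(e^x−1) − ln(1−e^{−x})] with x = hcν̃/k_BT. Physical constants
come from scipy (CODATA); hc·N_A = 11.96266 J mol⁻¹ cm, so one 100 cm⁻¹
mode carries 0.598 kJ mol⁻¹ of zero-point energy. The entropy log term is
evaluated as ln(expm1(x)) − x for x < 1 and log1p(−e^{−x}) above, which
keeps the identity S = −∂F/∂T accurate to better than 1e-6 relative even at
low temperature; modes with x > 700 are clamped (they contribute nothing but
would overflow). Negative (imaginary) input frequencies raise an error — the
structure is not a minimum. When a full 3N-mode Γ-point set is supplied, the
three acoustic zeros are removed as the three smallest-magnitude modes, and
any surviving mode below 5 cm⁻¹ draws a warning (thresholds are implementer
choices).

The Gibbs assembly G = U_el + F_vib + PV mixes a high-level electronic
energy with lower-level phonons; PV defaults to zero (negligible for a
crystal at ambient pressure) with a flag-equivalent: pass an explicit `pv`.

**Two-structure temperature model.** Thermal expansion is captured
approximately by computing everything twice: on fully relaxed cells (0 K
proxy) and on fixed experimental room-temperature cells with relaxed atomic
positions (298.15 K proxy), each with its own phonon set. ΔH(T) and ΔG(T)
between polymorphs are then straight lines through the two computed points;
values at other temperatures (default target 423 K, a 150 °C transition)
come from linear extrapolation, exact at the endpoints. A pair is classified
enantiotropic when its ΔG line crosses zero strictly inside (0, T_max]
— the stable form switches with temperature — else monotropic; the crossing
temperature is reported. The classification is invariant to swapping the
reference (signs flip, crossings do not). Because published stability tables
are typically printed at 0.1 kJ mol⁻¹, extrapolated values computed from
such inputs are only meaningful to roughly ±0.15 kJ mol⁻¹ of input rounding. This model deliberately neglects
quasi-harmonic volume optimization, phonon dispersion beyond Γ, and
large-amplitude/dynamic disorder.

## Synthetic fixtures: what they do and do not show

`fixtures` generates every input the pipeline needs with no external data:

- **Toy crystals** are rigid 1–2-atom Lennard-Jones species (ε in Eh, σ in
  Å) on a deterministic sublattice of a cubic cell with seeded jitter;
  ledgers are evaluated exactly under the pair potential, including the
  periodic energy as ΣE1 plus a brute-force intermolecular lattice sum. This
  makes the many-body-expansion bookkeeping *exactly* verifiable: assembly
  with high = low must reproduce the lattice sum and show a zero many-body
  term.
- **Polymorph pairs** share a geometry but carry engineered ledgers: every
  1-body energy of polymorph B is raised by the conformational penalty and
  its pairwise interactions lowered by the packing gain (the periodic energy
  shifted consistently), so the decomposition ground truth is known to
  machine precision.
- **Basis series** are exact E_CBS + A·X⁻³ forms; **frequency sets** are
  seeded uniform draws.

These fixtures validate bookkeeping, multiplicities, unit conversions and
the assembled arithmetic — not chemistry. Passing tests show the machinery
is exact on pairwise-additive surrogates; they say nothing about the
accuracy of any electronic-structure level on real crystals, about
hydrogen-bond physics, or about basis-set convergence of real fragment
energies, all of which enter through user-supplied ledgers.

Problem sizes used by the test suite and the acceptance script — toy cells
of 6–7 Å with Z ≤ 3, 20 crystals for the oracle comparison, 100 synthetic
basis series, 50 random frequency sets — were chosen as the smallest
fixtures that exercise every code path with non-trivial multiplicities.

## Known limitations

- No geometry optimization, space-group determination, or disorder handling.
- No three-body fragment terms, embedding charges, or counterpoise
  bookkeeping; the many-body physics is delegated entirely to the periodic
  low level.
- Polar cells (net dipole) are detected and warned about, not treated.
- Linear two-point temperature extrapolation cannot represent curvature in
  ΔG(T); classifications near a degenerate 0 K gap are sensitive to input
  rounding.
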