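# Methods

## Model

A solution is a list of solute molecules j with molar concentrations Cⱼ
(mol/L).  Each molecule carries a dissociation number gⱼ (particles per
molecule under the assumption of complete dissociation), an explicit
particle stoichiometry (ion species with integer charges, counts summing
to gⱼ), and an osmotic-coefficient specification Φⱼ.  Two concentration
functionals are defined on a solution alone:

- ideal total-particle concentration `C_TSP = Σⱼ gⱼCⱼ`, which equals the
  sum of the per-species particle view `Σᵢ Cᵢ` identically;
- non-ideal `C_TSP = Σⱼ gⱼ·Φⱼ(Cⱼ)·Cⱼ`.

A membrane assigns reflection coefficients σ ∈ [0, 1] (1 = impermeant,
0 = freely permeant), either per molecule or per particle species, with a
default for unlisted entries; `Membrane()` is the ideal water-only
membrane.  The membrane-dependent initial osmotic concentration of a
solution-vs-water system is computed by one of two conventions:

- molecule-based: `OC₀ = Σⱼ gⱼ·σⱼ·Φⱼ·Cⱼ` (the default — the only form in
  which σ and Φ combine consistently, since Φ is defined per molecule);
- particle-based: `OC₀ = Σᵢ σᵢ·Cᵢ`, which deliberately carries no Φ
  factor.  Combining per-particle σ with per-molecule Φ is not invented
  here; the particle convention is for ideal solutions with selective
  membranes.

Pressures follow `π = RT·OC₀` (unified law) and `π = θ·C_TSP·RT`
(extended law).  θ is a dimensionless, empirical, system-level
coefficient: it is only ever obtained by fitting — from a measured
pressure (`θ = π_exp/(RT·C_TSP)`) or from a measured corrected osmolar
activity (`θ = activity/C_TSP`) — and θ = 1 recovers the ideal law.  In
the extended forms C_TSP is the *ideal* particle sum: θ is the
non-ideality correction, so resolving Φ as well would count non-ideality
twice.

Composite systems (two solutions, one membrane) deconstruct into mirrored
solution-vs-water halves; the gradient is `Δπ = RT·(OC₀₁ − OC₀₂)`,
evaluated at t = 0 from initial concentrations.  Sign convention: Δπ > 0
means net water movement toward compartment 1, and every gradient result
names the receiving compartment explicitly.  Complex systems partition
per *molecule* (keeping dissociated ion pairs together) at a configurable
σ cutoff, default 0.95: molecules at or above the cutoff form the
pressure-generating osmosis subsystem, the rest an inventory-only
diffusion subsystem.  No flux or kinetics model is attached to the
diffusion side, and no time course is modelled anywhere — all quantities
are initial-state.

## Applicability check

The σ-summation forms presuppose that the membrane is exclusively
impermeable to all cations or to all anions.  When charged species of
both signs have σ < 1, paired electro-neutral diffusion undermines the
per-species bookkeeping; `electroneutrality_check` returns a WARN verdict
naming the permeant cations and anions.  It is a verdict, not an
exception, because the condition bounds applicability rather than
computability; membrane-potential feedback on single permeant ion species
is likewise out of scope.

## Parameters and units

| parameter | meaning | default |
|---|---|---|
| g | particles per molecule (complete dissociation) | 1 |
| Φ | per-molecule osmotic coefficient | 1 (ideal) |
| σ | reflection coefficient, per molecule/species | 1 (impermeant) |
| T | absolute temperature, K | 298.15 |
| R | gas constant in L·unit·mol⁻¹·K⁻¹ | CODATA value for the active unit |
| σ cutoff | complex-system classification threshold | 0.95 |

Internal units are mol/L and kelvin throughout; mM and mOsm/L are
accepted at I/O boundaries (CSV solute tables, the θ-fitting CLI) and
converted by a factor of 1000.  Pressure units are bar, mmHg and atm with
exact conversion factors (1 atm = 101325 Pa, 1 mmHg = 1 torr =
101325/760 Pa).  Concentration-dependent Φ is supported as a user-supplied
(C, Φ) table resolved by piecewise-linear interpolation between bracketing
rows; out-of-range concentrations raise rather than extrapolate.  Each
molecule's Φ is resolved at that molecule's own concentration — a stated
limitation, since in mixed electrolytes the coefficients actually depend
on total ionic strength, which this model does not represent.

## Embedded validation datasets and rounding conventions

Two small published datasets are embedded for validation and regression:

1. **Sucrose osmometry** (Minkov et al. 2013, constant-volume
   measurements at 22 °C; six concentrations 0.050–0.300 mol/L).  The
   source used R = 0.08314 L·bar·mol⁻¹·K⁻¹ and T = 295.15 K.  The
   validation layer recomputes π_pred = RT·C (3 dp), the signed error
   π_exp − π_pred (3 dp), Φ = π_exp/(RT·C) (3 dp) and OC₀ = σ·Φ·C with
   σ = 1 (4 dp, formed from the 3-dp Φ, because that is how the printed
   table was built).  With the *unrounded* product RT = 24.538771 every
   printed cell reproduces exactly, ties rounded half-up.  If RT is first
   rounded to its quoted display value 24.54, the 0.050-row Φ lands on
   0.896 instead of the printed 0.897 (and OC₀ on 0.0448 vs 0.0449); the
   report documents this convention sensitivity in its notes.
2. **Body fluids** (Guyton & Hall, *Textbook of Medical Physiology*,
   table 25-2: plasma, interstitial and intracellular fluid at 37 °C;
   R = 62.3637 L·mmHg·mol⁻¹·K⁻¹, RT/1000 = 19.3421 mmHg per mOsm/L).
   Recomputed: θ = activity/C_TSP (4 dp), π_pred and π_corr (nearest
   integer mmHg), absolute and relative errors formed from the rounded
   integers.  Plasma and interstitial columns match print in full.  Four
   intracellular cells do not follow from the printed inputs under any
   rounding order — printed θ 0.9330 vs recomputed 0.9329, π_pred 5824 vs
   5826, absolute error 389 vs 391, relative error 6.68% vs 6.71% — and
   are flagged as known discrepancies, excluded from the pass criterion
   rather than silently matched.  Their provenance (possibly unrounded
   upstream inputs) cannot be recovered from the printed table.

Rounding is never applied inside the computational core; it exists only
in this validation/report layer, where it mirrors each table's display
convention so computed and printed cells are comparable.  Built-in
`round` (banker's) is avoided in favour of half-up, which is what printed
half-way cells (0.04485 → 0.0449) follow.

## Randomised testing

Property tests (hypothesis, derandomised profile; plus seeded
numpy-generator loops) cover: particle-count conservation between the
molecule and particle views; homogeneity of C_TSP in concentration;
reduction of the non-ideal to the ideal sum at Φ = 1; agreement of the
two OC₀ conventions when Φ = 1 and σ is uniform within each molecule;
OC₀ ≤ ideal C_TSP whenever σ, Φ ≤ 1; antisymmetry of the composite
gradient under compartment swap and its equality with the difference of
the mirrored simple-system pressures; exhaustive/disjoint partition by
`split_complex`; θ round-trip recovery through the extended law to
1e-12 relative on 1000 random (θ, C_TSP, T) triples; and unbiased mean θ
recovery (within 0.5%) under 1% multiplicative pressure noise at
N = 1000.  Generated systems use up to four random solutes (mixtures of
nonelectrolytes and 1:1/2:1 salts), concentrations up to 1 mol/L and
Φ ∈ (0.05, 1] — the dilute regime the laws are valid in.  These synthetic
systems exercise the algebra and invariants; they do not emulate
solute–solute interactions, ionic-strength-dependent Φ, protein oncotic
behaviour or membrane-potential dynamics, so passing them says nothing
about those effects in real fluids — that is what the two embedded
measured datasets are for, within their own limits (a single solute
series, and three bulk fluid compartments).

## Design choices and limitations

- Complete dissociation is assumed; partial dissociation equilibria,
  Debye–Hückel/Pitzer activity theory, and Donnan or virial oncotic
  models are out of scope.
- A dissociable molecule read from CSV without per-ion detail receives a
  single neutral pseudo-species carrying its g particles: particle totals
  and molecule-based OC₀ are unaffected; only per-ion σ assignment and
  the electroneutrality check need explicit species rows.
- The σ cutoff defaulting to 0.95 reflects that "negligible permeability"
  has no canonical threshold; it is a parameter, not a claim.
- Whether a composite gradient should be evaluated at t = 0 or after
  permeant solutes relax is ambiguous when σ < 1; the package computes
  the t = 0 gradient from OC₀ as defined and says so in its outputs.
- Any possible anti-osmotic action of the permeant fraction is
  represented nowhere: the diffusion subsystem is inventory only.
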