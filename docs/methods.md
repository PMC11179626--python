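# Methods

## Scientific setting

Human serum albumin (HSA) carries both Zn²⁺ (a high-affinity site A at
the domain I/II interface and a weaker site B) and long-chain fatty
acids (sites FA1–FA7). Occupation of the FA2 site, which spans the
domain I/II interface, allosterically disables site A: the protein must
adopt a "closed" arrangement of domains I and II to form the site, and a
fatty acid lodged in FA2 sterically blocks that closure. `allofit`
implements the two quantitative workflows needed to study this switch:

1. **ITC occupancy analysis** — equilibrium sets-of-sites modelling of
   isothermal titration calorimetry (ITC) data, including a global fit
   across a panel of isotherms in which the thermodynamic constants are
   shared and only the occupancy Θ of the high-affinity site varies per
   isotherm (per fatty-acid load).
2. **Conformational free energy** — a steered-pulling → umbrella-
   sampling → WHAM protocol along collective variables (CVs), with the
   CV geometry usable on real protein coordinates and the sampling
   engine running on analytic landscapes at desk scale.

## Binding model

The cell contents are modelled as a macromolecule M with independent
classes of identical sites. Class *i* (stoichiometry `nᵢ`, association
constant `Kᵢ` in M⁻¹, molar enthalpy `ΔHᵢ` in J/mol of sites) saturates
as `θᵢ = Kᵢx/(1+Kᵢx)` at free ligand concentration `x`, and mass balance

    x_total = x + m_total Σᵢ nᵢ θᵢ(x)

fixes `x` uniquely on `[0, x_total]` because the left side is strictly
increasing. The root is found by bracketed Brent iteration (globally
convergent, machine-precision termination) and verified against the
mass-balance residual at relative tolerance 1e-12 (default). Binding
constants are concentration-based; activity corrections, proton linkage
and ion competition are out of scope — the model therefore yields
*apparent* ITC constants, as is standard for this experiment. The
independent-classes family matches the "sets of sites" models of the
common ITC fitting packages; cooperative or stoichiometric-series
schemes are deliberately not implemented. All internal units are SI
(mol/L, L, J); kcal/mol appears only at presentation.

## Titration simulation

The synthetic stage emulates a perfusion-cell instrument (VP-ITC
family): the cell stays full and each injection displaces cell contents.
After cumulative injected volume `ΔV`, with cell volume `V`:

    m_total = m₀ (1 − ΔV/2V) / (1 + ΔV/2V)
    x_total = x_syr (ΔV/V) / (1 + ΔV/2V)

and the heat of injection k is

    q_k = Q_k − Q_{k−1} + (dV_k/V)(Q_k + Q_{k−1})/2 + q_dil ,

where `Q = V m_total Σ nᵢθᵢΔHᵢ` is the cell heat content and `q_dil` a
constant per-injection dilution offset (the in-model counterpart of a
blank-subtraction residual). This is the Origin-style displacement
bookkeeping; the exact-exponential dilution alternative was rejected for
fidelity to the software family the field uses. The first injection is
kept in simulation; fitting offers an exclude-first flag.

**Default study conditions** (the generator's fixed design):

| quantity | default | note |
|---|---|---|
| Zn²⁺ titration | 1.5 mM into 50 µM albumin | 35 injections: 2 µl + 34×8 µl |
| fatty-acid titration | 500 µM myristate into 12.5 µM albumin | same schedule |
| cell volume | 1.4 mL | VP-ITC nominal; configurable |
| temperature | 25 °C | isothermal; ΔCp out of scope |
| Zn²⁺ model | N₁=1, K₁=2.9×10⁵ M⁻¹; N₂=2, K₂=2.5×10⁴ M⁻¹ | one high-affinity site + a set of two weaker sites |
| Zn²⁺ enthalpies | ΔH₁=−12 kJ/mol, ΔH₂=−30 kJ/mol | chosen once as realistic exothermic values of distinct magnitude (the printed sources report only K and N); magnitudes give heats of tens of µcal per 8 µl injection, typical for this titration |
| myristate model | N=2/1/4, K=1.76×10⁶ / 3.91×10⁵ / 3.11×10⁴ M⁻¹ | enthalpies −20/−15/−8 kJ/mol, all exothermic as observed for fatty-acid binding |
| noise | i.i.d. Gaussian, sd = 1% of the largest \|heat\| | simplest model supporting recovery studies |

These closed forms give a final molar ratio of 6.51 for the Zn²⁺
design (274 µl of 1.5 mM titrant into 1.4 mL of 50 µM protein),
consistent with isotherm x-axes that extend well past 5 mol. eq.

What the generator does **not** emulate: baseline drift and peak
integration of raw power traces, injection kinetics, temperature-
dependent enthalpies, correlated noise, and titrant impurity or active-
fraction errors. Recovery tests on these synthetics therefore
demonstrate the *estimator's* correctness and precision under the
stated noise model, not robustness to instrument systematics.

## Fitting

Single-isotherm fits minimize the unweighted sum of squared heat
residuals with bounded trust-region least squares (lmfit/SciPy).
Association constants are fitted internally as log₁₀K for conditioning
(a linear-K option exists and agrees to 1e-4 relative). Parameters can
be fixed, bounded, or (in global fits) shared; the default multi-start
count is 8 seeded perturbed restarts, with the best-SSR solution
returned and the restart SSR spread recorded. Standard errors come from
the Jacobian at the optimum, with a seeded residual-bootstrap
alternative (`bootstrap_standard_errors`) for when the Gaussian noise
model is in doubt; pairs of free parameters with |r| > 0.95
are flagged rather than silently reported (the two Zn²⁺ classes overlap
enough that e.g. N₁/N₂ correlations near the threshold are common).
χ² is reported as plain SSR and SSR/(n_obs − n_free); no per-point
weighting, since per-point σ are not available for this data class.

The global fit stacks all isotherm residuals into one vector; K and ΔH
are shared, stoichiometries fixed by convention (N₁ = 1, N₂ = 2 — "one
set of one high-affinity site and another set of two weaker sites", one
ΔH per class), and each isotherm gets its own occupancy Θᵢ multiplying
N₁, bounded to [0, 1.5]: values above 1 are allowed so that model
misfit shows up in the estimate instead of being clamped away. With a
single isotherm the global fit degenerates (with a warning) to a single
fit with Θ in the role of N₁.

Replicate studies (the 200-seed K₁ bias check) use the field's standard
strategy of fixing stoichiometries and one restart from a displaced
start; with all six two-class parameters free, K₁ is too weakly
identified at 1% noise for a per-replicate point estimate to be
meaningful (the fit then reports it through wide standard errors and
correlation flags instead). Problem sizes — 35 injections, 12-isotherm
panels, 200 replicates — mirror the study design.

## Free-energy protocol

CVs are distances (nm), planar angles ([0°, 180°]) and dihedrals
((−180°, 180°], signed atan2 convention) over mass-weighted centers of
named atom groups. Groups are selected from PDB coordinates
(chain/residue-range/atom-name, first-listed altloc conformer, element
masses from the parser); the shipped selections over the HSA domain
ranges (I ≈ 1–195, II ≈ 196–383, III ≈ 384–585) are illustrative
placeholders, because the authoritative atom-group definitions, pulling
rates and force constants for the eight restraints (D1–D4, P1, R1–R3)
live in supplementary material not reproduced here — they stay
configurable, with no defaults asserted as authoritative. Backbone RMSD
uses Kabsch superposition; a transition is considered complete when the
backbone RMSD to the closed reference drops below 0.25 nm.

The sampling engine is overdamped Euler–Maruyama Langevin dynamics in
reduced units (kT = 1), bit-reproducible per seed. It is a desk-scale
embodiment of the *protocol*, not of the molecular system: per-window
all-atom sampling is cluster-scale, so analytic landscapes with known
Boltzmann profiles stand in for the force field, making the whole chain
(steer → select windows → sample → WHAM → read-out) verifiable against
closed forms. Steered pulling applies a moving harmonic restraint and
accumulates work `W = Σ k(c_t − x_t)Δc`. Window selection sweeps the
window count from 28 upward (39 at most, the study's range) over evenly
spaced centers, runs a short seeded equilibration per window, and
accepts the first count whose adjacent histogram intersections all meet
the overlap target (default 0.1); an unreachable target raises an
infeasibility report suggesting a softer spring.

WHAM iterates the standard self-consistent equations on shared bins
(default 200 bins, tolerance 1e-8 kT on max|Δf|, 10⁵ iteration cap,
f₁ ≡ 0 anchor), with periodic minimum-image bias distances and bin
topology for dihedrals. Empty interior bins are reported as NaN gaps,
never interpolated. Profiles are shifted so the minimum is zero; the
closed-state read-out linearly interpolates ΔG at a target CV value and
refuses extrapolation. Relative ΔG between systems subtracts a named
reference system's read-out; a "total" over several CVs is a simple sum,
ignoring correlations between CVs.

Numerical choices that matter: Euler–Maruyama is stable only for
`dt < 2·friction/U''max` — the engine raises an explicit unstable-step
error if the trajectory leaves the landscape domain; its stationary
variance on a harmonic well carries an O(κ·dt/2) relative bias, so
validation runs use `κ·dt ≲ 0.05`. Histogram-overlap vetting uses 50
shared bins and the min-sum intersection, a scale-free measure in
[0, 1].

## Verification strategy

Every operation is checked against an independent oracle: the one-class
quadratic in stable (citardauq) form and a 1e-12 bisection bracket for
the solver; hand-evaluated closed forms for the dilution bookkeeping;
stoichiometric-limit and no-binding limits for simulated heats;
noiseless round-trip identity and seeded noisy-replicate statistics for
the fits; rotation-matrix re-implementation for dihedrals; equipartition
and quasi-static work identities for the Langevin engine; Boltzmann
closed forms (harmonic, discrete two-state, 5 kT double well) for WHAM.
`scripts/acceptance.py` recomputes the headline quantities of both
pipelines from scratch under a caller-supplied seed.

## Known limitations

- Apparent constants only; no competition/linkage corrections, so K
  values are condition-specific as in any uncorrected ITC analysis.
- Unweighted residuals treat every injection as equally informative.
- The identifiability of overlapping site classes is intrinsically poor;
  the package surfaces this (correlation flags, wide CIs) but cannot
  remove it.
- The free-energy module quantifies protocol correctness on analytic
  landscapes; transferring conclusions to a real protein requires the
  cluster-scale molecular sampling that is out of scope here.
- 1-D WHAM only; per-CV profiles are combined by simple summation.
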