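# allofit

Quantitative analysis of the fatty-acid/Zn²⁺ switch on human serum
albumin (HSA): equilibrium **sets-of-sites ITC model fitting** — single
isotherms and global panels with shared thermodynamics and per-isotherm
site occupancy — plus a desk-scale **steered-pulling / umbrella-sampling
/ WHAM** free-energy protocol with collective-variable evaluation on
protein structures.

Albumin binds Zn²⁺ at a high-affinity interdomain site (site A) and
long-chain fatty acids at sites FA1–FA7. A fatty acid bound in the FA2
site blocks the domain closure that forms site A, so rising fatty-acid
levels switch plasma zinc away from albumin. The package is for
biophysicists who want to (a) fit isothermal titration calorimetry
(ITC) data with independent classes of sites, including the global
"shared K/ΔH, floating occupancy Θ" analysis that quantifies how much
of the high-affinity site survives each fatty-acid load, and (b)
exercise the free-energy protocol that rationalizes the switch.

## Model

The cell holds macromolecule M (total `[M]`) with independent site
classes; class *i* has stoichiometry `Nᵢ`, association constant `Kᵢ`
(M⁻¹) and enthalpy `ΔHᵢ`. At free ligand `x`,

    θᵢ = Kᵢ x / (1 + Kᵢ x),      [X]ₜ = x + [M]ₜ Σᵢ Nᵢ θᵢ ,

and the heat after injection k in a perfusion cell of volume V is

    qₖ = Qₖ − Qₖ₋₁ + (dVₖ/V)(Qₖ + Qₖ₋₁)/2 + q_dil ,
    Q  = V [M]ₜ Σᵢ Nᵢ θᵢ ΔHᵢ .

Fits minimize Σₖ(qₖ^obs − qₖ^model)²; global fits share K/ΔH across a
panel while the occupancy Θᵢ of the highest-affinity class floats per
isotherm. Free-energy profiles come from the weighted-histogram
analysis (WHAM) self-consistent equations over harmonic umbrella
windows along a collective variable, with the closed-state read-out
ΔG(CV_target) taken relative to a reference system. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Recover the occupancy decline of the high-affinity site from a
synthetic 12-isotherm panel (six "wild-type" isotherms with occupancy
descending 1 → 0.1 across a fatty-acid series, six "FA2-knockout"
isotherms with occupancy 1, 1% heat noise):

```python
import numpy as np
from allofit import make_synthetic_panel, fit_global, occupancy_vs_condition, ParameterSpec
from allofit.binding import BindingModel, SiteClass

theta = list(np.linspace(1.0, 0.1, 6)) + [1.0] * 6
meta = [{"condition": "WT", "fa_mol_eq": i} for i in range(6)] + \
       [{"condition": "FA2-KO", "fa_mol_eq": i} for i in range(6)]
panel = make_synthetic_panel(seed=42, theta_schedule=theta, metadata=meta)

start = BindingModel([SiteClass(1.0, 1e5, -8e3), SiteClass(2.0, 1e4, -2e4)])
specs = [ParameterSpec("n1", 1.0, fixed=True), ParameterSpec("n2", 2.0, fixed=True)]
result = fit_global(panel, start, specs)

print(f"K1 = {result.shared['k1'].value:.3g} M^-1, "
      f"K2 = {result.shared['k2'].value:.3g} M^-1")
print(occupancy_vs_condition(result, meta, key="condition", sort_key="fa_mol_eq")
      .to_string(index=False))
```

prints

```
K1 = 2.83e+05 M^-1, K2 = 2.5e+04 M^-1
condition  fa_mol_eq    theta  theta_se
       WT          0 0.990440  0.010779
   FA2-KO          0 1.005758  0.010817
       WT          1 0.819598  0.010323
   FA2-KO          1 1.005811  0.010817
       WT          2 0.646773  0.009779
   FA2-KO          2 1.000121  0.010803
       WT          3 0.456097  0.009041
   FA2-KO          3 1.010111  0.010827
       WT          4 0.275047  0.008157
   FA2-KO          4 0.997967  0.010797
       WT          5 0.102259  0.007150
   FA2-KO          5 0.998456  0.010799
```

The shared constants come back within a few percent of the generating
values (K₁ = 2.9×10⁵ M⁻¹, K₂ = 2.5×10⁴ M⁻¹), the wild-type arm's
occupancy falls monotonically with fatty-acid load, and the knockout
arm stays at Θ ≈ 1 — the signature of a disabled fatty-acid site
leaving zinc binding intact.

The same analysis is scriptable from the shell (`allofit simulate`,
`allofit fit`, `allofit globalfit`), and the free-energy pipeline is
available as `allofit pull`, `allofit umbrella`, `allofit wham`,
`allofit profile-diff`, with `allofit cv-eval` evaluating dihedral /
planar-angle / distance collective variables defined in YAML on a PDB
structure.

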