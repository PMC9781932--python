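# cosolv

Co-solvency modelling and green-solvent screening for drug-like solutes
in neat and binary aqueous–organic solvents.

Finding a solvent mixture that dissolves an active pharmaceutical
ingredient well — and is environmentally acceptable — is a screening
problem: far more candidate solvents and compositions exist than anyone
can measure. `cosolv` implements a complete computational screening
pipeline for this problem, exercised here on the two aromatic amides
acetaminophen (paracetamol) and phenacetin:

1. **Thermodynamic curation models.** Temperature series in a neat
   solvent are fitted with the Buchowski–Ksiazczak (λh) equation

   ln[1 + λ(1 − x)/x] = λ·h·(1/T − 1/T_m),

   and composition–temperature surfaces in binary solvents with the
   Jouyban–Acree model

   ln x₁ = x₂\*·ln x₂ˢᵃᵗ + x₃\*·ln x₃ˢᵃᵗ + (x₂\*x₃\*/T)·Σᵢ Jᵢ(x₂\*−x₃\*)ⁱ,

   where x₂\* is the solute-free fraction of the organic component.
   Literature data are curated in exactly two passes: fit, drop points
   whose percentage error against the back-computed curve exceeds 10%,
   refit.

2. **σ-profile descriptors.** From COSMO-type screening-charge
   histograms P(σ) the package solves the self-consistent σ-potential
   μ_s(σ), derives hydrogen-bond acceptance / donation / hydrophobicity
   band descriptors (HBA, HBD, HYD), relative misfit / H-bond /
   dispersion energy shares ΔE_j (closing to 1), and an iterative
   saturation-solubility estimate anchored by the fusion properties
   ΔG_fus(T) = ΔH_fus(1 − T/T_m). Compositions where the solver escapes
   to complete miscibility are repaired by linear ln x extrapolation.

3. **Gated ensemble of shallow networks.** Many single-hidden-layer
   networks map the 8-descriptor vector to log₁₀ x. After a 70/15/15
   split, a candidate joins the ensemble only if, on validation, RMSD
   < 0.06, outliers (|standardized residual| > 3) ≤ 2% and ≥ 99% of
   predictions are physical (log₁₀ x ≤ 0). Predictions are the
   unweighted member mean, guarded by a range-box + leverage
   applicability domain (h\* = 3(p+1)/n).

4. **Green screening.** Candidate aqueous binaries are swept over a
   composition grid, ranked by predicted solubility at 25 °C under a
   strict environmental-index filter (EI < 0.5), and each predicted
   surface is re-expressed as Jouyban–Acree parameters for use without
   the model.

The measured solubility table for acetaminophen/phenacetin in aqueous
DMSO, DMF and 4-formylmorpholine ships as a fixture
(`cosolv.load_table1()`), as do the fusion constants and EI metadata.
Synthetic generators (`cosolv.synth`) provide σ-profiles and datasets
with known ground truth for everything else.

## Worked example

```python
import cosolv as cv

table = cv.load_table1()
system = table.filter(solute_id="acetaminophen", solvent1_id="DMSO")
a2 = cv.NeatAnchor.from_records(system.filter(x2_star=1.0))
a3 = cv.NeatAnchor.from_records(system.filter(x2_star=0.0))
params, stats = cv.jouyban_acree_fit(system, a2, a3)
print(params.j, stats["mape"])
```

Running `python examples/01_fit_cosolvency_models.py` prints

```
Jouyban-Acree fit, acetaminophen in aqueous DMSO
  J0 =    2651.4 K
  J1 =   -2243.3 K
  J2 =    2017.4 K
  back-fit MAPE = 13.1% over 16 mixed points
  measured optimum at 25 degC: x2* = 0.8, log10 x = -0.50
```

J₀ > 0 is the co-solvency signature: the 80:20 DMSO/water mixture
dissolves more acetaminophen (log₁₀ x = −0.50) than neat DMSO. The
other scripts in `examples/` walk through curation, σ-descriptors, the
saturation solver, ensemble training and the screening driver, each
printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:
`cosolv curate|descriptors|cosmo-solubility|train|predict|screen|simulate`
(see `cosolv --help`).

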