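# Methods

This note records the models implemented in `cosolv`, their
assumptions, the defaults that matter, and the design choices made
where the problem was genuinely open.

## Thermodynamic models and curation

**λh (Buchowski–Ksiazczak).** The implicit relation
ln[1 + λ(1−x)/x] = λh(1/T − 1/T_m) is solved for x ∈ (0, 1] by
bisection; the left side is strictly decreasing in x, so the bracket is
guaranteed and the returned root has residual < 1e−12. The model passes
through the pure-melt point x = 1 at T = T_m by construction. λ (> 0,
dimensionless) reflects solute association; h (K) the dissolution
energetics. Fitting minimises squared residuals in **log₁₀ x**, not in
x: the datasets this model serves span roughly four orders of magnitude
of solubility, and linear-scale least squares would fit only the most
soluble points. MAPE is still reported on the linear scale. The λ = 1
special case collapses to the closed van't Hoff-type form
x = exp(−h(1/T − 1/T_m)), which doubles as the fit oracle in the tests.

**Jouyban–Acree.** With the neat-solvent anchors ln x₂ˢᵃᵗ(T),
ln x₃ˢᵃᵗ(T) fixed, the model is linear in (J₀, J₁, J₂); the fit is
plain linear least squares on the excess transform
y = [ln x₁ − x₂\* ln x₂ˢᵃᵗ − x₃\* ln x₃ˢᵃᵗ]·T/(x₂\*x₃\*) against the
basis {1, (x₂\*−x₃\*), (x₂\*−x₃\*)²}. At least three distinct mixed
compositions are required (basis rank). A single pooled J set is fitted
across temperatures — T appears explicitly in the model, and pooling is
the reading most consistent with that. Anchors at arbitrary T come from
a λh fit of the neat records when a melting temperature is supplied,
otherwise from a linear fit of ln x against 1/T.

**Two-pass curation.** Pass 1 fits all records; records with linear-
scale percentage error *strictly* above the threshold (default 10%; a
point at exactly the threshold is retained) are excluded; pass 2 refits
on the remainder. The procedure never iterates further: a `stable` flag
records whether a hypothetical third pass would have excluded more,
instead of looping. Retained ∪ excluded always partitions the input.

## σ-profiles, σ-potentials and descriptors

Profiles live on a fixed uniform grid σ ∈ [−0.035, 0.035] e/Å², step
0.001 (71 bins) — wide enough to contain the descriptor bands with
margin. File input is two-column text rebinned conservatively through
the cumulative-area curve, so total surface area is preserved for any
input spacing. Mixtures are mole-fraction-weighted bin sums.

Contact energies are carried **per contact segment** of area a_eff;
with that convention the σ-potential self-consistency reads

μ(σ) = −RT·ln Σ_σ′ P̂(σ′)·exp{[μ(σ′) − e(σ,σ′)]/RT},

(the a_eff/RT of per-area formulations cancels), solved by successive
substitution with damping 0.5 from μ = 0. Convergence is declared when
the geometric estimate of the *remaining* distance to the fixed point —
last update × ρ/(1−ρ) with ρ the observed contraction — falls below
0.25·tol·RT (tol = 1e−8 by default, max 500 iterations). This makes the
guarantee about the converged value rather than the last step, so
halving tol can move the answer by at most tol·RT. For a single-bin
profile the equation collapses to the closed form
μ(σ) = a_eff(α′/2)σ², used as an exact oracle.

The energy decomposition follows the standard three-term split:

- misfit E_MF = a_eff(α′/2)(σ+σ′)² ≥ 0;
- hydrogen bond E_HB = a_eff·c_hb·min(0, σ_don+σ_hb) when the acceptor
  patch exceeds +σ_hb, else 0 (≤ 0 always). The acceptor-side condition
  acts as a gate and the donor excess sets the magnitude; a variant in
  which donor and acceptor excesses multiply is available as
  `hb_variant="product"`. The gated form is used because it alone makes
  neutral–neutral contacts non-bonding while preserving the hand-worked
  value −0.0115 e/Å² for a (−0.02, +0.02) contact at σ_hb = 0.0085;
- dispersion E_vdW = 2·a_eff·τ_vdw, independent of σ.

Default parameters (a_eff = 6.25 Å², α′ = 3000 kJ mol⁻¹(e/Å²)⁻²,
c_hb = 80 kJ mol⁻¹(e/Å²)⁻¹, σ_hb = 0.0085 e/Å², τ_vdw = 0) are
configuration chosen for plausible kJ/mol magnitudes at typical
polarities, not claims about any proprietary parametrisation; every
value is overridable through `CosmoParameterSet`.

**Affinity descriptors.** Band means of μ over HBA = [−0.03, −0.01],
HBD = [0.01, 0.03], HYD = [−0.01, 0.01] e/Å². The solute potential is
σ-inverted (μ(−σ)) so its donor face is scored against the solvent's
acceptor band and vice versa; descriptors are solute-inverted minus
solvent differences. The solvent-side potential is computed for the
solute-free mixture — the infinite-dilution limit. Band *means* rather
than band areas keep the units clean; with fixed-width bands the two
differ by a constant factor.

**Energy descriptors.** Per component, shares ΔE_j = E_j/Σ_j E_j close
to 1 wherever the denominator is nonzero (a zero denominator is flagged
and the shares set to 0). Mixture values are mole-fraction-weighted
component sums; E_tot is the weighted total contact energy. The first
slot of the 8-vector is the computed log₁₀ solubility; the full order
is [log10x_cosmo, HBA, HBD, HYD, dE_tot, dE_HB, dE_vdW, dE_misfit],
min-max normalised per training set before modelling (dE_tot is carried
raw and normalised like every other column).

## Saturation solubility

The solid–liquid condition ln(γx) = −ΔG_fus/RT uses
ΔG_fus(T) = ΔH_fus(1 − T/T_m) — the standard no-ΔCp approximation,
consistent with having only T_m and ΔH_fus (acetaminophen: 442.2 K,
26.90 kJ/mol; phenacetin: 408.1 K, 30.70 kJ/mol). The guard
max(0, ΔG_fus) keeps above-melting inputs from producing a negative
melting penalty. ln γ of the solute is the band integral
(A_solute/a_eff)·ΣP̂_solute(σ)[μ_mix(σ) − μ_solute(σ)]/RT — residual
term only, no combinatorial contribution. This is deliberate: the
estimate feeds the model as a *descriptor*, where rank consistency
across solvents matters and absolute accuracy does not. The iteration
starts at x = 1e−4 with damping 0.5 in ln x, rebuilds the saturated-
mixture profile (including the current solute fraction) each cycle, and
stops at |Δln x| < 1e−8. An update that would push ln x ≥ 0 terminates
with a complete-miscibility flag instead of a saturation point. Flagged
points on a composition sweep are replaced by the least-squares line
through the last five preceding valid points in ln x vs x₂\*; unflagged
points are returned bit-exactly.

## Ensemble model

The base learner is a deliberately small numpy network — one hidden
layer (fixed), tanh/logistic/rectifier activations, squared or absolute
loss, Adam, minibatch 32, early stopping monitored on the *test*
subset (patience 60, max 800 epochs), every stochastic step driven by
the config seed so retraining is bit-identical. A hand-rolled learner
was chosen because the contract requires the absolute-loss option and
early stopping against a caller-supplied subset, neither of which the
usual library regressors expose.

Splitting is 70/15/15 (train/test/validation) with floor-sized test and
validation and the remainder to train. Normalisation is per-descriptor
min-max from the training subset only, frozen into the model.

Admission is the exact conjunction: validation RMSD < 0.06 log units
(strict), outlier rate ≤ 2% with outlier := |standardized residual| >
3, and reliability ≥ 99%. Reliability is read as "the prediction is an
admissible mole fraction", i.e. log₁₀ x ≤ 0 — the formal-range wording
this gate descends from is internally inconsistent (a log mole fraction
cannot lie between 0 and 1), and physical admissibility is the
interpretation that makes the gate meaningful. Aggregation is the
unweighted member mean, which keeps every ensemble prediction inside
the member envelope. The applicability domain combines a normalised
range box (margin configurable, default 0) with leverage
h = x'(X'X)⁻¹x against h\* = 3(p+1)/n; a singular training matrix
degrades the check to the box alone, flagged in the diagnostics. The
full hyperparameter pool is hidden ∈ {4, 8, 12, 16, 24, 32} ×
{tanh, logistic, rectifier} × {squared, absolute} × 10 seeds (360
candidates); tests and the acceptance script use small explicit pools
(typically 6 candidates, hidden 16/24, tanh, squared) and 600-row
tables, sizes chosen so the whole pipeline runs comfortably on one CPU
while still exercising every gate.

## Screening

Candidates are swept on x₂\* ∈ {0, 0.05, …, 1} at reference temperature
298.15 K. Each surface is re-expressed as Jouyban–Acree parameters by
anchoring on the *predicted* neat endpoints (endpoint reproduction is
then exact by construction) and regressing J on the in-domain mixed
points; the back-fit MAPE is reported alongside. The EI filter is a
strict inequality (EI < 0.5), so a candidate at exactly 0.51 — or
0.50 — is excluded; EI values are consumed as user metadata, never
computed. Ranking sorts by maximum in-domain predicted log₁₀ x at the
reference temperature, ties broken by lower EI; candidates lost to the
filter, to missing EI, or to a fully out-of-domain surface are logged,
never silently dropped. Water miscibility is deliberately not checked
(fatty-acid-type false positives are a known failure mode of solubility
ranking); the output carries a free-text warning column instead.

## Synthetic data

Generators are pure functions of (spec, seed). σ-profiles are
non-negative Gaussian mixtures rescaled exactly to the prescribed total
surface area; the water-like preset has narrow polar wings at ±0.016
e/Å², the alkane-like preset is a single neutral peak, and the default
solute emulates an aromatic amide (donor peak, acceptor peak, large
apolar bulk) — qualitative shapes only, no claim of matching DFT-derived
profiles. Solubility datasets are drawn from known λh or JA parameters
with multiplicative log-normal noise (mean-preserving; CV as specified)
because measured uncertainties scale roughly with magnitude; planted
outliers are 1.5× multiplications (~50% percentage error, far beyond
the 10% curation threshold). Descriptor tables are uniform in [0,1]⁸
with a named smooth target mapping into physical log₁₀ x ≤ 0 values
plus Gaussian noise (default SD 0.03 log units — the level at which the
0.06 RMSD admission gate is attainable but not trivial).

What passing on synthetic data shows — and does not. Parameter
recovery, curation recovery, gate fidelity and solver oracles verify
the *machinery* exactly. They do not certify predictive accuracy on
real measurements: real σ-profiles, real activity coefficients and
real literature noise are all richer than the generators. The shipped
84-record measurement table provides the package's only contact with
real data (anchor log-solubilities, co-solvency optima, and a
back-fit MAPE of ~13% for the three-parameter JA model on the DMSO
surface, whose water endpoint lies four orders below the optimum).

## Numerical choices and limitations

- λh fitting parameterises λ = exp(θ) to enforce positivity;
  Levenberg–Marquardt from (λ=1, van't Hoff h).
- Ties at the curation threshold retain the record (strict >).
- The σ-potential and saturation solvers are deterministic; no
  randomness exists outside explicitly seeded generators.
- Quantum-chemical σ-profile generation, proprietary COSMO
  parametrisations, conformer weighting and combinatorial activity
  terms are out of scope; σ-profiles are inputs.
- The saturation estimate is qualitative by design (descriptor duty);
  its miscibility flag triggers at ln x ≥ 0 proposals, which is
  conservative for strongly favourable synthetic solvents.
- EI provenance (including any adjustment such as excluding a
  photochemical contribution) belongs to the metadata notes column,
  not to the code.
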