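# oxiqspr

Quantitative structure–property modelling and kinetic measurement of
**antioxidant activity**, expressed as log₁₀ k₇ — the rate constant
(L·mol⁻¹·s⁻¹) of oxidation-chain termination by reaction of a substrate
peroxyl radical RO₂• with an antioxidant molecule InH.  The package is aimed
at physical-organic chemists and QSPR modellers who (a) determine k₇ from
oxygen-uptake experiments on initiated radical-chain oxidation and (b) build
descriptor-based consensus regression models to predict log k₇ for new
phenolic antioxidants.

## What it computes

**Kinetics.**  For AIBN-initiated oxidation in the kinetic regime, the
quasi-steady-state treatment of inhibited chain oxidation gives the
dimensionless inhibition parameter

    F = V₀/V − V/V₀ = f·k₇·[InH] / √(2k₆·Vᵢ)

where V₀ and V are the uninhibited and inhibited initial oxygen-uptake
rates, 2k₆ is the quadratic peroxyl–peroxyl termination constant and Vᵢ the
initiation rate (Vᵢ = 2e·kₚ·[AIBN], log₁₀ kₚ = 17.70 − 35/(4.575·10⁻³ T)).
A through-origin fit of F against [InH] yields the effective inhibition
constant f·k₇; the induction period τ = f·[InH]/Vᵢ yields the
stoichiometric coefficient f; and k₇ = f·k₇ / f, reported as log₁₀ k₇ with
propagated uncertainties.

**QSPR.**  Structures are encoded as multilevel-neighborhood-of-atoms (MNA)
substructural descriptors — canonical recursive strings `A(D₁D₂…)` over an
explicit-hydrogen molecular graph with cyclicity marks — plus three
whole-molecule descriptors (topological length, topological volume,
lipophilicity).  Partial models come from self-consistent regression
(ridge-regularized least squares with backward elimination of insignificant
descriptors), optionally refined with Gaussian radial basis functions, and
are combined into a consensus model whose prediction is the mean over the
partials inside the applicability domain (leverage + unseen-descriptor
checks).  Validation uses the standard external battery (R², R²₀, R′²₀,
r²m averages, CCC, Q²F1/Q²F2, RMSE, MAE, SD, MAE+3SD) with 5% trimming and
high/moderate/low classification against fractions of the training activity
range.

**Synthetic data.**  Generators produce rate tables and uptake curves from
the steady-state law with known f·k₇ and f, and structure–activity datasets
over a phenol grammar where log k₇ is an exact linear function of
descriptor counts — so every stage is testable by parameter recovery.

## Worked example

Fit the bundled oxygen-uptake rate table for the chromane antioxidant AO1
(1,4-dioxane, 348 K, Vᵢ = 10⁻⁷ M/s, 2k₆ = 6.67·10⁷ M⁻¹s⁻¹):

```python
from oxiqspr import fit_fk7, k7_from
from oxiqspr.reference_data import AO1_RATE_TABLE, REFERENCE_CONSTANTS, STOICH_FACTORS

fit = fit_fk7(AO1_RATE_TABLE, REFERENCE_CONSTANTS)
f, f_se = STOICH_FACTORS["AO1"]
res = k7_from(fit.fk7, f, fk7_se=fit.fk7_se, f_se=f_se)
print(f"fk7   = {res.fk7:.3e} +- {res.fk7_se:.1e}")
print(f"f     = {res.f_stoich} +- {res.f_se}")
print(f"k7    = {res.k7:.3e} +- {res.k7_se:.1e}")
print(f"logk7 = {res.logk7:.2f}")
```

prints

```
fk7   = 1.322e+06 +- 7.6e+04
f     = 30.0 +- 4.0
k7    = 4.406e+04 +- 6.4e+03
logk7 = 4.64
```

i.e. each AO1 molecule terminates about 30 oxidation chains, with an
effective inhibition constant f·k₇ ≈ 1.32·10⁶ M⁻¹s⁻¹ and a chain-termination
constant k₇ ≈ 4.4·10⁴ M⁻¹s⁻¹ (log k₇ = 4.64).

The same workflow is available from the shell:

```bash
oxiqspr simulate qspr --n 120 --seed 7 --out qspr.csv
oxiqspr train --in qspr.csv --preset mna --seed 20191 --out model.json
oxiqspr predict --model model.json --in mols.smi --out pred.csv
oxiqspr kinetics fit --rates ao1.csv --f-stoich 30
```

## Layout

- `oxiqspr.chem_graph` — SMILES/SDF parsing, explicit-H graphs, ring perception
- `oxiqspr.descriptors` — MNA recursion, whole-molecule descriptors, matrices
- `oxiqspr.dataset` — activity records, rank-ordered 5:1 splitting
- `oxiqspr.qspr` — SCR, RBF-SCR, consensus models, applicability domain
- `oxiqspr.validation` — external-validation metric battery and quality rules
- `oxiqspr.kinetics` — Vᵢ, F-parameter, f·k₇, τ, f, k₇ with uncertainties
- `oxiqspr.synthdata` — ground-truth generators for both pipelines
- `oxiqspr.reference_data` — bundled AO1/AO2 measurements and reported values

See `docs/methods.md` for the models, assumptions and numerical choices.
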