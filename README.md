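# lfer2p

Two-parameter linear free energy relationships (2p-LFERs) for predicting
how neutral organic chemicals partition between water and biological
phases — structural (muscle) protein, serum albumin, storage lipid and
phospholipid — plus a multiphase equilibrium model that turns those
phase affinities into whole-tissue, organ:plasma and milk–water
distribution estimates.

It is aimed at environmental chemists, toxicologists and exposure
modellers who need protein– and lipid–water partition coefficients for
chemicals that lack experimental values or Abraham solute descriptors.
Full poly-parameter (Abraham) LFERs need six descriptors that exist for
only a few thousand chemicals; the 2p-LFER needs just the two most widely
available properties there are, and loses little accuracy doing it.

## The model

The core relationship predicts a log10 phase–water partition coefficient
as an affine combination of hydrophobicity and volatility/solubility:

```
log K_phase–water = λ1·log Kow + λ2·log Kaw + λ3
```

Published coefficient sets ship in a built-in registry — chicken, fish
and combined structural protein, bovine serum albumin (whose intercept is
statistically zero and dropped), phospholipid and storage lipid. The
package also evaluates one-parameter (log Kow only) and poly-parameter
Abraham models, fits new 2p-LFERs by OLS with bootstrap coefficient SEs
and backward term elimination, runs the standard QSPR validation battery
(hold-out, k-fold, repeated k-fold, LOOCV, bootstrap validation,
Bland–Altman agreement), provides chemical-space diagnostics (PCA with
square cosines, Pearson matrices) and applicability-domain checks
(Williams plot classification by leverage and studentized residual), and
includes a seeded synthetic-chemistry generator for testing and
calibration experiments.

For tissues, phase capacities mix linearly:
`K_tissue = f_water + Σ f_i·10^(log K_i)`, from which tissue log Ks,
organ:plasma log distribution ratios and per-phase chemical loads follow.

## Worked example

```python
from lfer2p import (get_2p_coefficients, predict_2p, phase_logk_from_2p,
                    builtin_tissue_compositions, tissue_k, distribution_ratio)

c = get_2p_coefficients("combined_structural_protein")
print(f"lambda1={c.lambda1}, lambda2={c.lambda2}, lambda3={c.lambda3}")
print(f"benzo[a]pyrene  logKpw = {predict_2p(6.13, -4.73, c):.3f}")
print(f"TBP             logKpw = {predict_2p(4.00, -4.24, c):.3f}")

pk = phase_logk_from_2p(6.13, -4.73)
tissues = builtin_tissue_compositions()
print(f"BaP muscle-water logK  = {tissue_k(tissues['muscle'], pk):.3f}")
print(f"BaP muscle:plasma logD = {distribution_ratio(tissues['muscle'], tissues['plasma'], pk):.3f}")
```

prints

```
lambda1=0.851, lambda2=-0.092, lambda3=-1.08
benzo[a]pyrene  logKpw = 4.572
TBP             logKpw = 2.714
BaP muscle-water logK  = 4.847
BaP muscle:plasma logD = 0.596
```

The first two numbers are structural-protein–water partition
coefficients: benzo[a]pyrene (log Kow 6.13, log Kaw −4.73) is predicted
to be ~37,000× enriched in muscle protein over water, tri-n-butyl
phosphate ~520×. The last two run the same chemical through the
multiphase model with representative tissue compositions: whole muscle
binds benzo[a]pyrene slightly more strongly than its protein fraction
alone (storage lipid contributes), and muscle is predicted to hold ~4×
the plasma concentration at equilibrium.

The same analyses are scriptable through the `lfer2p` command
(`predict`, `fit`, `validate`, `chemspace`, `domain`, `multiphase`,
`synth` subcommands; see `lfer2p --help`).

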