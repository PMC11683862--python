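# Methods

## The model

`lfer2p` predicts log10 phase–water partition coefficients of neutral
organic chemicals from two macroscopic descriptors: the octanol–water
partition coefficient (log Kow, a hydrophobicity proxy) and the air–water
partition coefficient (log Kaw, a volatility/solubility proxy). The
two-parameter linear free energy relationship (2p-LFER) is the affine form

    log K_phase–water = λ1·log Kow + λ2·log Kaw + λ3 .

The package ships published coefficient sets for six phase–water systems
(chicken, fish and combined structural protein; bovine serum albumin,
where the intercept is statistically zero and dropped; phospholipid;
storage lipid). The one-parameter variant (log Kow only) and the
poly-parameter Abraham variant (descriptors E, S, A, B, V or L with
system coefficients c, e, s, a, b, v/l in either the v- or l-form) are
evaluated by the same module; no Abraham system coefficients are bundled,
because the sources that define them license those tables separately —
users supply their own.

Assumptions worth keeping in mind: the relationship is linear in the two
log-scale descriptors; it applies to neutral species only (no ionization
correction); and the descriptors themselves must be trustworthy —
chemicals at the extremes of hydrophobicity or volatility carry larger
input error, which the applicability-domain diagnostics are designed to
expose.

## Fitting and inference

`fit_ols` is plain multiple linear regression (no weighting, no
regularization — the model class is deliberately linear). Reported
statistics: R², Adj R² = 1 − (1−R²)(n−1)/(n−p−1), F = (R²/p)/((1−R²)/(n−p−1)),
per-coefficient analytic SEs from the coefficient covariance, residuals,
fitted values and hat (leverage) values.

Two conventions were genuinely open and are resolved as follows:

* **RMSE denominator** — default `sqrt(SSE/n)`, the convention common in
  the LFER literature where RMSE is reported alongside a separate Adj R²;
  `rmse_denominator="residual_df"` switches to `sqrt(SSE/(n−p−1))`.
* **Coefficient SE flavour** — the headline SEs of the shipped
  coefficient sets are bootstrap standard deviations (1000 case
  resamples); `fit_ols` always reports analytic SEs too, and
  `bootstrap_coefficient_se` recomputes the bootstrap flavour with a
  caller-controlled seed. For fits without an intercept, R² is still
  computed against the centred total sum of squares so that the statistic
  stays comparable across the two model forms.

Backward elimination (`drop_insignificant_terms`) removes the least
significant term with two-sided t-test p > 0.05 and refits until all
remaining terms are significant; removed terms are reported with
coefficient exactly 0.0 (this is how the albumin model loses its
intercept). Coefficient sets from two fits are compared with
z = (b1 − b2)/√(SE1² + SE2²) against a 1.96 critical value.

## Validation protocol

* **Hold-out**: test size is round-half-away-from-zero of n·fraction
  (default 0.2 test), so a 51-record table splits 41/10.
* **k-fold / repeated k-fold**: ids are sorted canonically, shuffled with
  the seed, and dealt round-robin into folds; folds re-randomize each
  repeat. The score is the predictive R² on the held-out records
  (1 − SSE/SST around the held-out mean) — the Q² convention, not a
  squared correlation. Both 5- and 10-fold are supported; 5-fold is the
  default.
* **LOOCV**: PRESS via the exact hat-value shortcut Σ(e_i/(1−h_ii))²,
  with an explicit n-refit loop available as a cross-check;
  Q² = 1 − PRESS/SST.
* **Bootstrap validation**: each replicate draws round(n·fraction)
  records with replacement (default 50%), refits, and scores R² over the
  full table; mean and SD across (default) 1000 replicates.
* **Bland–Altman**: paired differences a−b, limits of agreement
  bias ± 1.96·SD (sample SD), outliers strictly outside the limits —
  used to decide whether two measurement series (e.g. two muscle-protein
  datasets) agree well enough to merge.

All schemes sort ids before applying the seed, so results are invariant
to the order records happen to be stored in.

## Chemical-space and applicability-domain diagnostics

PCA operates on the correlation matrix by default (the analysed variables
mix log K values with Abraham descriptors, so standardization is the only
defensible scaling; the observed response column is standardized together
with the descriptors). Reported per dimension: eigenvalue share of
variance, cumulative share, variable loadings (variable–component
correlations) and squared cosines (cos2 = loading², each variable's cos2
summing to 1 across dimensions). Eigenvector signs follow the
largest-|loading|-positive convention so outputs are reproducible.

The Williams classification flags a training record as outside the
applicability domain when its leverage h_ii exceeds the threshold
(default 3·(p+1)/n; a fixed value such as 0.06 can be passed to match a
published plot) or its studentized residual exceeds ±2. Residuals are
internally studentized by default, e_i/(s·√(1−h_ii)) with s² = SSE/(n−p−1);
externally studentized (deletion) residuals are available.

## Multiphase equilibrium partitioning

A tissue is a mixture of water, storage lipid, phospholipid, structural
protein and albumin with mass fractions f_i. Phase capacities mix
linearly:

    K_tissue–water = f_water·1 + Σ_i f_i·10^(log K_i–water)

so the tissue log K is the log of a fraction-weighted sum of phase
capacities with water fixed at 1. Organ:reference distribution ratios are
differences of tissue log Ks (plasma is just another composition, not a
special case), per-phase chemical loads are f_i·K_i normalised by the
capacity sum, and milk is the same model applied to a milk composition.
Fractions must be non-negative and sum to 1 within ±2% (literature
rounding); near-misses are renormalized with a warning.

The shipped composition file
(`data/synthetic_tissue_compositions.json`) contains **synthetic
representative values** assembled from typical mammalian physiology, not
the source tables of any particular study; users reproducing published
tissue-distribution statistics must overlay the study's own composition
tables. Fractions are on a mass basis and the supplied partition
coefficients must match that basis.

## Synthetic data generator

The generator emulates the structural-protein training chemistry: uniform
marginals over the published descriptor ranges (log Kow 1.4–6.1,
log Kaw −8.6 to 2.1; E −0.1–3.63, S 0–1.98, A 0–0.69, B 0–1.28,
V 0.79–1.44, L 3–11.74; an alternative range set covers the wider
albumin window, log Kow 1.40–6.8 and log Kaw −10.6 to 2.2). Uniform
marginals are the least-informative choice given that only ranges are
stated. A Gaussian copula couples log Kow and log Kaw when a target
Pearson correlation is requested (normal-scale ρ = 2·sin(πr/6), the exact
inverse for uniform margins). Observations are generated as
λ1·log Kow + λ2·log Kaw + λ3 + N(0, σ), with default truth
(0.851, −0.092, −1.080) and σ = 0.3, close to the combined-protein
training RMSE of 0.334. One seed fans out into per-stage substreams, so
adding a stage never perturbs earlier draws; replicate seeds derived in
experiments stay below 2³¹.

What the generator does **not** emulate: chemical-class clustering,
descriptor intercorrelations beyond the single log Kow/log Kaw knob, and
heteroscedastic measurement error. Consequences: PCA on synthetic
51×9 matrices concentrates far less variance in the leading dimensions
than real training sets do (real descriptors are strongly
intercorrelated), and the synthetic fit R² runs higher than the published
0.878 because independent uniform descriptors spread the response more
widely than real chemistry does at the same noise level. Passing tests
therefore demonstrate correctness of the estimators and protocol, not
real-data performance.

## Numerical choices and problem sizes

OLS is solved through the standard QR-based least-squares path; rank
deficiency is detected up front and named. Leverage comes from the QR
factor (row sums of squares of Q). LOOCV refuses records with h_ii = 1
(exact interpolation). Bootstrap resampling redraws rank-deficient
replicates, aborting above a 10% redraw rate. Determinism contracts:
every randomized routine takes a seed and produces identical output for
identical input and seed.

Default experiment sizes — n = 51 tables for protocol demonstrations
(matching the combined training set), n = 500 with 200 replicates for the
parameter-recovery study, 1000 bootstrap replicates — were chosen so every
statistic is stable at the third decimal while the full suite and the
reproduction script each run in seconds.

## Known limitations

Neutral chemicals only; no ionization correction (predictions for
ionizable species, e.g. charged perfluoroalkyl acids, can be off by an
order of magnitude). Accuracy inherits the accuracy of the log Kow /
log Kaw inputs. The multiphase model is equilibrium-only — no perfusion,
kinetics or physiologically based modelling — and its outputs are only as
good as the composition tables supplied.
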