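# Methods

## Model

The response is the log₁₀-transformed within-species standard deviation
of CT_max (°C).  For n species the model is

    y = Xβ + ε,   ε ~ N(0, σ² V(λ))

where V is the phylogenetic variance–covariance matrix — entry (i, j) is
the branch length shared by species i and j from the root to their most
recent common ancestor; the diagonal holds root-to-tip distances — and
Pagel's λ multiplies the off-diagonal entries.  The model assumes
Gaussian residual variation whose correlation structure interpolates
between independence (λ = 0) and pure Brownian motion on the tree
(λ = 1).  λ is restricted to [0, 1], which keeps V(λ) positive
semi-definite for any tree; values above 1 can break positive
definiteness and are rejected.

Covariates: latitudinal group (temperate/tropical, boundary at 23°
absolute latitude), habitat (freshwater/marine), hemisphere
(northern/southern), ΔT = CT_max − T_a (°C), CT_max (°C), the number of
individuals measured, optionally heating rate (°C/min), and the three
interactions of group with ΔT, hemisphere and habitat.  Binary factors
are coded 0/1 with references temperate, freshwater, northern.

## Curation

Record-level filters run in a fixed order: (1) drop death-endpoint
records — death overshoots the loss-of-equilibrium threshold that
defines CT_max; (2) drop polar-zone records (too few polar species for a
group effect) and brackish-habitat records (ambiguous habitat class);
(3) reduce each surviving species to one record.

The published selection phrasing ("lowest or mid-point tested
acclimation temperature with the largest sample size") is ambiguous, so
the rule is an explicit mode recorded in the curation report:

* `lowest_then_largest_n` (default) — lowest T_a, ties by largest n,
  then input order;
* `midpoint_then_largest_n` — median of the distinct tested T_a values
  (lower-middle for even counts), then largest n;
* `largest_n_then_lowest` — largest n, ties by lowest T_a.

Further documented choices: latitude exactly 23° is classed temperate;
records lacking a hemisphere are excluded (reason `unknown_hemisphere`)
rather than guessed; records with a single individual carry no standard
deviation and are excluded; a missing S.D. may be reconstructed as
se·√n when a standard error is reported (flagged and counted); an S.D.
of zero is excluded as `degenerate_sd`, never propagated as −∞.  Every
excluded record lands in exactly one reason list and
input = output + Σ exclusions is asserted, so curation is fully
reconciled.  Temperatures are °C throughout.

## Trees

Newick reading/writing is backed by dendropy; internal node labels are
ignored, polytomies are kept as-is (the covariance matrix is
well-defined for them and random resolution would hide nondeterminism).
Taxonomy-derived topologies without branch lengths are repaired by
Grafen's method: node height = ((descendant tips − 1)/(n − 1))^ρ with
ρ = 1 by default, giving an ultrametric tree of unit depth; a unit
branch-length policy is available as an alternative.  Which policy a
reproduction run uses is a parameter, since published taxonomy trees
rarely state one.

Tip labels are matched to trait tables case-insensitively with spaces
and underscores equivalent; unmatched species are dropped with a
warning and counted, not raised.  Pruning to the analysed species keeps
the root even if it becomes unifurcating, so every retained tip's
root-to-tip distance — and hence the covariance submatrix — is preserved
exactly.

## Estimation

* β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky whitening; no explicit inverse of
  V is ever formed.
* σ² and λ are estimated by maximum likelihood (not REML), matching the
  convention of the standard comparative-methods implementations; the
  profile over λ uses a 101-point grid on [0, 1] refined by bounded
  scalar minimisation to 1e-6, which is robust to mild multimodality of
  the profile likelihood.  A maximum at 0 or 1 is flagged on the fit.
* Standard errors of β̂ use the unbiased residual variance RSS/(n − p),
  so t = β̂/SE follows an exact t(n − p) under Gaussian errors;
  log-likelihood and AIC use the ML variance RSS/n.  Both are reported.
* AIC = −2·logL + 2k with k = p + 1 (σ²) + 1 more when λ was estimated:
  λ is a fitted parameter and is penalised as one.
* F = ((TSS_V − RSS_V)/(p − 1)) / (RSS_V/(n − p)) against the
  intercept-only fit under the same V; R² = 1 − RSS_V/TSS_V, reported
  as a percentage.  These are whitened-space conventions and are stated
  because R² under GLS has no single standard definition.
* p-values are two-sided; the reporting significance level is 0.05; no
  multiple-testing correction is applied.
* Numerical contract: V is factorised symmetrically; a reciprocal
  condition number below 1e-12 is a hard error suggesting a smaller λ
  or branch-length repair — never a silent pseudo-inverse.
* The ordinary GLM comparator is the identical machinery with V = I,
  so "λ = 0 ⇒ PGLS ≡ OLS" holds to machine precision by construction
  and is asserted in tests.

On residual degrees of freedom: a published analysis of 203 species
with 10 coefficients reports F on (9, 192) residual df, consistent with
202 complete cases or a differing df convention.  This package reports
the df pair it actually used alongside every F statistic rather than
forcing a convention.

## Synthetic data

The generator emulates the structure of a published CT_max compilation:

* a pure-birth (Yule) tree rescaled to unit height, tips `sp1..spN`;
* binary covariates evolved by a symmetric 2-state Markov process
  (default rate 1.0 per unit height), which produces the clade-level
  clustering of groups and habitats seen in real family distributions;
* species-level log₁₀ S.D. generated as Xβ + ε with ε multivariate
  normal, covariance σ²V(λ) (defaults λ = 0.5, σ² = 0.04, i.e. residual
  s.d. 0.2 log10 units);
* per species, a ladder of acclimation temperatures 3 °C apart with
  CT_max rising 0.4 °C per °C of acclimation; individual fish drawn
  Normal(record mean, species s.d.) and aggregated to mean/S.D./n, so
  emitted summaries are noisy estimates of the latent truth, as in real
  data;
* contamination: 30% of non-primary records get a death endpoint; 2% of
  species are polar and 3% brackish (whole-species, so survival is
  deterministic); 8% of species lack heating rate, supporting the
  drop-count of the supplementary heating-rate model; heating rates are
  log-uniform on [0.0017, 1] °C/min, with zero true effect unless a
  config switch injects one;
* the lowest-acclimation record always has the strictly largest sample
  size, making the default selection rule's answer unique and recorded
  in the ground truth.

The default tropical-group effect is −0.48 log₁₀ units.  This was
computed, not eyeballed: the mean standard error of that coefficient in
the full interaction model across replicate default datasets is ≈ 0.17
(the three group interactions and the phylogenetic clustering of the
group covariate inflate it far beyond the i.i.d. approximation
σ/√(n·p·q) ≈ 0.03), and 2.83 × 0.17 ≈ 0.48 gives ≈ 0.8 power at the
5% level and n = 200.  Gaussian individual draws are a simplification;
the analysis only consumes mean/S.D./n, so heavier-tailed individual
variation would enter only through the sampling noise of the S.D.

What passing tests on these data do **not** show: robustness to
non-Gaussian residuals, measurement error in covariates, taxonomically
realistic tree shape, or the reporting quirks of real compilations
(unit mistakes, duplicated studies, range-midpoint latitudes).  The
generator is a statistical, not a biological, replica.

## Replicated experiments

Problem sizes are chosen to give tight Monte-Carlo error at desk scale:
λ/β recovery uses 100 replicates of 200-tip trees (λ true 0.5; binary
effect 0.2, continuous effect 0.1, both with |β|/SE well above 3); the
type-I contrast uses 2000 null replicates of 100-tip trees with
λ = 0.7 errors and a clustered covariate (Mk rate 0.3 per unit height,
roughly 6–7 expected state changes per tree; monomorphic draws are
redrawn since the contrast is undefined without both levels).  Observed
behaviour: mean λ̂ ≈ 0.46–0.49, coefficient recovery within ~2%, PGLS
rejection ≈ 0.06 at the nominal 0.05 versus ≈ 0.26–0.30 for OLS — the
inflation PGLS exists to correct.

## Limitations

* ML only; REML estimation of σ² and λ is future work.
* No confidence intervals or likelihood-ratio tests for λ; no other
  branch-length transforms (κ, δ); no measurement-error (SE-weighted)
  PGLS.
* The λ upper bound of 1 is the conventional correlation-strength
  domain; trees for which λ slightly above 1 would be admissible are
  not explored.
* Curation assumes one latitude/group label per species; species
  spanning both hemispheres are resolved by the record's stated
  hemisphere or excluded.
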