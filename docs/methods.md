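# Methods

## Model

`famlong` fits a three-level variance-component model for a quantitative
trait measured repeatedly on members of pedigrees.  For measure *i* of
individual *j* in family *k*,

    y_ijk = x_ijk' β + u_k + g_jk + v_ij + e_ijk

with independent, zero-mean Gaussian random terms: a family-level intercept
*u* (variance σ<sub>u</sub>²), an additive polygenic effect *g* whose
within-family correlation is the expected genetic correlation 2Φ from the
pedigree (variance σ<sub>g</sub>²), a serial within-individual effect *v*
with compound-symmetry correlation ρ across an individual's visits
(variance σ<sub>v</sub>²), and iid measurement error *e* (variance
σ<sub>e</sub>²).  Stacking observations family-by-family (member order =
order of first appearance in the PED file; visits ascending), the
covariance of the response is block-diagonal over families:

    V_k = A_k σu² + B_k σg² + C1_k σv² + C2_k (ρ σv²) + I_k σe²

where `A_k` is all ones, `B_k` expands the genetic correlation matrix over
visits (`D_k ⊗ J*` for balanced visits), and the serial part `I_k ⊗ R`,
`R = I + ρ(J − I)`, is split into its diagonal (`C1`) and off-diagonal
(`C2`) matrices so that every component matrix is known and every unknown
enters linearly.  Unbalanced visit patterns are handled by deleting the
missing rows/columns of the balanced Kronecker forms, which is the exact
marginal covariance of the observed subset.

Fixed effects are an intercept, one SNV dosage (constant across a person's
visits, values in [0, 2]) and optional covariates (age, sex, medication).

## Estimation: iterative generalized least squares

Starting from ordinary-least-squares fixed effects and identity weights,
the engine alternates until convergence:

1. **Variance step.** With residuals r = y − Xβ, the component
   coefficients solve the GLS regression of the residual cross-products on
   the known component matrices with weight V⁻¹ ⊗ V⁻¹.  This is computed in
   the equivalent trace form, accumulated per family:
   `M[r,s] = Σ_k tr(V_k⁻¹ S_r V_k⁻¹ S_s)`,
   `b[r] = Σ_k r_k' V_k⁻¹ S_r V_k⁻¹ r_k`, θ = M⁻¹b.  No Kronecker product is
   ever materialized; the literal full-vectorization construction exists
   only in `famlong.reference` as a validation oracle.
2. **Fixed-effect step.** β = (X'V⁻¹X)⁻¹ X'V⁻¹y with V from step 1,
   accumulated over family blocks; cov(β̂) = (X'V⁻¹X)⁻¹.

At a fixed point, `tr(V⁻¹S_r) = r'V⁻¹S_rV⁻¹r` for every component, which is
exactly the Gaussian maximum-likelihood score equation: the converged IGLS
estimate is the (unrestricted) ML estimate.  `famlong.reference.ml_fit`
verifies this numerically via an independent quasi-Newton maximization of
the profile log-likelihood.  No REML/RIGLS correction is applied; the
resulting O(1/K) downward bias of variance estimates at small family counts
K is documented below and visible in the validation experiments.

Association is tested per coefficient with the Wald statistic
Z = β̂ / se(β̂) and a **two-sided** normal p-value p = 2·Φ(−|Z|).  A
one-sided test would only be appropriate with a priori knowledge of the
effect direction, which an agnostic genome scan does not have.

### Identifiability of the serial/error split

Because `R` has unit diagonal, the serial diagonal matrix `C1` is
*identically* the observation-level identity `I`: the printed five-matrix
regression has two equal columns and its normal equations are singular on
every layout, balanced or not.  Only four combinations are estimable from
second moments:

    σu²,  σg²,  ρσv² (within-individual covariance),
    ω² = σv² + σe² (within-individual variance)

and the Gaussian likelihood depends on V only through them.  The engine
therefore solves the variance step exactly in the reduced basis
{A, B, C2, I} — this is the full solution set of the five-column problem,
and any split of the identity coefficient yields the same V, β̂, standard
errors and p-values.  For reporting, the five components are completed by
the minimum-norm convention σv² = σe² = ω²/2, ρ = (ρσv²)/σv², which
coincides with the pseudoinverse (minimum-norm least-squares) solution of
the literal five-column regression.  Consequences:

* association results (β, Z, p) and the identifiable components are
  unaffected and fully testable;
* the individually reported σv², ρ, σe² track the truth only when the
  generating process has σe² = σv²; no estimator can do better, since
  different splits generate identical data distributions.  The test suite
  contains one deliberately failing check
  (`test_parameter_recovery_full_decomposition`) documenting this limit.

`FitResult.est` always carries the identifiable coefficients;
`VarianceComponents.within_covariance` / `.within_variance` expose them
from the reported components.

## Numerical choices

* **Convergence**: maximum relative parameter change < `tol` (default 1e-6,
  relative floor 1e-3 to avoid chasing noise on near-zero components);
  `max_iter` default 50.  In practice the fit moves little after two
  iterations.
* **Initialization**: β from OLS; identity weights for the first variance
  step.
* **Negative variances** are legitimate solutions of the least-squares
  variance step and are kept during iteration (preserving the exact ML
  correspondence); at finalization they are truncated to zero
  (`clamp_mode="truncate"`, default) or reported raw (`"allow"`).  ρ is
  clamped into (−1/(n_visits_max − 1), 1), the interval on which every
  per-individual compound-symmetry block is PD, using the maximum visit
  count (most restrictive).
* **Boundary handling.** A candidate is accepted only when every family
  block is PD *and* has condition number below 1e5: a strongly negative
  family component can nearly cancel the polygenic one in large families,
  pushing V onto the PD boundary where the GLS weights are meaningless.  A
  refused candidate is replaced, for that iteration, by the
  non-negativity-constrained solution of the same normal equations (active
  set: offending variances zeroed, system re-solved); after two refusals
  the fit switches permanently to the constrained iteration, whose fixed
  point is well-defined, instead of cycling toward the boundary.  Remaining
  inadmissible candidates trigger step-halving toward the previous
  admissible point (the admissible set is convex, so halving terminates);
  after 10 failed halvings the last admissible estimate is returned with
  `converged=False`.
* **Step-1 solves** use the diagonally normalized normal equations (the
  raw components differ by orders of magnitude in scale) via least
  squares.
* **Factorizations**: per-family Cholesky; a block is flagged
  near-singular when its eigenvalue condition number exceeds 1e7.
* **Degenerate layouts** (e.g. single-visit singleton families) make the
  remaining components exactly collinear; this is detected on the
  unweighted Frobenius Gram of the component matrices (a property of the
  design, independent of the current V) and raises a `CollinearityError`
  naming the confounded pair.
* **Monomorphic SNVs** yield a result row with NA statistics and reason
  code instead of a failed fit.

## Synthetic data

The generator emulates family-study inputs in the style of a large
blood-pressure pedigree study: multi-generation pedigrees (default: 20
families from a founder couple, sibships 1 + Poisson, 80% of children
marrying in a founder spouse, expected size ≈ 13), diallelic dosages by
gene dropping from founder genotypes at a configurable MAF (default 0.3,
optional jitter mimicking imputed doses), and three visits per person.
Covariates: age (baseline N(45, 12²), +5 years per visit), sex (from the
pedigree), medication status (Bernoulli 0.3 per person); their effects on
the trait default to zero.  Trait values are drawn per family as L·z with
L the Cholesky factor of the *same* assembled V the estimator uses — one
shared covariance implementation, so recovery experiments probe estimation,
not two divergent model writings.  A heritable null trait (polygenic
variance h², residual 1 − h², default h² = 0.68) supports type-I-error
experiments; per-SNV genotype permutation (default across all individuals,
the stricter null; within-family optional) supports the permutation design.

Not emulated: linkage disequilibrium between SNVs, ascertainment of
families, trait non-normality, genotyping error.  Passing tests therefore
demonstrate correctness of the estimator under its own model assumptions,
not robustness to their violation.

## Validation experiments (sizes as run by the suite and script)

* **Oracle equivalence**: 100 random instances of ≤ 2 families / ≤ 12
  observations; trace form vs explicit Kronecker GLS to 1e-10 relative.
* **Estimator validity**: one seeded 20-family × 4-member × 3-visit
  dataset; IGLS vs numerical ML within 1e-4 relative on every parameter.
* **Parameter recovery**: 200 replicates of 100 nuclear families at truth
  (σu², σg², σv², ρ, σe², β) = (0.5, 1, 0.8, 0.4, 1, 0.3), unclamped fits;
  100 families keep the ML small-sample bias well inside the 3-SE
  Monte-Carlo bands so the consistency claim is actually testable.
* **Type-I error**: 1000 null tests (20 replicates × 50 SNVs, default
  pedigree template) per design — null trait at h² = 0.68 and permuted
  genotypes against a trait with a real causal SNV (effect 0.5); empirical
  FPR at α = 0.05 checked against the 95% binomial band [0.0365, 0.0635],
  plus Kolmogorov–Smirnov uniformity of permutation p-values.
* **Longitudinal power advantage**: 500 replicates, 25 nuclear families,
  causal effect 0.35 at MAF 0.3 under (0.3, 0.5, 0.4, 0.3, 1.5) — a
  measurement-noise-dominated regime chosen by the standard design-effect
  argument n_visits/(1 + (n_visits−1)·r̄), where repeated measures buy the
  most information; three-visit power vs first-visit-only power at
  α = 0.05, gap required to exceed 3 Monte-Carlo SE.
* **Kinship**: textbook coefficients exactly (parent–offspring 1/4, full
  sibs 1/4, half sibs 1/8, first cousins 1/16, full-sib-mating child
  diagonal 5/8) and a gene-dropping Monte-Carlo oracle (≥ 200k meioses)
  within 3 SE.

## Known limitations

* ML (not REML) variance estimates: downward bias O(1/K) in the number of
  families; association tests are affected only weakly, but variance
  components from few, small families should be read with that bias in
  mind.
* Only compound symmetry for the serial correlation; AR(1) or unstructured
  R are nonlinear in their parameters and outside the linear variance-step
  framework (`build_components` accepts only `compound_symmetry` and is the
  extension point).
* The serial/error variance split is reported by convention, not estimated
  (see above).
* Single-trait, single-SNV-at-a-time scans; no rare-variant collapsing, no
  multiple-testing adjustment (downstream consumers apply their own).
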