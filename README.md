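# famlong

Association testing for quantitative traits measured **repeatedly** on
members of **pedigrees** — the setting of family-based whole-genome
sequencing studies with longitudinal phenotypes (blood pressure across
clinic visits, say).  A single SNV dosage is tested against the trait while
the covariance among observations is modelled at three levels:
measurements within individuals within families.

For measure *i* of individual *j* in family *k*,

    y_ijk = x_ijk' β + u_k + g_jk + v_ij + e_ijk

with family effect u ~ N(0, σu²), polygenic effect g ~ N(0, σg²·2Φ) where Φ
is the kinship matrix computed from the pedigree, a serial within-individual
effect v with compound-symmetry correlation ρ across visits (variance σv²),
and iid error e ~ N(0, σe²).  The response covariance is block-diagonal over
families,

    V_k = A_k σu² + B_k σg² + C1_k σv² + C2_k (ρσv²) + I σe²,

with known component matrices.  Estimation is by **iterative generalized
least squares** (IGLS): alternately (1) regress residual cross-products on
the component matrices by GLS with weight V⁻¹⊗V⁻¹, computed in an exact
trace form that never materializes a Kronecker product, and (2) solve the
weighted least squares β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y.  The fixed point is the
Gaussian maximum-likelihood estimate; each SNV is tested with the Wald
statistic Z = β̂/se(β̂) and a two-sided normal p-value.  A note on what is —
and is not — identifiable in the serial/error split is in
`docs/methods.md`.

The package also ships a seeded generator for the study designs it is
validated on (multi-generation pedigrees, gene-dropped dosages, traits
drawn exactly under the model, a heritable null trait, genotype
permutation), and an evaluation harness for type-I-error and power curves
over p-value cutoffs, including the longitudinal vs first-visit-only
(cross-sectional) comparison.

## Worked example

Simulate a 30-family study (nuclear families, 3 visits per person, 5 SNVs,
the first causal with effect 0.5 per dosage unit) and scan it:

```sh
cat > study.yaml << 'YAML'
seed: 7
n_families: 30
template: nuclear
template_n_children: 2
n_snvs: 5
snv_effect: 0.5
maf: 0.3
YAML
famlong simulate study.yaml --out-prefix study
famlong scan --ped study.ped --dosage study.dose.tsv --phen study.phen.csv --out assoc.tsv
```

`assoc.tsv` then contains (printed with 4 decimals):

```
snv_id    beta     se       z      p  sigma_u2  sigma_g2  sigma_v2    rho  sigma_e2  n_iter  converged
  snv1  0.6282 0.2508  2.5043 0.0123    0.3055    1.6901    0.9308 0.2303    0.9308      13       True
  snv2  0.0088 0.2584  0.0342 0.9727    0.5046    1.4962    1.0083 0.3663    1.0083      10       True
  snv3  0.2309 0.2629  0.8782 0.3798    0.4840    1.6132    0.9686 0.2992    0.9686      12       True
  snv4  0.1167 0.2422  0.4819 0.6299    0.5418    1.4274    1.0223 0.3886    1.0223      10       True
  snv5 -0.1974 0.2811 -0.7023 0.4825    0.6767    1.2469    1.0572 0.4418    1.0572      14       True
```

The causal SNV (snv1, true effect 0.5) is the only one reaching p < 0.05;
its dosage effect is estimated at 0.63 ± 0.25 trait units per allele copy.
The variance columns are the fitted components (data generated at σu² = 0.5,
σg² = 1.0, within-individual covariance ρσv² = 0.32, within-individual
variance σv² + σe² = 1.8; the reported σv²/σe² split follows the convention
described in `docs/methods.md`).  Other subcommands: `famlong kinship`
(pedigree → kinship table), `famlong eval-type1` and `famlong eval-power`
(calibration and power experiments from a config file); the same
functionality is available as a library (`famlong.fit_igls`,
`famlong.assoc_scan`, `famlong.simulate`, `famlong.evaluate`).

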