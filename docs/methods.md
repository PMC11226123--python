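# Methods

## Model

A binary phenotype with population prevalence K is modelled as the
indicator L > τ of a standard-normal latent liability, with
τ = Φ⁻¹(1 − K). For a pair of relatives the two liabilities are bivariate
standard normal with correlation

    r = κ a² + δ d² + c²,

where a², d², c² are the standardized additive-genetic, dominance and
shared-environment variance fractions (e² = 1 − a² − d² − c² is the
unique-environment remainder), κ is the expected fraction of additive
genetic variance shared (1 for MZ twins, ½ for DZ twins and full
siblings) and δ the dominance analogue (1 and ¼). The model assumes no
assortative mating, no gene–environment correlation or interaction, and
equal environments across zygosity groups; C and D are not jointly
identifiable from twin data, hence the separate ACE and ADE variants.

### Unknown zygosity

When a registry records sex but not zygosity, opposite-sex pairs are
certainly DZ while the same-sex group mixes MZ and DZ pairs. Under
independent assortment of DZ sexes, half of DZ pairs are opposite-sex, so
the MZ proportion among same-sex pairs is estimated by Weinberg's
differential rule p_MZ = (N_ss − N_os)/N_ss (clipped to [0, 1] with a
warning if negative). The same-sex group is then treated as a single
group with the mixture-averaged coefficients

    γ = p_MZ + (1 − p_MZ)/2,      δ_ss = p_MZ + (1 − p_MZ)/4.

This is an approximation: the same-sex concordance table is a mixture of
two bivariate normals rather than one bivariate normal with the averaged
correlation. The Monte-Carlo recovery results below quantify the
(small) bias this induces at realistic parameter values.

### Estimation

Pair order within registry data is arbitrary, so every 2×2 concordance
table is symmetrized (each pair contributes ½ to (y₁,y₂) and ½ to
(y₂,y₁)); fractional counts are carried in floating point into the
multinomial likelihood. Symmetrization justifies a single threshold τ
shared by both members.

- **Tetrachoric correlation.** The orthant probability
  P(L₁ > τ, L₂ > τ) is computed in closed form from Owen's T function
  (near machine precision; an adaptive-quadrature and a scipy-MVN route
  serve as independent oracles in the tests). The likelihood is
  maximized over (artanh ρ, τ) by L-BFGS-B, keeping ρ interior; standard
  errors come from the central-difference observed information. Zero
  cells receive no continuity correction — the likelihood handles them —
  and all-mass-on-the-diagonal tables yield a boundary estimate with a
  warning and no SE.
- **Biometric fit.** The ACE/ADE model is fitted by joint ML across
  groups over (a, b, τ), where a and b are path coefficients (components
  are their squares, so non-negativity is automatic) subject to
  a² + b² ≤ 1, using SLSQP. The threshold is shared across groups by
  default (same trait, same population); `shared_tau=False` frees it per
  group. Starting values come from per-group tetrachoric fits passed
  through the closed-form method-of-moments solution.
- **Method-of-moments oracle.** For the twin design,
  a² = (r_ss − r_os)/(γ − ½) and c² = r_os − a²/2; the ADE analogue
  solves the corresponding 2×2 linear system. The raw solution is
  returned untruncated and is used to cross-check the ML route.

### Uncertainty

SEs of a² and c² (or d²) are delta-method transforms (var(a²) = 4a²·var a)
of the inverse observed information of (a, b, τ). At a zero boundary
(b̂ = 0) every mixed partial involving b carries a factor b, the
information matrix decouples, and the Wald SE of a² collapses to the
conditional (AE-model) value; Wald intervals then under-cover. `conf_int`
therefore defaults to an "auto" policy: Wald intervals in the interior,
profile-likelihood intervals (deviance drop of χ²₁(0.95)/2, found by
bisection over constrained refits) whenever a component is within 1e-4 of
a boundary. Both methods can be forced explicitly. Measured over 200
registry-scale replicates with true a² = 0.57, c² = 0, this hybrid
achieves 95% CI coverage of about 0.97 for a², versus roughly 0.90 for
pure Wald.

### Stratified comparisons

Heritability differences between strata use the two-sample statistic
z = (a²_A − a²_B)/√(SE_A² + SE_B²) with a two-sided normal p-value and
per-test α = 0.05 (no multiplicity correction — comparisons are reported
individually). The Weinberg adjustment is computed once globally by
default (`gamma="global"`), since stratum-level same-sex/opposite-sex
imbalances are mostly sampling noise; `gamma="auto"` recomputes it per
stratum and a numeric value fixes it. Sex-stratified fits are impossible
under the twin design (no opposite-sex pairs within one sex) and raise an
error pointing to the twin/sibling design, which contrasts same-sex
twins (κ = γ) with same-sex sibling pairs (κ = ½). Sibling pairs default
to a shared-environment coefficient of 1; `sibling_c_coef` exposes the
assumption as a sensitivity knob, since twin-sibling designs are known to
return smaller C estimates when sibling environments are less shared.

## Synthetic registry generator

The generator emulates the structure the estimator assumes: bivariate
normal liabilities per pair (Cholesky of the 2×2 correlation matrix,
numpy PCG64 generator, fixed seeds portable across platforms),
thresholded at τ(K); MZ pairs always labelled same-sex, DZ pairs
opposite-sex with probability ½ (independent sexes), siblings a separate
same-sex group. True zygosity and latent liabilities are emitted only
behind a debug flag and are never read by estimation code. Default
prevalence is 0.17, matching the adult book-borrowing rate the package's
acceptance checks are built around; strata may override (a², c², K) only,
so group composition stays comparable across strata.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real registries: assortative mating, sex-limited
genetic effects, violations of the equal-environment assumption,
MZ/DZ-specific prevalences, cohort trends, or any misclassification of
group labels. It draws each pair independently, whereas real sibships
share families across pairs.

## Problem sizes and numerical choices

- Exact-table self-consistency checks use N = 10⁵ per group, where ML and
  method-of-moments agree to ~1e-8 (tolerance 5e-3).
- Monte-Carlo recovery uses 200 replicates at the two-group design with
  10,712 MZ + 23,238 DZ true pairs (expected same-sex/opposite-sex split
  ≈ 22.3k/11.6k) and prevalence 0.17: mean bias of â² is about −0.015
  (within the ±0.02 band), mostly attributable to the mixture
  approximation and the c² ≥ 0 constraint.
- Z-test calibration uses two strata of 8,000 MZ + 16,000 DZ pairs each —
  the scale of a median split of a registry with ~34k twin pairs — with
  a² = 0.5, c² = 0.2 (interior, so Wald SEs apply) over 500 comparisons;
  the measured null rejection rate at α = 0.05 is ≈ 0.04–0.05.
- Orthant probabilities are exact to ~1e-15; optimizer tolerances are
  ftol 1e-12 (SLSQP) and gtol 1e-10 (L-BFGS-B); Hessian step 1e-4.
- Degenerate inputs: |ρ| = 1 uses closed-form cell probabilities; tables
  with all mass in one cell are rejected for tetrachoric fitting;
  grid-agreement checks exclude tables with near-empty cells, where the
  likelihood has a flat ridge to the correlation boundary and ρ is only
  weakly identified.

## Known limitations

- The Weinberg mixture-averaging of the same-sex group is first-order;
  at very high a² or very low prevalence the induced bias grows.
- The sign-flip symmetry of the tetrachoric (relabelling one member's
  phenotype negates ρ) holds exactly only at τ = 0 under the
  shared-threshold model, because flipping one member breaks
  exchangeability (it would require thresholds +τ/−τ).
- Wald SEs for components at the zero boundary are reported but flagged;
  rely on the profile intervals there.
- One phenotype per fit; multivariate (cross-trait) twin models and
  continuous moderators are out of scope, as are ordinal phenotypes with
  more than two categories.
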