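# Methods

## Model family

All four models extend the two-parameter logistic IRT model for binary
responses of persons nested in intersectional groups (the cells of the
full cross-classification of `D` categorical demographic variables).
With `x_s` the dummy-coded main-effect vector of group `s` (reference
group = all first levels; effect coding is available, in which case no
group is a reference) and `x̃_s = (1, x_s)`:

* Group-specific item intercepts `b_js ~ N(x̃_sᵀβ_j, σ²_bj)`. The fixed
  part carries traditional uniform DIF; the variance carries
  intersectional uniform DIF. Present in every variant.
* Group-specific item slopes `a_js` follow a normal distribution
  left-truncated at zero whose *pre-truncation* mean is `x̃_sᵀα_j` and
  variance `σ²_aj` (Ris/RisM only). Truncation keeps slopes positive;
  all slope moments are computed from the underlying normal via a
  log-space Mills-ratio form that stays accurate tens of standard
  deviations into the tail.
* Abilities `θ_is ~ N(x_sᵀγ + u_s, 1)`; the within-group variance is
  fixed at 1 and the reference-group mean at 0 (the ability-mean design
  has no constant column) for identification. The group-level deviation
  `u_s ~ N(0, τ²)` is intersectional impact (RiM/RisM only).

An item is free of intersectional non-uniform DIF when `σ²_aj = 0` and
additionally free of intersectional uniform DIF when `σ²_bj = 0`.
Anchor items have `β`/`α` main effects fixed to zero but their
*variances* are estimated like any other item: anchoring is needed only
for the unpenalized main effects.

## Estimation

The marginal likelihood integrates over `N` abilities plus `J×S` (or
`2·J×S`) item effects, so each Bernoulli term `log σ((2y−1)·(aθ+b))`
is replaced by the local quadratic lower bound

```
log σ(x) ≥ log σ(ξ) + (x−ξ)/2 − λ(ξ)(x²−ξ²),  λ(ξ) = (σ(ξ)−½)/(2ξ)
```

tight at `|x| = ξ`, with one variational parameter `ξ_ij` per observed
response (each person belongs to exactly one group, so no group index
is needed). Under a mean-field factorization every coordinate update is
closed-form: Gaussian factors for `θ_i`, `b_js`, `u_s`, a truncated-
normal factor for `a_js` (mirroring its prior — the natural conjugate
family under the quadratic bound), and `ξ_ij ← sqrt(E[(aθ+b)²])`. The
E-step sweeps θ → u → b → a → ξ once per EM iteration; any order
preserves ascent.

M-step closed forms: fixed slopes (Ri/RiM) as a ratio of bound-weighted
moments; intercept coefficients `β_j` by least squares of the `b`
posterior means on `x̃` (anchors: base column only); impact `γ` by
group-size-weighted least squares of ability means; `τ² = mean(E[u²])`;
and the penalized variance update

```
σ²_bj = R_j / (S + 2η),   R_j = Σ_s [(E[b_js] − x̃_sᵀβ_j)² + Var[b_js]]
```

which is the exact maximizer of the penalized per-item term. Slope
coefficients and slope variances (Ris/RisM) have no closed form because
the truncated-normal normalizer depends on them; they are updated by
bounded scalar maximization per coordinate (brackets (−5, 5) for
coefficients, (1e-4, 10) for variances, tolerance 1e-8).

The penalty applies only to the DIF variances, never to main effects or
to `τ²`. Larger `η` gives sparser variance patterns; the path is fitted
over 20 log-spaced values in [0.1, 100] (defaults), warm-starting each
fit from the previous one and the first from an unpenalized fit.

### Zeros, floors and flags

* The closed-form variance update never returns an exact zero by
  itself; once it falls below the floor δ = 1e-6 it is collapsed to an
  exact structural zero and the item switches to a genuine fixed-effect
  update (its intercept coefficients are re-estimated from the
  bound-weighted likelihood directly). Without the switch the EM rate
  for a collapsed item's coefficients tends to zero and they freeze.
  A collapsed variance stays collapsed for the remainder of that fit;
  warm starts along the ascending penalty path make this consistent
  with the path's sparsity monotonicity.
* `log x` of a near-zero variance is replaced by `log δ` inside
  objective and information-criterion evaluation only — applied
  consistently to prior *and* entropy variance logs so the two nearly
  cancel, as they do exactly in the shrinkage limit — never inside the
  updates themselves.
* Flags are deterministic: an item is reported as intersectional
  UDIF/NUDIF iff its estimated variance exceeds ε = 1e-3
  (configurable). `k` in the information criterion counts variances
  above ε, intercept and slope variances separately.
* The convergence trace records the penalized objective (= ELBO when
  η = 0), the quantity the coordinate updates provably do not decrease;
  convergence is declared when its relative change drops below 1e-5
  (default, max 500 iterations). Raw-ELBO monotonicity cannot hold
  under a penalty, and the unfloored penalized objective diverges
  logarithmically while null variances decay geometrically, which is
  why the floored objective is the convergence quantity.

### Selection

`GIC(η; c) = −2·ELBO + c·log(N)·k`, with the floored ELBO as surrogate
for the intractable log-likelihood; `c = 1` reproduces BIC. Ties break
toward larger `η` (the sparser model) — a conservative default; users
who prefer sensitivity over specificity should lower `c`. The elbow
table reports the flagged-item count of the GIC-selected fit for each
`c` in a grid (default 0, 0.25, …, 3); choosing `c` from the plateau is
deliberately left to the user, exactly like reading a scree plot —
automatic elbow detection is out of scope.

## Synthetic data

The generator reproduces the standard factorial designs. Fixed item
parameters are drawn once per design: slopes from U(1.0, 2.5),
intercepts from N(0, 1) (a user-supplied table can pin them instead).
Factors: 10 groups (binary × five-category, P = 5) or 40 groups (three
binary × five-category, P = 7); 50 or 100 persons per group; 20% (items
1–4) or 60% (items 1–12) DIF items with items 17–20 as anchors; planted
DIF variances half low / half high — (0.31, 0.98) for intercepts,
(0.22, 0.46) for slopes, the endpoints of pilot ranges observed on
large-scale assessment data; traditional DIF on every non-anchor item
via 0.2 per dummy on intercepts (0.1 on slopes, slope-variant designs
only), giving group offsets 0.2–0.4 at 10 groups and up to 0.8 at 40;
traditional impact 0.1 per dummy (ability-mean offsets 0.1–0.2, up to
0.4); intersectional impact variance 0 or 0.5 (ICC ≈ 0.1). Group
slopes for slope-variant designs are drawn by inverse-CDF sampling of
the truncated normal. One master seed spawns independent
per-replication streams, so earlier replications are bit-identical
when more are requested.

What the generator does **not** emulate: unequal group sizes,
between-group ability-variance heterogeneity, missing-data mechanisms
(missingness is supported by the estimator but not planted), polytomous
items, and real-data features such as speededness or local dependence.
Passing simulation tests therefore demonstrate correctness of the
algorithm under the model's own assumptions, not robustness to their
violation.

## Evaluation

True/false-positive rates are computed per parameter class: TP = share
of planted-DIF parameters flagged, FP = share of clean parameters
flagged, separately for intercepts (UDIF) and slopes (NUDIF). Study
summaries report per-replication rates, their means and Monte-Carlo
standard errors. The shipped study runs use 10 replications per
condition — large enough for the rates, which average over items, to
stabilize — rather than a larger replication count.

## Known limitations

* **Slope attenuation.** The local quadratic bound is loose where the
  posterior ability variance is non-negligible, and the looseness grows
  with `a²·Var(θ|·)`. Estimated slopes (and, less so, intercepts) are
  therefore biased toward zero relative to marginal maximum likelihood,
  most visibly for steep items and short tests; the degenerate
  single-group comparison in `scripts/acceptance.py` quantifies the gap
  against a quadrature-ML oracle. Importance-weighted ELBO corrections,
  the standard remedy, are out of scope here. DIF *detection* is
  largely unaffected — it rests on which variances survive shrinkage,
  not on their absolute accuracy.
* **Variance underestimation.** Unpenalized DIF-variance estimates are
  downward-biased: the maximum-likelihood-type update `R/S` absorbs
  fitted main effects without a REML-style correction, and the bound
  makes the `b` posteriors slightly overconfident. The acceptance
  script reports the measured relative bias.
* **NUDIF detection is hard.** Slope-variance detection needs many
  groups and large per-group samples; with few groups, or together with
  intersectional impact, slope flags should be interpreted with
  caution. Intercept (UDIF) results remain reliable even when data
  contain NUDIF.
* Degenerate inputs: a single-group design (no demographic variables)
  is supported and reduces, under a large penalty, to a plain 2PL fit;
  persons with no observed responses receive their prior; rank-deficient
  group designs are rejected with an identifiability error.
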