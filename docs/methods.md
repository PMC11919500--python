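# Methods

This note documents the models, algorithms, defaults, and design choices of
`socsel`, and what the synthetic validation does and does not demonstrate.

## The statistical model

Contextual analysis partitions selection between two nested phenotypic
levels by regressing individual fitness on the individual's trait deviation
and its group's trait deviation simultaneously.  For individual *j* in
group *k* in year *l*:

    w_jkl = β0 + β_{w,ΔPi}·ΔP_ijkl + β_{w,ΔPg}·ΔP_gjkl
            + (group size, elevation, covariates) + u_j + v_l + e_jkl

* **ΔP_ijkl** — the individual trait, mean–variance standardized within its
  group-year (intra-group scale): individual-level selection inherently
  compares groupmates.
* **ΔP_gjkl** — the group trait, standardized across all unique group-years
  of the dataset (inter-group scale): group-level selection operates across
  groups.  Moments are computed with one observation per group-year, not
  per member, so large groups do not dominate
  (`group_moment_weighting: per_group`; a per-individual option exists as a
  sensitivity switch).
* **u_j, v_l** — random intercepts for individual identity and year.
* Binary outcomes (summer survival, hibernation survival, weaned) use a
  binomial GLMM with logit link; litter size (conditioned on a weaned
  litter) a Poisson GLMM with log link.  Gradients are reported on the link
  scale, as fitted; no Lande–Arnold transformation is applied.

Eight cohort models make up the default analysis: weaned and litter size
(adult females, + June mass), hibernation survival for each of the four
age–sex cohorts (+ August mass; the degree–density pair is pre-removed for
known collinearity), and summer survival for adult males and females
(+ June mass and a predation index = predators sighted per observation-hour
per colony-year).  Sample (n−1) standard deviations are used everywhere;
continuous covariates are z-scored within each model's data for numerical
comparability.

### Estimation

The GLMMs are fitted by penalized quasi-likelihood (Breslow–Clayton): an
iterated working linear mixed model whose two variance components are
re-estimated by REML at each step (Nelder–Mead on the log variances,
bounded below at 1e-8).  Because both random effects are intercepts, the
mixed-model equations separate: the individual block is diagonal and is
eliminated in closed form, leaving a dense system in the year effects plus
fixed effects, so one fit costs O(n) per REML evaluation (~0.1 s at
n ≈ 500).  Fixed-effect p-values are Wald z tests.

PQL is known to bias variance components for binary data with large random
effects; at the modest heterogeneity simulated here (SD 0.3 on the logit
scale) fixed effects agree with lme4's Laplace fits to within ~0.01 (one
test cross-checks this through Rscript), and with an ordinary GLM to within
1e-3 when the variance components are zero.  A variance component estimated
at its boundary is reported in the fit's `boundary` list — equivalent to
dropping the component, never silent.  A fit whose working model stops
improving within 50 iterations is flagged `converged=False`; this occurs
under quasi-separation (e.g. the heavily zero-inflated cut-point trait in
small cohorts) and such fits are excluded from the gradient-magnitude
summary, whose aggregation rule is: mean and standard error of |β| over all
trait predictors of all converged models, per level, with no significance
filtering.

### Multiple comparisons and collinearity

* **FDR** — Benjamini–Hochberg step-up within each predictor's family of
  p-values across the fitted models (`fdr_mode: per_predictor`, default) or
  across the whole predictor × model table (`whole_table`).
* **VIF screen** — each predictor is regressed on all others; while any
  trait predictor's VIF = 1/(1−R²) exceeds 5, the offending trait's
  individual and group columns are removed **together**.  Removing only one
  level of a collinear analogous pair would silently re-attribute selection
  between levels, which is exactly what the design is meant to prevent.

## Social groups

* **Sampling period** for the simple-ratio association index: one calendar
  day at one location (the finest unambiguous reading of daily co-location
  records); with that definition the "both observed, not together" term is
  structurally zero.  A whole-day period (`sampling: day`) is available.
* **Map equation** — the two-level formulation on the undirected weighted
  association network, node visit rates proportional to strength.
  Unrecorded strength-proportional teleportation leaves the stationary
  distribution of an undirected walk unchanged, so no teleportation
  parameter enters the objective.  Optimization is greedy single-node moves
  alternated with module aggregation (modules collapsed to supernodes with
  internal weight as self-loops, which preserves all partition-dependent
  terms), with 10 random-restart sweeps (`mapequation: n_trials`),
  deterministic per seed.  On graphs of ≤ 8 nodes the optimizer attains the
  exhaustive-search optimum in all 100 random acceptance instances; the
  optimizer, not the objective, is the only heuristic element.
* Nodes with zero association weight, and any singleton module, are
  **isolates**: they belong to no group and contribute no trait rows.
* **Male augmentation** — adult males join each group containing ≥ 1 of
  their interaction partners; primary assignment (and hence trait/fitness
  attribution) never changes.  Group size is the network node count
  including augmented males.

## Network traits

All measures except the weighted matrix itself operate on the undirected,
binarized simplification — they are defined in terms of the presence of
social relationships, not interaction rates.

* **Closeness** is r / Σd over the r individuals reachable from the focal
  animal (hop counts); unreachable targets are excluded rather than given
  infinite distance, and the r-scaling keeps values in (0, 1] and
  comparable across group sizes.  NA for within-group isolates.
* **Embeddedness** is the exact structural-cohesion level: the largest k
  such that the individual belongs to a k-vertex-connected subgroup.  The
  implementation recursively removes a minimum cut-set and recurses into
  every component *plus the cut-set*; since a k-connected subgroup cannot
  be split by fewer than k removals, it survives intact inside one branch,
  making the recursion exhaustive.  (One-sided cohesive-blocking
  implementations in common graph libraries can miss the deepest block;
  the in-package recursion matches brute-force enumeration over all vertex
  subsets on every random instance tested.)  Worst observed cost ≈ 5 s for
  a dense 35-member group, computed once per network for all members.
* **Cut points** are qualifying *edges* (relationships "that if broken"
  split their component into two parts of ≥ 2 individuals each), divided by
  group size; the articulation-point reading is available as
  `cutpoints_mode: vertex`.
* **Local clustering** is NA (excluded from models), not 0, for individuals
  with fewer than 2 partners: a zero would conflate "no opportunity" with
  "open triads".  Transitivity is NA when a network has no connected triple.
* The "inverse" of average path length and cut points is a **sign flip
  after standardization**, not a reciprocal — a reciprocal would distort the
  distribution being standardized.  A table-level flag makes double
  application an error.

## Synthetic data

The generator defines the study conditions the validation runs under:

* 19 annual cohorts × 9 groups/year; group sizes from a truncated negative
  binomial on [2, 35] whose *truncated* mean and SD are calibrated to
  7.65 ± 5.92 by solving for the underlying parameters (so truncation does
  not shift the realized moments).
* Cohort mix adult F/M, yearling F/M = 0.43/0.14/0.27/0.16; 40 % of adults
  carry over to the next year (yearlings age into adults), giving the
  individual random intercept repeated observations.
* Co-location: 60 daily sampling occasions; members attend their group's
  site with a Beta(6, 2) per-group cohesion (mean 0.75), which concentrates
  simple-ratio indices within true groups; adult males visit another
  group's site at rate 0.02/day and interact there, exercising augmentation.
* Interactions: within-group dyads included with probability 0.65; counts
  per dyad zero-truncated negative binomial (mean 12, size 0.8) split
  randomly by direction — field interaction counts are strongly
  overdispersed, and partial dyad inclusion keeps density < 1 so all eight
  measures vary.
* Filter levers with reconcilable counts: 21 % of affiliative records carry
  an unidentified participant, 12 % of interactions are agonistic, 5 % fall
  after the season, and 2 transients/year have < 5 observations.
* Fitness is generated **from the contextual model itself on the
  standardized, sign-flipped trait scale** — the true gradients live on
  exactly the scale the fitted models see, so recovery is exact in
  expectation and estimates are directly comparable to the configured
  truth.  Generating on raw traits would conflate scaling with selection.
  Baselines: summer survival 0.90, hibernation survival 0.75, weaning 0.50,
  litter size 3 (log scale); random-effect SDs 0.3/0.3; litter size is
  zero-truncated Poisson; hibernation survival is missing for known summer
  deaths.

Two generation paths share this configuration.  The record-level path
exercises every pipeline stage.  The trait-level path
(`simulate_model_data`) draws standardized deviations directly with the
exact moment structure the standardization stage guarantees, so the
replicate studies (1000-replicate type-I error, 200-replicate recovery) are
affordable; they characterize the estimator, while a full-scale end-to-end
run and smaller round-trip tests cover the record-to-gradient chain.
Replicate-study problem sizes — 60 groups/replicate for type-I error, 150
groups × mean size 8 for recovery, 6 years per replicate — were chosen as
the smallest sizes at which the paper-scale questions (gradients of ±0.5,
α = 0.05 tests) are well powered.

What the synthetic runs do **not** show: the generator draws trait values
with simple correlation structure (or none), has no spatial structure
beyond colony labels, no dispersal, observation error only through the
unknown-participant lever, and fitness truly generated by the fitted model
family.  Passing tests therefore demonstrate correctness and calibration of
the machinery, not robustness to model misspecification in real field data.

## Known limitations

* No nonlinear (quadratic/correlational) selection terms, no Price-equation
  decomposition, no pedigree/heritability machinery.
* PQL's variance-component estimates (not the gradients) should be treated
  as rough; a Laplace/AGQ backend could replace the working-LMM core
  without touching the interface.
* Single-run end-to-end gradient estimates carry sampling error of ~±0.2 at
  the default scale; the replicate studies are the calibrated surface.
* Maximum structural cohesion is exponential-time in the worst case
  (clique-hard); practical for the group sizes this design targets (≤ 35).
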