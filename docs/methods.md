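# Methods

`omicsbridge` implements a network-integration framework for cross-sectional
multi-omics studies in which different molecule layers (here: IgG glycan
peaks measured as percent of total chromatographic area, and specialized
pro-resolving lipid mediators, SPMs) are observed on nested, partially
overlapping sample sets, with genotypes available for a further subset.

## The model

Each layer's molecular network is a conditional-independence graph: an edge
between molecules x and y survives only if no tested subset S of the other
molecules renders them conditionally independent.  For residualized,
approximately Gaussian data the test is the Fisher-z test of the partial
correlation r(x, y | S):

    z = sqrt(n − |S| − 3) · atanh(r),   p = 2 Φ(−|z|)

The skeleton search is the order-independent ("stable") variant of the PC
adjacency algorithm: conditioning sets of growing size (0 … `max_cond_size`,
default 3) are drawn from the adjacency sets frozen at the start of each
size level.  Under faithfulness this is equivalent to testing all subsets of
the other molecules, at a fraction of the cost; for ≤ 12 molecules an
exhaustive search gives the same result and can be emulated by raising
`max_cond_size`.  Every retained edge records its **strength**: the largest
p-value observed across all of its conditional tests, so −log10(strength_p)
measures how robustly the dependence resists explanation.

**Structural independence across layers.**  The framework assumes each
layer's topology is already shaped by — and therefore invariant to —
variation in other layers (a cross-sectional steady-state argument).  This
licenses learning each layer on its *maximal* sample (e.g. 456 samples for
the glycan layer, 368 for the lipid layer), then integrating: within-layer
edge sets are frozen, and only cross-layer pairs are tested (at
`alpha_integration`, default 1e-2) with conditioning sets drawn from the
pair's within-layer neighborhoods and accepted bridge neighbors.  Molecules
incident to a surviving cross-layer edge are **bridging molecules**.

**Alpha selection (SPOT).**  The significance level for within-layer
learning is chosen from the grid 10^-2 … 10^-5 by topology stability: learn
the skeleton at each level, compute Hamming distances between consecutive
levels, and take the larger alpha of the most stable (minimal-HD)
consecutive pair, preferring larger alpha on ties.  The minimal-consecutive-
HD rule is this package's concrete reading of stability selection; the full
profile is logged so a user can inspect the plateau.

## Causal orientation with polygenic instruments

Single genetic variants are usually too weakly associated with any one
molecule to serve as Mendelian-randomization instruments.  Instead:

1. **Variant screen** — every candidate variant is regressed against every
   molecule of a layer (covariates plus the top 5 genotype principal
   components for population stratification); variants with any p < 0.05
   survive.
2. **Polygenic factors** — principal components of the standardized
   screened dosages; components are retained up to 80% cumulative explained
   variance (configurable).  Signs are fixed deterministically.
3. **Instrument validity** — a factor is *strong* if marginally associated
   with at least one molecule at p < `strong_p` (default 1e-3), and
   *pleiotropic* unless some single candidate target molecule explains all
   of its other associations (conditional independence given that target).
   Only strong, non-pleiotropic factors orient edges.  Note a caveat of the
   single-target conditioning: conditioning on a molecule that itself has
   molecular parents can open collider paths and flag a genuinely valid
   instrument as pleiotropic; orientation propagation (below) recovers most
   of the affected directions.
4. **Orientation** — valid factors are attached to molecules by the same
   conditional-independence search, then forced to point outward (genotypes
   are fixed at conception: exogeneity).  Unshielded triples are scanned
   for colliders and Meek rules 1–3 propagate directions.  An edge whose
   direction is not identified stays undirected; conflicts and would-be
   directed cycles also resolve to undirected, with a logged warning.

Two robustness choices in the collider step matter in practice.  First,
collider status is decided by a **majority vote** over all separating
subsets of the nonadjacent pair (the `maj.rule` idea from the pcalg
literature) rather than the single separating set recorded during skeleton
learning; triples with no clear vote are ambiguous and excluded from rule-1
propagation.  Second, the vote's "is this subset separating?" decision uses
a conventional `alpha_sep = 0.05`, *not* the strict edge-retention alpha:
declaring independence at p ≥ 10^-3 would accept nearly everything as
separating and poison the vote.  With a single recorded separating set and
no vote, orientation conflicts roughly double and directed-edge recovery on
simulated instrumented systems drops from ~0.93 to ~0.51.

**Node roles.**  From directed molecule edges only (undirected edges count
toward neither degree): degree-0 molecules are *independent*; out-degree 0
with in-degree ≥ 1 is an *absolute receiver*; in-degree 0 with out-degree
≥ 1 a *broadcaster*; in > out a *receiver*; anything else *mixed*.  Node
strength is the sum of incident edge strengths (−log10 worst-case p),
molecule edges only.

## Direction between bridge endpoints

Bridge edges connect layers whose networks were learned separately, so no
collider logic spans them.  Direction is probed by residual independence:
regress y on x, test dependence of the fitted residual on x with a
distance-correlation permutation test (default 1999 permutations), and
swap roles for the reverse.  Least-squares residuals are exactly
uncorrelated with the regressor, so a *nonlinear* dependence measure is
required for the test to carry information.  In the true linear direction
with independent noise the residual is genuinely independent of the
regressor, so that p-value is approximately uniform — it cannot be required
to be large.  Identification comes from the anti-causal direction: with
non-Gaussian (e.g. log-normal) noise, the reverse residual retains real
dependence on the regressor (the LiNGAM asymmetry).  The verdict rule is
therefore asymmetric rejection:

    x→y  iff  p_reverse < 0.05  and  p_forward ≥ 10 · p_reverse

and symmetrically for y→x; everything else is *inconclusive* — in
particular the bivariate-Gaussian case, where both residuals are
independent and the direction is provably unidentifiable.  Both thresholds
are configurable (`alpha_verdict`, `margin`).  An early design that instead
demanded a *large* forward p-value (≥ 0.5) was discarded: the forward test
is calibrated under the true direction, so that rule rejects the true
direction about half the time regardless of effect size.

## Stability: the Variable Reduction Test

An absolute receiver influences nothing, so deleting it cannot change any
d-separation relation among the remaining molecules; relearning on the
reduced set must reproduce the same directions.  The test removes each
absolute receiver in turn (or shuffles its values, `mode="permute"`),
relearns with the identical pipeline, and counts direction flips among
edges directed in both networks.  The report gives per-removal and whole-
network granularity; a flip usually marks an orientation that was itself a
statistical error in the full network.

## Synthetic studies

The generator emulates the target study design rather than any particular
biology: two layers from sparse linear structural equation models (random
DAG, density 0.1, weights ±Uniform(0.4, 0.8), noise SD 0.6), 24 + 14
molecules, a planted cross-layer bridge (lipid "5-HEPE" → glycan "GP21",
effect 0.5), per-molecule genetic anchors in simulated dosage panels (455 +
750 variants, Binomial(2, MAF) with MAF ∈ [0.05, 0.5]), covariate effects
(age, sex, race/ethnicity, CVD events, statin use; scale 0.2 SD), batch
location shifts (SD 0.3), nested observation (456 layer-A samples ⊇ 368
overlap ⊇ 266 genotyped), a percent-of-total compositional readout for the
glycan-like layer, and ~3% missingness in the lipid-like layer (under the
10% mean-imputation ceiling).  Noise defaults to a centered, scaled
log-normal (σ = 0.8) because residual-independence direction finding needs
non-Gaussian noise; Gaussian noise is available for null calibration.  The
compositional step adds baselines of 10–40 area-percent before closure, so
the closure denominator is nearly constant and the latent correlation
structure survives — real compositional distortion at low totals is *not*
emulated.  Linkage disequilibrium, genotype imputation error, and real
glycan biochemistry are likewise out of scope, so passing tests demonstrate
statistical correctness of the machinery, not biological realism.  An
optional two-subpopulation mode (MAF divergence ±0.1) exercises the
population-stratification adjustment.

A note on factor construction in simulation: principal components of
*independent* variant blocks with equal effects have a degenerate
(equal-eigenvalue) spectrum, so PCA mixes blocks and every factor looks
pleiotropic.  Orientation studies therefore supply the per-source
instruments directly as factor scores (the textbook valid-instrument
condition); the screen → PCA route is exercised where the spectrum is
informative.

## Numerical and procedural choices

- Percentiles for winsorization: linear interpolation between closest ranks
  (numpy default, "type 7").  Exact idempotence of winsorization holds when
  (n − 1)·pct/100 is integral; otherwise a second pass can drift by one
  interpolation gap.
- Preprocessing order is fixed: total-area normalization (compositional
  layers) → winsorize (5th/95th) → missingness policy (< 10% missing:
  mean-impute; > 50%: drop; between: drop by default, configurable) →
  standardize (mean 0, SD 1, ddof 1) → residualize on covariates
  (categoricals as indicator contrasts, batch as location shifts).
- Pairwise screen: Frisch–Waugh–Lovell partialling, algebraically identical
  to per-pair OLS (verified against statsmodels); BH adjustment supports an
  explicit family size m_total larger than the supplied vector, so a
  published subset of a known grid adjusts exactly.
- Partial correlations are clipped to ±(1 − 1e-15) before atanh; dosage
  columns with zero variance are excluded from the screen with a warning;
  strength p-values of exactly 0 are clamped to 1e-300 before −log10.
- Permutation p-values use the add-one convention (1 + #{≥ obs}) /
  (n_perm + 1) and a caller-supplied generator, so seeded runs reproduce
  byte-identically; the run-log contains no timestamps for the same reason.
- Acceptance-scale problem sizes: 20-seed batches for recovery studies,
  500 replicates for null calibration of the screen, 50 + 50 seeds with
  999 permutations for direction calibration — sizes at which every
  Monte-Carlo bound tested is separated from its threshold by several
  standard errors.

## Known limitations

- Fisher-z assumes approximately linear-Gaussian dependence after
  residualization; heavy-tailed layers are winsorized but not rank-
  transformed (nonparanormal tests are out of scope).
- The pleiotropy check conditions on one candidate target at a time; see
  the collider-opening caveat above.
- The integration step tests cross-layer pairs only; a joint re-learning
  over concatenated layers is deliberately not offered (it is the strategy
  this framework replaces).
- With no genetic instruments the only orientation information is collider
  structure; on collider-free systems (chains) the network is left fully
  undirected, by design.
- Direction verdicts for bridges are heuristic evidence, not proof: the
  asymmetric-rejection rule controls the obvious failure modes
  (Gaussianity, independence) but weak effects at modest n can still yield
  inconclusive or, rarely, wrong verdicts.
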