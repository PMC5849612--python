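# Methods

## Scope

`wingbeam` implements a quantitative inference chain for resolving the
locomotor habits of archosaurs — living birds, non-avian dinosaurs,
pterosaurs and crocodylians — from the cross-sectional geometry of their
wing (anterior limb) bones:

1. beam-theory section properties from binary cortical-bone rasters;
2. allometric body-mass reconstruction for fossil taxa;
3. phylogenetically informed multivariate statistics that first resolve
   *volancy* (can the animal fly?) and then the *flight mode* of taxa with
   unknown habits.

Manual steps that precede the quantitative chain in practice — tracing
periosteal and endosteal surfaces on tomographic slices, restoring crushed
sections, choosing the mid-diaphyseal sampling plane — are inputs here,
not operations.

## Section geometry

A section arrives as a boolean grid (true = cortical bone) with a physical
pixel size in mm. Properties:

- **CA** (cortical area) = true-pixel count x pixel_size²; before counting,
  enclosed voids other than the largest one are filled into the cortex
  (the largest enclosed space is taken to be the medullary cavity). This
  matches the convention of working from solid traced profiles in which
  vascular canals are not part of the medullary cavity.
- **TA** (total subperiosteal area) by flood fill: every false pixel not
  reachable from the grid border is enclosed by the periosteal surface and
  counts toward TA. **CA/TA** is the relative cortical thickness.
- **Second moments** Ixx = ∫y²dA, Iyy = ∫x²dA, Ixy = ∫xy dA about the
  centroid, each pixel contributing as a solid unit square about its own
  centre plus its px⁴/12 self-moment (the convention of the standard
  ImageJ section-moment macros; oracles converge under it).
- **Principal moments** are the eigenvalues of [[Ixx, Ixy], [Ixy, Iyy]];
  **J = Imax + Imin** holds exactly by construction. **theta** is the
  orientation of the Imax eigenvector, degrees in (−90, 90], measured from
  the +x (column) axis; a tie (circular section) reports 0 by convention.
- **Ellipticity** Imax/Imin is carried as a QC flag only (> 1.50 means J is
  typically overestimated); it is deliberately not used as a comparative
  character because its functional interpretation is ambiguous.
- **Vascular density** uses the separate grayscale path: connected
  components of sub-threshold pixels inside the cortical mask whose pixel
  area falls within an explicit size gate, expressed as canals per mm² of
  CA. The grey threshold and canal size range are mandatory parameters —
  no universal defaults exist across imaging set-ups.

Rasterisation in the synthetic generator counts a pixel inside a shape iff
its centre satisfies the implicit inequality (no anti-aliasing), which
keeps the discretisation-error analysis clean: CA, TA and J of an annulus
with outer radius >= 50 px agree with the closed forms to better than 1%,
and the bracket-averaged error falls roughly as 1/R (it oscillates with
fractional pixel coverage, so monotonicity is a property of the local
average, not of individual radii).

## Mass allometry

Fossil body masses come from published scaling relations. The package does
not author regressions: the relations registry
(`wingbeam/data/allometric_relations.json`) stores name, functional form,
coefficients, predictor definition, calibration range and citation text,
and is validated against the reconstructions it must reproduce — the
basal-pterosaur chain (seven wing-element lengths → 233 mm wing length,
1.56 x humeral length → 30 mm interglenoid distance, 2 x wing length +
interglenoid → 0.496 m span → 95 g) and the pterodactyloid relation
(3.270 m span → 6540 g). Because the source coefficients are not printed
in the primary literature we work from, the shipped span–mass entries use
an isometric exponent (mass ∝ span³) with the amplitude calibrated to
those two published reconstructions; the registry design lets corrected
coefficients be dropped in without a code change. Intermediates are
carried at full precision; a reporting flag reproduces conventional
osteometric rounding (30 mm rather than 29.64 mm).

## Phylogenetic machinery

- **Chronograms** are rooted trees with branch lengths in MY (dendropy
  backs parsing and serialisation). Insufficiently resolvable divergence
  nodes are placed a standard +4 MY rootward of their closest established
  crownward node.
- **BM covariance** C has C[i,j] = shared root-to-tip path length; under
  Brownian motion tip covariances are sigma² C. `simulate_bm` draws branch
  increments of variance sigma² x branch length in deterministic preorder,
  so one integer seed fixes the whole simulation table.
- **Pagel's λ** scales the off-diagonal of C. `fit_lambda` maximises the
  profile likelihood (GLS mean and rate profiled out; ML, not REML) over
  λ ∈ [0, 1] by bounded 1-D optimisation seeded from an 11-point grid.
  At 100 tips, λ = 1 data yield λ̂ >= 0.8 and i.i.d. data λ̂ <= 0.2 in
  well over 90% of replicates.
- Near-singular shared-path matrices (effectively duplicated tips) are
  factorised with an escalating ridge of at most 1e-6 of the mean
  diagonal; this changes no reported quantity at its printed precision.

## Comparative inference

- **Phylogenetic PCA**: GLS ancestral mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X,
  evolutionary covariance (X−1a)ᵀC⁻¹(X−1a)/(n−1) converted to a
  correlation matrix (mode "cor"), eigendecomposition, scores from the
  sd-scaled centred data. On a star tree this reduces exactly to ordinary
  correlation PCA; on non-star trees it matches R `phytools::phyl.pca`
  to machine precision (cross-checked in the test suite via Rscript).
  Component signs are fixed by making the largest-magnitude loading
  positive.
- **Volancy clustering**: PAM (k = 2) on the first three pPC scores, with
  Euclidean dissimilarity. When the number of candidate medoid sets is at
  most 10⁴ — which covers any two-cluster partition of a realistic taxon
  sample — the exact optimum is found by enumeration; larger problems fall
  back to the classic BUILD+SWAP heuristic (which provably can stop in
  local optima). k-means (25 restarts, seeded) on the raw parameter matrix
  provides the non-phylogenetic cross-check; the two partitions agree on
  the default synthetic data in every seed tested. Clusters are mapped to
  volant/non-volant by majority vote; the success rate is the percentage
  of labelled taxa whose mapped cluster matches.
- **Phylogenetic ANCOVA**: the observed F for the locomotor-group effect
  in y ~ covariate + group is referred to a null distribution of F values
  computed on responses re-simulated under BM along the tree (rate and
  root state estimated from the data by GLS, equivalent to the
  independent-contrasts estimator), with the design held fixed. Only the
  response is simulated; co-simulating the covariate is a possible
  alternative we did not adopt because the covariate enters the design as
  a fixed regressor. The empirical p uses (1 + exceedances)/(1 + n_sims)
  so it is never exactly zero. Under the BM null the rejection rate at
  α = 0.05 sits within [0.03, 0.08] (200 replicates x 1000 simulations;
  the estimator is slightly conservative by construction). Locomotor
  groups represented by a single taxon carry no within-group df and are
  set aside (and logged) by the pipeline stage; the core routine treats
  them as an error.
- **LDA**: Fisher axes from the generalised eigenproblem B v = λ W v
  (pooled within-group covariance W, between-group scatter B; number of
  axes = min(groups − 1, variables)); classification by minimal
  Mahalanobis distance to group means in the pooled metric with equal
  priors (appropriate for small, unbalanced palaeontological groups;
  proportional priors are a configuration switch away). Accuracy is
  resubstitution percent-correct and is invariant under any invertible
  affine transform of the variables. Singleton groups are allowed: they
  contribute a mean (and can attract mystery taxa) but no within-group
  scatter. Mystery taxa are excluded from all fitting and classified
  afterwards; ties are broken by group order and flagged.
- **MANOVA**: Wilks' Λ = det(W)/det(W+B) with Rao's F approximation;
  pairwise contrasts by Hotelling's T² with Bonferroni correction
  (configurable). With one variable and two groups the F reduces exactly
  to one-way ANOVA.
- **λ screening**: per-variable λ̂ with a likelihood-ratio test against
  λ = 0 (χ²₁ reference, Bonferroni-corrected across the four variables —
  the boundary at λ = 0 makes the per-variable test conservative, which is
  the safe direction for this gate). If no variable rejects independence,
  plain LDA is recommended; otherwise data should be pre-whitened by the
  λ-scaled covariance (`whiten_by_lambda`) before discriminant analysis.
- **Transforms**: J/M spans orders of magnitude, so the default pipeline
  log10-transforms it and leaves CA/TA raw; a standardise switch exists.
  Whether the original analyses log-transformed or standardised is not
  recorded, so this is exposed as configuration rather than hard-coded.

## Synthetic data: what it emulates, what it does not

`make_dataset` emulates the statistical structure the analyses assume:
69 taxa in 13 locomotor categories (5 avian flight modes per scheme,
volant wing-propelled diving, two pterosaurian modes, and five non-volant
modes), on a star, balanced or pure-birth chronogram scaled to 250 MY
depth, with categories occupying contiguous clades. Traits are category
means + BM deviations simulated along the tree + i.i.d. noise; body
masses are log-uniform per category, spanning 10 g to 10⁶ g overall
(five orders of magnitude). Construction guarantees: volant category-mean
CA/TA < 0.60 < non-volant; J/M rising from flapping-dominated flight to
soaring; adjacent flight modes separated by >= 5 pooled-SD Mahalanobis
distance so that volancy clustering (>= 95% success), PAM/k-means
agreement, and unanimous classification of planted burst-like mystery
taxa hold with comfortable margin rather than by luck of a seed.
Defaults: noise SD 0.012 (CA/TA) and 0.04 (log10 J/M); BM rates 6.4e-7
and 2.56e-6 per MY (marginal BM SD ≈ 0.013 and 0.025 at the tips).

What the generator does **not** emulate: measurement error correlated
between humerus and ulna of one individual, taphonomic deformation,
intraspecific and ontogenetic variation, category overlap as strong as in
real avian flight-mode data (where resubstitution accuracy is nearer 55%
than 95%), or non-BM evolutionary processes. Passing tests therefore
demonstrate correctness of the machinery under its stated model, not that
real archosaur data will be this well-behaved.

`make_mystery` draws unlabeled rows from one category's generative model
(mean + i.i.d. noise, no tree), standing in for fossil specimens of
unknown habit; the true category is recorded for test bookkeeping only.

## Problem sizes and determinism

The shipped verification suite uses desk-scale sizes chosen to make every
Monte-Carlo bound decisive: 20 generator seeds for the end-to-end
properties, 200 replicates x 1000 BM simulations for ANCOVA calibration
(the analytic vectorisation of the F statistic over simulated responses
makes this cheap), 50 replicates at 100 tips for λ recovery, and 100
random instances against exhaustive search for PAM. Every stochastic
routine takes one explicit integer seed; identical config + seeds
reproduce byte-identical output tables.

## Known limitations

- TA uses strict flood fill; marginal cracks reaching the border are not
  closed and would locally deflate TA (restoration is upstream, manual).
- The BUILD+SWAP PAM path (used only beyond the enumeration bound) can
  return local optima, as all classic PAM implementations can.
- The ANCOVA null simulates the response only (see above).
- Allometric amplitudes are calibrated to two published reconstructions,
  not refitted to specimen data; the crocodylian relation has no published
  output to pin it and should be treated as indicative.
- The λ likelihood-ratio test uses the plain χ²₁ reference; the λ = 0
  boundary halves its effective size, which we accept as conservative.
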