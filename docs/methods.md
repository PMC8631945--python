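# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data generator does and does not emulate.

## Lever model and MA curves

The mandible is treated as a rigid lever. In 2D (compression fossils) the
joint is a single pivot point — if both condyles were digitized on a
flattened specimen, their midpoint; in 3D it is the line through
condyle_anterior and condyle_posterior, and every moment arm is a
perpendicular distance to that axis (the axial component exerts no
moment). The outlever is the straight-line moment arm, not the arc
distance, because lever mechanics acts through moment arms.

The gnathal-edge polyline is resampled at `n_points` positions equally
spaced in cumulative chord length; MA at each position is
inlever/outlever. The direction convention is `s = 0` proximal (molar
region) to `s = 1` distal (incisivus apex), so curves decrease.
`n_points` defaults to 100; analyses of coarsely digitized edges should
sample at the digitized density (the study pipeline does), because
resampling more finely than the digitization interpolates between noisy
vertices and correlates adjacent measurement errors. Raw curves are never
smoothed: the polynomial fit is itself the smoother.

Degenerate inputs are rejected rather than repaired: a zero outlever (an
edge point on the joint axis) reports the offending `s`; an adductor
attachment on the joint, repeated consecutive edge points, and
non-finite coordinates are errors.

## Procrustes alignment and the composite fossil

Generalized Procrustes analysis translates each configuration to its
centroid, scales it to unit centroid size, and iteratively rotates each
onto the running mean (itself renormalized), stopping when the summed
squared Procrustes distance changes by less than `tol = 1e-10` (at most
100 iterations). Scaling is always to unit centroid size — MA is
dimensionless, and downstream use is shape-only. Reflections are never
applied silently: mirroring flips the chirality of lever geometry, so
left/right standardisation is an explicit `reflect_to_reference` step
(negation of the first coordinate axis) driven by the recorded side of
each specimen.

The superimposition is defined only up to one global rotation; the
solution is oriented so the mean shape best aligns with the first input
configuration. This gauge makes the mean of identical inputs equal the
normalized input exactly and makes re-aligning an already-aligned set an
identity (to roughly the square root of the convergence tolerance).
Alignment is invariant to similarity transforms of any specimen except
that rotating the *first* specimen rotates the shared frame — a pure
gauge effect with no influence on distances, the mean shape, or any
downstream statistic.

The composite fossil mandible is the GPA mean shape of the fragment
configurations, which must share one complete ordered label set including
the semantic roles (no missing-landmark imputation); the roles are
retained so lever geometry can be derived from the composite.

## Functional space

Polynomials are fitted by ordinary least squares on the monomial basis in
`s ∈ [0, 1]` (the common domain makes coefficients comparable across
specimens). The common order minimises the pooled least-squares AIC: per
curve, a Gaussian likelihood at the MLE variance `rss/n` and `order + 2`
parameters (coefficients plus one variance), summed over curves. Ties
break toward the lower order. `rss` is clamped at 1e-300 so numerically
perfect fits cannot produce infinite likelihoods; note that for exactly
noise-free data AIC differences at roundoff scale are meaningless, so
order-selection behaviour is only specified in the presence of noise.

The descriptor matrix uses the non-intercept coefficients by default
(five descriptors at order 5); the intercept is nearly collinear with the
curve level already carried by the slope coefficients on [0, 1], and the
`include_intercept` policy is available. PCA is performed on the
covariance matrix by default (all descriptors share the same
dimensionless units); correlation-mode standardisation is an option that
errors on zero-variance descriptors. Component signs are fixed by forcing
the largest-magnitude loading of each component positive, applied
identically in PCA and pPCA.

## Phylogenetic comparative layer

The Brownian covariance `C` has entries equal to the depth of the most
recent common ancestor of each tip pair; the root sits at depth zero and
a root edge, if present in the Newick source, is ignored (the convention
of standard BM covariance constructions). Polytomies and zero-length
branches are allowed; negative branch lengths are errors; a singular `C`
(duplicate zero-depth tips) raises with a suggestion to adjust branch
lengths.

Blomberg's K follows the standard construction (observed MSE ratio about
the GLS phylogenetic mean over its Brownian expectation); `K_mult` sums
squared deviations over descriptors in both numerator and denominator and
reduces exactly to K for one column. Both the per-descriptor univariate K
vector and the single K_mult are reported; K_mult is treated as the
multivariate analogue of a single printed signal statistic. The
permutation test shuffles trait rows across tips with the tree fixed
(9999 permutations by default, seed mandatory) and uses the add-one
p-value, whose smallest attainable value at 9999 permutations is 0.0001.

Phylogenetic PCA computes the GLS mean and the evolutionary covariance
`R = (X − 1a)' C⁻¹ (X − 1a)/(n − 1)`, eigen-decomposes `R`, and scores
every tip — the fossil included — in that single decomposition (no
two-stage projection). When `C` is proportional to the identity the
result equals ordinary PCA up to the shared sign convention. A warning is
issued when tips do not outnumber descriptors. Cholesky factorisation is
used throughout; eigenvalues of `R` are clipped at zero before variance
percentages are formed.

The fossil tip is grafted onto a stem edge chosen by the user
(`Phylogeny.attach_tip`): the edge above a named tip or the MRCA of a
label pair is split at a configurable fraction (default one half), and
the pendant branch defaults to reaching the depth of the deepest existing
tip. The synthetic study grafts its fossil onto the stem of the omnivore
clade.

## Synthetic study design

The generator's defaults define the study conditions; every test and the
acceptance analysis run at these values.

**Profiles.** Each diet class has a target MA profile. All three classes
live on one exponential family `ma(s) = level·exp(−curvature·s) + floor`
(floor 0.1): herbivores level 0.6 with curvature 0.35 — a gently curved,
"almost linear" decrease — omnivores 0.45/0.8, carnivores 0.3/1.5. A
strictly linear herbivore base was rejected during design: with two
different functional families the three class means form a bent triangle
in coefficient space, and the intermediate profile then projects outside
the herbivore–carnivore chord on PC1 in a quarter of replicates, which
contradicts the biological reading of "intermediate". A `linear` profile
shape remains available.

All species share a tooth-row relief waveform — shifted-Legendre P3/P4/P5
amplitudes (0.06, 0.05, 0.04) added to the base profile and scaled by the
species' level — plus small heritable per-species deviations (Brownian,
tip sd 0.004 per amplitude). The relief gives the curves genuine,
exactly fifth-order structure, which is why pooled AIC selection settles
at order 5 on study data; its level-scaling makes the leading coefficient
axis coincide with the level axis, so PC1 orders the diet classes.

**Inverse construction.** `mandible_from_profile` places edge vertices at
exactly uniform arc-length fractions with radii `1/ma*(s)` around a pivot
at the origin and a unit inlever: the radii are fixed by the profile and
the fan of directions is solved by bisection for the common chord length
spanning the fan angle (the fan widens automatically when a steep profile
needs a longer arc). At zero noise, `ma_curve` recovers the target
profile to the chord-interpolation error, below 1e-6 at the default 1600
edge vertices — the construction is its own oracle.

**Noise model.** Digitization error is applied along the local edge
normal only (sd 0.005 in inlever units, i.e. 0.5% of the inlever), while
the condyle and adductor attachment are exact: sliding a point along a
continuous contour is not an error, and sharply defined anatomical points
are digitized much more precisely than a worn tooth edge. Two artefacts
motivated this model and the coarse default digitization (50 edge
points, MA sampled at that density): tangential noise components inflate
the measured arc length into a smooth random warp of the `s` axis, and
resampling more finely than the digitization correlates neighbouring
errors — both masquerade as high-order curve structure and drive the
pooled AIC to the top of its candidate range.

**Phylogeny and trait evolution.** Trees are pure-birth (Yule, unit
rate, two starting lineages, a final waiting time after the last split).
Diet classes are assigned by packing whole subtrees depth-first into the
classes in fixed order, so each class is a union of a few genuine clades
and phylogenetic signal exists by construction. Species deviate from
their class profile by Brownian jitter on level (tip sd 0.04), curvature
(0.12) and the relief amplitudes (0.004), with clipping to keep profiles
valid (level in [0.1, 1.5]; exponential curvature in [0.2, 3]). The
fossil is the exact omnivore default profile, fragmented into four copies
(random rigid motion, reflection with probability one half, isotropic
landmark noise sd 0.02) and recomposed by GPA.

**What the generator does not emulate.** Real tooth rows are not smooth
degree-5 waveforms; real digitization error is not exactly normal to the
edge; diet classes are not perfectly clade-aligned; fossil distortion is
taphonomic shear, not isotropic noise; and 3D extant mandibles are
generated only as 2D configurations (the 3D lever path is exercised with
hand-built geometries in the tests). Passing tests therefore validate the
computational chain and its statistical behaviour under a controlled,
realistic-in-structure world — not the anatomical fidelity of any curve.

## Problem sizes

The test suite and the acceptance analysis run at the design scale of the
comparative study: 43 extant species plus one composite fossil, 50 edge
points per mandible, order selection over candidates 1–8 (1–6 in
replicate loops), 9999 permutations for the headline signal test and 199
inside calibration loops, 50 study replicates for the fossil-centrality
rate, and 100–200 replicates for Monte-Carlo checks. These sizes give
stable statistics while keeping any single check to seconds.

## Known limitations

- High-order monomial coefficients are ill-conditioned descriptors; with
  very noisy curves the variance of the top coefficients can swamp
  biological structure. The package reports the AIC table so users can
  judge whether the selected order is noise-driven.
- K_mult weights descriptors by raw variance; descriptors on wildly
  different scales should be ordinated in correlation mode or rescaled
  before signal testing.
- GPA assumes a complete common landmark set; there is no missing-data
  imputation or sliding-semilandmark machinery.
- The permutation null shuffles tips freely and is exchangeable only
  under no signal; it is a significance test, not a K confidence
  interval.
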