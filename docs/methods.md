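# Methods

This note documents the model, the numerical choices, and the synthetic
study design behind `tmstarget`, at the level of detail a user needs to
judge what the package's tests do and do not establish.

## Model chain and conventions

All model vectors live on the gray-matter voxels of one reference grid
(`VoxelGrid`): world coordinates are MNI-style mm, voxel indices 0-based,
and the NIfTI affine maps index → mm, so externally produced volumes drop
in unchanged. Volume I/O zero-fills outside the mask; maps with NaN inside
the mask are rejected rather than silently dropped.

**Scalp coordinates.** CPC is constructed by plane slicing: the sagittal
curve is the surface section through NZ, IZ and the preauricular midpoint
(for a perfectly symmetric head, where that midpoint degenerates onto the
NZ–IZ axis, the plane through NZ and IZ perpendicular to the ear-to-ear
axis is used); the coronal curve for a given `p_nz` is the section through
AL, AR and the sagittal point at that arc fraction. Curves are exact
triangle–plane intersection chains, not vertex shortest paths, so they
have no staircase bias and the forward-map error halves (at least) with
each mesh subdivision — a property the tests check against the closed-form
sphere parameterization. The inverse map finds the coronal plane
containing the query point by bisection on the signed plane distance, a
smooth 1-D root for star-convex heads. Poles (`p_nz ∈ {0, 1}`) are
rejected rather than silently collapsed.

**Coil frame.** The 0° direction at `s` is the tangent-plane vector
perpendicular to the intersection of the tangent plane with the plane
through `s`, AL and AR, oriented toward IZ ("backward"). θ rotates the
handle about the outward normal with the right-hand rule, which makes
anticlockwise-from-outside positive; the frame is orthonormal to 1e-9.
The tangent normal is the area-weighted average of the face normals in
the nearest vertex's 1-ring, pointed away from the landmark centroid.

**Local effect.** `threshold_efield` keeps voxels at or above
`percent/100` of a robust peak, defined as the 99.9th percentile (upper
rule) of suprazero gray-matter magnitudes — stable against single-voxel
FEM spikes while equalling the maximum on small supports. Weights default
to the voxel's E-field magnitude (an "E-field-weighted" profile); a
uniform-weight mode exists for users who prefer the flat convention. The
default threshold is 75%, the inclusive end of the 75–99% band swept by
the sensitivity analysis. Frequencies in (1, 5] Hz are rejected as
unclassified rather than guessed.

**Stand-in E-field.** Where no FEM volume is supplied, the analytic
stand-in is `peak · exp(−r²/2) · exp(−d/λ)` with an (optionally
anisotropic) tangential Gaussian footprint (`σ` = 10 mm default, about the
centimeter-scale focality of a figure-8 coil) and exponential depth decay
(`λ` = 20 mm). Depth is clipped at zero above the coil plane. The default
footprint is isotropic; setting `sigma_across < sigma_tangential`
emulates the elongated focus of a figure-8 coil and is the only mechanism
by which orientation matters in the stand-in. The stand-in uses the field
magnitude (no cortical-normal component — no cortical surface is modeled
at this scale); external volumes are consumed as-is, in V/m, never
rescaled.

**Stimulation network.** `E_n = C·E_l/‖E_l‖₁` with the 1-norm taken over
absolute weights, so excitatory and inhibitory protocols give exactly
negated networks and, for a correlation-valued `C`, `E_n` is a convex
combination of columns bounded in [−1, 1]. `C` stores raw Pearson r (a
Fisher-z input is accepted as-is if that is what the user supplies). The
dense backend materializes `C`; the lazy backend keeps the
column-standardized time series `X` and computes `C·v` as `X'(Xv)/(T−1)`;
the two agree to 1e-8 by contract and are interchangeable everywhere.

**Pathology.** `P = I_pt − I_hc`, or for foci tables the signed sum of
hard spheres (binary indicators, additively combined — preserving the
linearity of the difference-map formulation) evaluated at voxel centers.
Default radius 10 mm, the midpoint of the 4–16 mm sensitivity range.
Foci outside gray matter are kept; only their in-mask portions contribute.

**NTA and optimization.** `NTA = −corr(E_n, P)` with plain Pearson over
all gray-matter voxels (a flag to exclude the stimulated support exists
but is off by default — nothing in the model formulation requires the
exclusion, and including all voxels keeps NTA a pure map comparison).
`grid_search` evaluates the full position × orientation product with no
early stopping; failed placements become missing cells excluded from the
argmax; ties break lexicographically (lowest position index, then lowest
orientation index). The ANOVA is the balanced two-way fixed-effects
decomposition with subjects as replicates; missing cells void it rather
than being imputed, and p-values use the plain F distribution.

## Cohort statistics

The model's hypothesis is directional (higher NTA → more improvement), so
all tests are one-tailed for r > 0. Permutation p-values use the add-one
correction `p = (1 + #{r* ≥ r_obs})/(1 + n_perm)`, guaranteeing validity
and p > 0; the default `n_perm` is 10⁵, scaled down in the seeded
simulation studies (10³) where 200 replicates are run. The
network-relocation null rebuilds the pathological map with every focus
moved to a uniformly sampled gray-matter voxel, preserving foci count,
signs and weights; relocating the pathological map (rather than permuting
the connectome) is the implemented null, and reports label it as such.
Partial correlation residualizes both variables on [1, covariate] and
tests with n − 3 df; sex is a binary indicator, no interactions.

## The synthetic study

The generator emulates every input at desk scale:

* **Head**: an icosphere (subdivision 4, ~2,500 vertices) scaled to an
  85 mm sphere/ellipsoid, with NZ/IZ on the anterior/posterior midline
  and AL/AR lateral, all on the equator.
* **Gray matter**: a 14 mm-thick shell 2 mm under the scalp, 6 mm voxels
  (~2,200 voxels), restricted to the upper head (z > 0.05 R) where TMS
  placements project.
* **Connectome**: voxels partition into K = 2 spatially contiguous
  azimuthal sectors (anterior/posterior). Each voxel's series mixes its
  network factor (within-network correlation 0.45; between-network
  −0.30, anti-correlated like task-positive/task-negative systems) with
  idiosyncratic noise over T = 600 timepoints — roughly an 8-minute
  resting scan at sub-second TR. A **mirror-circuit** component adds
  smooth spatial bumps (15 mm scale, about the size of a functional
  patch) whose loadings in the posterior network are negated at the
  front-back mirrored position of the anterior network. This emulates
  specific long-range antagonistic pairs (in the spirit of the
  DLPFC–subgenual pairing that motivates depression targeting) and is
  what makes the NTA landscape peak at a unique scalp site: with a
  purely block-constant connectome, NTA is flat across the entire
  anti-correlated network and no placement is identifiably optimal.
* **Pathology**: hyperactive foci at the four target-network voxel
  centers closest to the planted direction (anterior-superior, 45° above
  the horizontal); the true optimal cortical site is its front-back
  mirror at mid-shell depth, whose scalp projection is computed with the
  same normal-alignment restoration the model exposes for literature
  targets.
* **Cohort**: per-subject connectomes are independent finite-T draws of
  the same population model; placements are jittered (CPC sd 0.12)
  around — and therefore also away from — the planted optimum, as in a
  retrospective cohort all treated over one broad region; outcomes are
  `β·NTA + ε` with Gaussian noise (default sd 0.05, a moderate clinical
  coupling), or with the noise chosen to hit a target population
  correlation when a study requires a fixed effect size.

What the generator does **not** emulate: cortical folding and true FEM
field geometry, BOLD autocorrelation, scanner/site heterogeneity, and
individual head-shape variation (subjects share the analytic head, and
vary in connectome realization and placement). Passing tests therefore
show that the algorithmic chain is correct and statistically calibrated
under a faithful miniature of the study design — not that the model is
clinically validated; the clinical cohorts' headline correlations require
private imaging data and are out of reach by construction.

## Numerical choices and degenerate inputs

* Correlations guard against zero variance (error, not NaN) and clip to
  [−1, 1] against round-off.
* `robust_peak` uses the 'higher' quantile rule so tiny supports behave
  exactly like a maximum.
* Landmark/section tolerances scale with the mean edge length (snapping
  tolerance 1.5 edges; off-surface rejection at 3 edges), so refinement
  tightens every geometric guarantee.
* The argmax tie-break, the restore-placement tie-break (angle, then
  distance to target, then distance to the landmark centroid, then vertex
  order), and all RNG seeding are fully deterministic.
* Seeds fan out from one `SeedSequence`, so a study is bitwise
  reproducible from its single seed.

## Study sizes used by the seeded validation runs

Planted recovery: 20 subjects on an 8 × 8 position grid ([0.2, 0.8]²) ×
12 orientations (0° to −165°, 15° steps), recovery counted when the
argmax position is within one grid step of the planted projection. Null
calibration: 200 replicates of β = 0 cohorts (n = 15), 1,000 permutations
per test, rejection compared with the exact binomial 95% interval around
α = 0.05. Power: 50 replicates at a population correlation of 0.9 with
the power floor locked at 80% from the pre-release oracle run (the run
itself measured 100% for both nulls under these seeds). Threshold
stability: 10 connectome seeds × 25 placements, Spearman between the 75%
and 99% NTA vectors (all ≥ 0.98 in the oracle run, floor 0.8). These
sizes are the package's chosen study conditions; they keep each validation
run in the minutes range on a single CPU.
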