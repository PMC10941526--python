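# Methods

## The Vogt-Bailey (VB) index

At each vertex of a cortical surface mesh the VB index quantifies how
homogeneous the local multivariate tissue microstructure is. Six
diffusion-derived metrics describe every brain-tissue voxel: fractional
anisotropy (FA), mean/axial/radial diffusivity (MD, AD, RD), and the NODDI
neurite density and orientation dispersion indices after modulation by the
tissue fraction 1 − ISO (NDI_mod, ODI_mod). Per subject, each metric volume
is z-scored over the tissue mask (population SD, ddof 0) so that a voxel
carries a standardized 6-vector.

The searchlight is *hybrid*: the vertex's mesh one-ring (the vertex plus its
edge neighbours) is mapped to nearest voxels through the inverse affine with
round-half-away-from-zero, and only masked voxels inside the 3×3×3 index
cube centred on the vertex's own voxel are kept (deduplicated). Working in
index space keeps the cube well defined for anisotropic voxels. Over the
n matched voxels an affinity graph is built: edge weight = Pearson
correlation of the two 6-vectors across the feature dimension, negative
values clipped to 0, zero-variance vectors assigned 0. The VB index is the
algebraic connectivity λ₂ of the unnormalised Laplacian L = D − W divided
by n. Division by n is the unique linear scaling for which the maximally
homogeneous neighbourhood — a complete graph with unit weights, whose λ₂
equals n — scores exactly 1; a disconnected affinity graph (a sharp feature
transition through the searchlight) scores 0.

Numerical choices: full symmetric eigendecomposition (n ≤ 27 makes iterative
solvers pointless), eigenvalues sorted ascending, index 1; eigenvalues in
(−1e−10, 0) are clipped to 0 and anything more negative is an error.
Neighbourhoods with fewer than 3 masked voxels, or whose centre voxel is
unmasked, yield a missing value — λ₂ of a 2-node graph is just twice the
single edge weight and carries no connectivity information. Failures are
per-vertex; a map never aborts.

The exact "modified" Pearson variant used by the original VB toolbox is not
restated in our source description, so the affinity is standard Pearson with
positive clipping, isolated behind `vb_core.affinity` so it can be swapped
without touching the spectral code. Bit-compatibility with the released
toolbox is not claimed.

## Surface smoothing

Per-vertex maps are smoothed with a single-pass Gaussian kernel,
σ = FWHM / (2√(2 ln 2)), over graph-geodesic distances (Dijkstra with
Euclidean edge lengths) truncated at 3σ (< 1.2 % of kernel mass) and
renormalised to row-stochastic weights. Geodesic rather than 3D Euclidean
distance is the standard surface choice: it cannot leak across a sulcus.
Missing vertices are excluded from every sum with renormalisation over the
present neighbours; a missing vertex stays missing. The default FWHM is
4 mm; `scripts/acceptance.py` measures the impulse response of this
operator on a 0.5 mm planar lattice and recovers a full width at half
maximum of 4.0 mm.

## Group inference

Smoothed VB maps enter a vertex-wise OLS model with columns (intercept,
group [preterm = 1], PMA at scan centred, sex centred 0/1). Both one-sided
group contrasts are tested. The t maps are enhanced with TFCE,
TFCE(v) = Σ_h e_v(h)^E · h^H · dh over the ladder h = dh, 2dh, …, ≤ max,
with E = 1, H = 2, dh = max/100 per map (the established surface defaults);
extent e_v(h) is the surface area — barycentric vertex areas — of the
connected component of {t ≥ h} containing v under one-ring connectivity.
The implementation processes thresholds top-down with an incremental
union-find (numba-compiled), which is exactly equivalent to per-threshold
component labelling and near-linear in practice.

Family-wise error is controlled by the permutation distribution of the
maximum TFCE value over vertices. Permutations use the Freedman–Lane
scheme: residuals of the nuisance-only model (intercept, PMA, sex) are
permuted, the nuisance fit is added back, and the full model is refit.
Corrected p-values follow (b + 1)/(m + 1); when the requested permutation
count reaches the number of distinct relabelings the test enumerates
exhaustively (identity included, p = b/m, exact). Significance over the two
hemispheres is assessed at the Šidák level 1 − 0.95^(1/2) ≈ 0.0253; the two
hemispheres are always analysed as independent runs.

Subject rows are internally re-ordered into a canonical order derived from
the design matrix, making every output — including the Monte-Carlo
permutation stream — independent of the order subjects were listed in.

An optional per-vertex nuisance map (e.g. sulcal depth) can be regressed
out of the stacked maps before inference: per vertex, the across-subject
map vector is regressed on (intercept, nuisance) and replaced by
residual + intercept, preserving the grand mean; constant nuisance values
leave a vertex untouched.

## Synthetic cohorts

The generator provides ground truth for every downstream stage. The surface
is an icosphere (4-way icosahedron subdivision, vertices projected to the
radius); a closed convex surface stands in for a hemisphere — no folding is
simulated, because the searchlight operates on native-space voxels and the
gyrification-specific artefacts the hybrid neighbourhood exists to avoid
cannot arise on it. The surface is partitioned into connected
geodesic-Voronoi patches (farthest-point seeds, multi-source Dijkstra label
growth, ties to the lowest patch id), emulating cortical areas with sharp
boundaries. The voxel grid encloses the mesh with a 2-voxel margin; the
tissue mask is the 3×3×3 dilation of the voxel shell occupied by vertices.
Each masked voxel inherits the patch of its nearest vertex and draws

  feature = patch_mean + PMA · slope + N(0, sd²) per channel,

with the patch means placed as a scaled standard-basis simplex at mutual
distance `patch_mean_separation` (hence patch_count ≤ 6 channels). The
group effect multiplies the noise SD by `homogeneity_boost` ≤ 1 for preterm
subjects inside `effect_patches` — more homogeneous local microstructure,
which is precisely what the VB index measures; boost = 1 gives a null
cohort with exchangeable group labels. PMA is uniform over `pma_range`,
sex alternates, and every subject gets a deterministic child seed.

Defaults (the study conditions): subdivisions 2, radius 4 mm, 1 mm voxels
(~1 mm edge length, so one-rings land inside the 27-voxel cube), 6 patches,
separation 3.0, noise SD 1.0, boost 0.5 in patches {0, 1}, PMA 38–43 weeks,
per-channel PMA slopes 0.01–0.06/week. Because z-scoring is per subject,
the PMA shift is removed exactly during standardisation: the covariate
column is genuinely null downstream, which is the intended role (a real
nuisance column for Freedman–Lane), not a modelling accident.

What the generator does not emulate: realistic dMRI noise or Rician bias,
partial-volume/CSF contamination, folding geometry, registration error, or
spatially correlated noise. Passing tests therefore demonstrate the
correctness and calibration of the estimator and the inference machinery
under the piecewise-homogeneous model, not robustness to acquisition
artefacts.

## Validation experiments and problem sizes

- **Type-I calibration**: 200 null cohorts (boost 1.0, 10 subjects/group) on
  the default small sphere, 200 permutations each. The fraction of cohorts
  with any vertex significant at 0.0253 in the preterm>term direction must
  lie in the exact binomial 95 % CI of the nominal level (measured 5/200 =
  0.025). The FWE level does not depend on mesh size, so the small surface
  is the appropriate scale for a 200-cohort experiment.
- **Power/recovery**: 10 cohorts with boost 0.5 and 15 subjects/group on a
  subdivisions-3, radius-12 mm sphere with 1.25 mm voxels. The larger
  surface is a resolution requirement, not a convenience: the 4 mm kernel
  spreads a strong effect ~1.3 mm beyond the planted boundary, and on a
  radius-4 sphere that halo alone exceeds a 0.2 false-discovery proportion
  however well the method localises. Measured: sensitivity ≈ 1.0, FDP
  0.03–0.09.
- Permutation counts are 200 rather than 10,000 (the production default in
  `RunConfig`): the attainable minimum p of 1/201 ≈ 0.005 sits comfortably
  below the 0.0253 threshold, which is all calibration requires.

## Known limitations

- The affinity is plain clipped Pearson; any proprietary modification in
  the original toolbox is out of scope (seam documented above).
- The convex synthetic surface cannot exhibit the cross-sulcal artefacts
  that motivate the hybrid searchlight; the hybrid rule is exercised
  geometrically (cube clipping, deduplication, mask handling) but its
  anatomical benefit is not testable here.
- Missing-data handling in inference is all-or-nothing per vertex (any
  missing subject ⇒ missing vertex), matching a complete-case
  massively-univariate GLM.
- TFCE p-values at vertices with TFCE = 0 are 1 by construction; no
  variance smoothing or tail approximation is implemented.
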