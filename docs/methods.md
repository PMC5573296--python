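# Methods

This note records the models, conventions and design choices behind
`atlaskit`, in the spirit of a methods section: what each stage computes,
which knobs matter, and what the synthetic cohort does and does not show.

## Cohort tables and provenance

The packaged reference cohort transcribes a published 30-subject study of
the parietal lobe: per-subject intracranial volume (ICV), brain volume,
age and gender, and per-hemisphere morphology of the supramarginal (SMG)
and angular (AG) gyri — sulcal slice landmarks, extent percentages,
additional-gyri counts, PISJ prominence (ordinal 0–3), connection flags,
and SMG/AG volumes in MNI space. Left and right hemispheres are stored as
one long table with a `hemisphere` column so paired operations need no
joins. Native per-subject SMG/AG volumes were never published and are not
fabricated; cohort-level native statistics are packaged separately
(`table4_volume_stats.csv`), as are the published leave-one-out fusion
metrics (`table11_fusion_results.csv`, region means only).

Three cells of the source tables are internally inconsistent and are
handled explicitly rather than silently:

* **a06, left AG extent**: the printed landmarks (sup 45, inf 85, top 52)
  give 83 %, but the table prints 77 % — exactly the value obtained if the
  ipsilateral SMG superior limit (42) anchors the denominator. The tests
  assert both facts; the other 119 extent cells recompute exactly.
* **left AG GM mean**: the exact column mean is 12 732.53 mm³; the table
  prints 12 732 (truncated; its SD rounds normally).
* **left AG GM+WM CV%**: the exact value is 30.4999; the printed 31 arises
  from re-dividing the already-rounded SD by the mean.

## Morphometry

Sulcus vertical extent: `pct = 100·(inf − top)/(inf − sup)`, where `sup`
and `inf` are the region's superior/inferior limits as axial slice indices
(increasing inferiorly) and `top` the superior end of the sulcus. Rounding
is half-up to an integer — the convention is fixed empirically by a
half-case in the reference data (62.5 printed as 63) and used package-wide
for presentation rounding. A sulcus is *long* (1) when `pct ≥ 50`; the
source protocol wording ("< 50 % = short") leaves the boundary itself
open, and `≥ 50 → long` is this package's documented convention (the
reference data contain no pct = 50 instance).

Footer statistics use the arithmetic mean, the sample SD (n−1 denominator,
confirmed against every printed SD in the reference tables), CV% =
100·SD/mean (undefined and reported missing when the mean is 0), the
even-n median as the midpoint of the two central order statistics, and,
for binary scores, Sum% = the integer percentage of subjects scoring 1.

## Volumetry

Volumes are voxel counts times the voxel volume (|det| of the affine's
spatial block); no partial-volume weighting is applied, as label rasters
are categorical. Grey-matter volumes intersect the label raster with a
binary tissue mask (mask ∧ label), mirroring the multiplication of tissue
masks into delineation images; masked volume is therefore never larger
than the unmasked volume. Lobe totals sum the four ipsilateral regions;
percent-of-lobe and asymmetry use half-up presentation rounding (integers
and one decimal respectively). The paired L/R comparison is the classical
two-tailed paired t-test with n−1 df; zero-variance difference vectors are
reported exactly (t = 0, p = 1 for identical inputs; p = 0 for a constant
nonzero offset) rather than as numerical noise.

Spatial normalisation, tissue classification and ICV estimation are
deliberately out of scope: the `space` tag (`native`/`common`) is carried,
not created — common-space inputs are supplied by the user or generated
synthetically, and ICV normalisation is an optional divisor using supplied
values.

## Correlation screen

Every unordered pair of numeric cohort variables is rank-correlated
(Spearman, ties averaged; binary and ordinal variables enter as-is), with
the two-sided p-value from the t-approximation
`t = r·√((n−2)/(1−r²))` — standard at n = 30, where exact permutation adds
nothing. No multiple-testing correction is applied; the screen mirrors a
fixed reporting threshold (default p < 0.005), and a Bonferroni column is
emitted for information only. Pairs coupled by construction — a gyri total
against its addends, an extent percentage against its own landmarks, the
length flag against its percentage, nested GM+WM/GM volumes, and the
duplicated lobe inferior limit recorded in both region blocks — are
flagged `trivial` so downstream reporting can set them aside. Constant
columns and pairs with fewer than three complete observations are skipped
with a log entry.

## Probabilistic and maximum-probability atlases

Given n co-aligned label volumes, the probabilistic map of region r is the
voxelwise subject fraction `p_r(v) = n_r(v)/n` (values exact multiples of
1/n; regional fractions plus the background fraction sum to 1). Grey-matter
masking is offered in both orders: per-subject masking *before* averaging
(the default, mirroring masks multiplied into individual atlas images) and
masking of the averaged map. The maximum-probability atlas assigns
`argmax_r p_r(v)`, background where all probabilities vanish; ties break
to the lowest region code — the argmax rule is inherent to the construct,
the tie-break is this package's documented convention. `probability_extent`
returns the world-space bounding box of voxels at or above a probability
threshold; differencing homologous boxes quantifies positional asymmetries
such as the brain torque.

## Label propagation and fusion

Registration is strictly behind the `TransformProvider` contract; no
registration algorithm is implemented. Three providers are bundled:
identity (a deliberate lower bound), the synthetic generator's exact warps
(an oracle upper bound), and precomputed dense displacement fields read
from NIfTI vector images (pull-back convention, target world → source
world). Label resampling is nearest-neighbour only. Fusion is per-voxel
majority vote with ties to the lowest code — the fusion rule in the
source experiment's software is not described, and plain vote is the
standard baseline in multi-atlas practice. The leave-one-out evaluation
treats each subject as target, fuses the other subjects' propagated
labels, and reports per region the mean/SD/CV% of the Jaccard index and
the mean signed volume error, computed per pair and then averaged (which
differs from the error of averaged volumes, and is asserted to differ in
the tests).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Geometry.** The template "lobe" is an ellipsoidal shell (outer
  semi-axes `32·(1.15, 1.0, 0.9)` mm, inner radius 21/32 of the outer)
  split into four angular sectors per hemisphere by the anterior/posterior
  and superior/inferior axes, coded with the standard region numbers (odd
  = right). Right-hemisphere sectors are displaced 8 mm anteriorly — the
  planted brain torque. The grey-matter band is the outer half of the
  shell. Sectors are schematic, not gyrally shaped: every pipeline
  operator is geometry-agnostic, so statistical fidelity takes priority
  over anatomical realism.
* **Deformations.** Each subject applies a global scale
  `s = exp(0.03·Z)` (≈ ±10 % volume variation, an ICV proxy) and a smooth
  random displacement field (Gaussian-smoothed white noise, smoothness
  8 mm, RMS amplitude 2 mm) through the backward map
  `b(x) = x/s − u(x)`; labels are sampled analytically through `b`, so the
  exact forward/backward maps are known. The forward map is recovered by
  fixed-point iteration (contraction factor ≈ s·‖∇u‖ ≪ 1; 10 iterations
  leave sub-micrometre error, and round-trip error is asserted below one
  voxel).
* **Defaults.** 30 subjects on a 64³ grid of 2 mm voxels — seconds to
  generate while leaving multi-voxel boundary structure. Tests use 10
  subjects (image cohort) and 500 rows (table-only cohort); tables can be
  sampled without rasterising images.
* **Planted correlations.** All rank structure is planted through
  Gaussian copulas, because every statistic of interest is rank-based.
  Targets default to the reference effect sizes: gender~ICV −0.7,
  region-volume~gyri-total 0.6, PISJ~age 0.5 on the left (half that on
  the right, mirroring the weaker published right-side association).
  Discretisation attenuates observed rank correlations, so latent
  correlations are calibrated: for the balanced (median-split) gender
  variable the closed form `ρ_s = √12·arcsin(ρ_lat/√2)/π` is inverted
  exactly (perfect separation bounds |ρ_s| at √3/2 ≈ 0.87); for discrete
  margins (Poisson-distributed gyri totals, the 4-level PISJ ordinal) the
  latent value is found by deterministic fixed-seed Monte-Carlo bisection
  at n = 10⁵. Recovery is asserted within twice the Bonett–Wright
  standard error `SE ≈ √(1+ρ²/2)·(1−ρ²)/√(n−3)` at n = 500.
* **Feature tables.** SMG/AG table volumes scale the analytic sector
  volumes to the reference MNI-space means per side (which also plants the
  ≈ 9.5 % leftward SMG asymmetry) with 10 % lognormal observation noise;
  GM is a noisy fraction (0.50 SMG, 0.61 AG) of GM+WM; landmarks are drawn
  so `sup < inf` and `sup ≤ top ≤ inf` hold by construction and the extent
  and length scores are computed with the morphometry operations
  themselves; connection-flag rates follow the reference Sum% values;
  gyri totals split multinomially into anterior/superior/posterior so the
  total always equals the sum.

What passing synthetic tests show — and what they do not: they verify the
*operators* (volumes recovered within voxelisation error; planted
correlations recovered; oracle registration bounds fusion error; identity
registration reproduces the bias of fused volumes toward the cohort mean).
They do not certify performance on real MRI: the phantom has no gyral
geometry, no intensity information, no rater variability, and its
deformations are far smoother than real inter-subject variability. In
particular, the published fusion accuracy (mean Jaccard 0.69) is not
reproducible without the original images, which were never deposited; the
packaged fusion table is the published summary, and the synthetic
leave-one-out experiment checks behaviour, not that number.

## Numerical conventions

Half-up rounding for all presentation values (banker's rounding would
contradict several printed cells); NIfTI-1 throughout, gzip-compressed,
RAS-positive affines, world origin at the grid centre for synthetic data;
voxel indices 0-based; probability maps stored as float32, labels int16,
masks uint8. Jaccard of a region absent from both volumes is undefined and
reported missing, never 1. The pipeline manifest records SHA-256 checksums
of every artifact; reruns with one seed are byte-identical (NIfTI gzip
streams are written with a zeroed timestamp).
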