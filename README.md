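# atlaskit

Morphometry, volumetry, probabilistic atlasing and multi-atlas
label-fusion evaluation for the human parietal lobe.

The parietal lobe is commonly subdivided into four regions — supramarginal
gyrus (SMG), angular gyrus (AG), postcentral gyrus (postCG) and superior
parietal lobe (supPL) — delineated on T1-weighted MRI using sulcal
landmarks (intraparietal sulcus, Sylvian fissure, angular sulcus, and the
primary intermediate sulcus of Jensen, PISJ, which separates SMG from AG).
`atlaskit` packages the analysis pipeline such a cohort study needs, for
researchers who have per-subject delineations (or want realistic synthetic
ones) and wish to reproduce, extend or stress-test the cohort-level
statistics:

* **cohort tables** — typed, validated readers/writers for per-subject
  demographics and per-hemisphere morphology scores; a 30-subject
  reference cohort is packaged;
* **morphometry** — sulcal scoring from slice landmarks and footer
  statistics. The vertical extent of the Sylvian fissure or angular sulcus
  is `pct = 100·(inf − top)/(inf − sup)` (half-up integer rounding), and a
  sulcus is *long* when `pct ≥ 50`;
* **volumetry** — region volumes by voxel counting from NIfTI label
  volumes, optional grey-matter masking (`V_GM(r) = |{v : L(v)=r ∧ M(v)=1}|·v_mm³`),
  lobe totals, percent-of-lobe, hemispheric asymmetry
  `100·(x̄_L − x̄_R)/x̄_R`, and paired L/R t-tests;
* **correlation screen** — all-pairs Spearman rank correlations with the
  two-sided t-approximation p-value, reported below a fixed threshold
  (default p < 0.005, uncorrected), with by-construction couplings flagged;
* **atlas builder** — voxelwise probabilistic maps `p_r(v) = n_r(v)/n`
  from co-aligned label volumes, and the maximum-probability atlas
  `argmax_r p_r(v)` (background where all zero, ties to lowest code);
* **label fusion** — leave-one-out multi-atlas label propagation through a
  pluggable transform provider, per-voxel majority-vote fusion, and
  evaluation by Jaccard overlap `J = |A∩B|/|A∪B|` (Dice `= 2J/(1+J)`) and
  signed percent volume error;
* **synthetic cohort** — a 3D phantom generator (ellipsoidal cortical
  shell in 8 sectors, smooth invertible deformations, global scale with a
  gender effect, planted rank-correlation structure) that exercises every
  stage with known ground truth.

## Worked example

```python
import atlaskit as ak

cohort = ak.load_reference_cohort()          # packaged 30-subject tables
left, right = cohort.hemi_frame("L"), cohort.hemi_frame("R")

s = ak.cohort_summary(left["smg_gmwm"])
print(f"left SMG (GM+WM, MNI): mean {s.mean:.0f} mm^3, SD {s.sd:.0f}, CV {s.cv_pct:.0f}%")
print(f"leftward SMG asymmetry: {ak.asymmetry_pct(left.smg_gmwm.mean(), right.smg_gmwm.mean())}%")
t = ak.paired_lr_test(left["smg_gmwm"], right["smg_gmwm"])
print(f"paired L-vs-R t-test: t = {t.t:.2f}, p = {t.p:.3f}")

hits = ak.all_pairs_screen(cohort, alpha=0.005)
for h in [h for h in hits if not h.trivial][:2]:
    print(f"{h.var_x} ~ {h.var_y}: r = {h.r:.2f}, p = {h.p:.2g}")
```

prints

```
left SMG (GM+WM, MNI): mean 36194 mm^3, SD 4985, CV 14%
leftward SMG asymmetry: 9.5%
paired L-vs-R t-test: t = 2.59, p = 0.015
icv ~ brain: r = 0.97, p = 1.4e-19
R_ag_pct ~ R_ag_g_sup: r = -0.88, p = 1.8e-10
```

The left supramarginal gyrus averages 36 194 mm³ and is 9.5 % larger than
its right homologue (significant at p < 0.05 in the paired test); head and
brain size track each other closely; and on the right, a shorter angular
sulcus goes with more gyri superior to the AG horseshoe (r ≈ −0.9).

The synthetic end of the pipeline runs from the shell:

```sh
atlas-kit simulate --seed 1 --n 10 --out sim/           # NIfTI labels + masks + truth
atlas-kit atlas build sim/ --out sim/atlas/             # probabilistic maps
atlas-kit fuse loo sim/ --provider oracle --out loo.csv # leave-one-out evaluation
atlas-kit run --seed 1 --n 10 --out run/                # all stages + manifest
```

With the generator's exact (oracle) transforms, leave-one-out majority-vote
fusion reaches mean Jaccard ≈ 0.93 per region — only nearest-neighbour
boundary error remains — while deliberately unregistered (identity)
propagation drops to ≈ 0.74 and shows the classic bias of fused volumes
toward the cohort mean.

## Layout

```
src/atlaskit/
  cohort_tables.py     typed cohort records, CSV I/O, packaged reference data
  morphometry.py       sulcal scoring, cohort summary statistics
  volumetry.py         LabelVolume/TissueMask, region volumes, paired tests
  stats_screen.py      Spearman screen
  atlas_builder.py     probabilistic + maximum-probability atlases
  label_fusion.py      transform providers, vote fusion, overlap metrics
  synthetic_cohort.py  3D phantom cohort and feature-table generator
  pipeline.py, cli.py  end-to-end runner and the atlas-kit CLI
  data/                reference tables (CSV)
docs/methods.md        models, parameters, numerical conventions, limitations
```
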