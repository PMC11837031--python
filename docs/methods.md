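# Methods

## Scope and assumptions

All operators act **after** spatial preprocessing: every map (grey-matter
partial-volume estimate, lesion mask, CSF map, subcortical segmentations,
diffusion scalars, tract-density maps) is assumed registered to one shared
voxel grid. No resampling or registration is performed; grid or voxel-size
mismatches are hard errors, never silently interpolated. Upstream
segmentation (tissue classes, subcortical structures, lesions,
tractography) is likewise consumed, not computed.

## Segmentation corrections

Memory-clinic scans carry heavy atrophy and vascular lesion load, which
breaks two standard segmentations in predictable ways, corrected here
before any measurement:

- **Lesion-masking of GM.** White-matter hyperintensities are commonly
  mis-classified as grey matter. The corrected GM map is
  `gm_pve * (1 - wmh_mask)`, i.e. GM partial volume is zeroed inside the
  lesion mask. This can only reduce GM-derived volumes (a tested
  invariant).
- **CSF-masking of subcortical structures.** Around enlarged ventricles,
  structure segmentations overreach into CSF. Voxels with CSF partial
  volume above a threshold (default **0.5**; with binary CSF maps this
  reduces to set subtraction) are removed from the structure mask. The
  exact threshold used upstream in clinical pipelines varies, so it is
  configuration, not constant.
- **Mislocalisation detection.** A structure whose mask overlaps binarised
  CSF at a fraction ≥ the threshold (default **1.0**, i.e. full overlap) is
  treated as a failed segmentation and excluded: its regional IDPs are
  emitted as missing, never as zero, because zero is a valid volume and
  absence is not.

## The IDP set

All volumes are (weighted) voxel counts × voxel volume, in mm³:

| family | count | definition |
|---|---|---|
| lobar GM volumes | 4 | Σ corrected-GM PVE within each lobe mask |
| tract-wise WMH volumes | 48 | lesion ∩ tract-mask voxel count per atlas tract |
| NBM volumes | 2 | Σ corrected-GM PVE within the L/R nucleus basalis masks |
| PSMD | 1 | P95 − P5 of MD over the WM skeleton (mm²/s) |
| tractography tract volumes | 27 | voxels with streamline density > 0.005 |
| regional MD / MO | 28 | GM-weighted mean in 14 regions × 2 metrics |

Totalling **110**. The regional set comprises the four corrected
subcortical structures (L/R hippocampus, L/R amygdala) plus five cortical
ROIs measured bilaterally (parahippocampal gyrus, precuneus, superior
frontal, superior parietal, supramarginal) — the bilateral treatment of the
cortical ROIs and the 27-tract tractography set are the decomposition this
package adopts to realise the 110-IDP total; alternative splits summing to
the same total exist, and the composition is configurable
(`ExtractionConfig`, atlas contents).

Numerical conventions, declared once and shared with the test oracles:

- **Percentiles** (PSMD): linear interpolation between closest order
  statistics (numpy default). Reference PSMD tooling does not pin a
  histogram convention, so one is fixed here.
- **Tract binarisation**: strict inequality (`density > 0.005`); a density
  exactly at the threshold does not count. "Binarised at 0.005" is
  ambiguous at the boundary; strictness is declared and boundary-tested.
- Lobar and NBM volumes are **partial-volume-weighted** sums rather than
  binary counts, consistent with GM-weighting across all volume IDPs.

## Quality control

**IQR flagging.** Within each (modality, metric), Q1 and Q3 use linear
interpolation between order statistics (quantile type 7 — the convention is
unstated in clinical QC practice, so one is declared). A scan is flagged on
a metric iff its value lies below Q1 − k·IQR or above Q3 + k·IQR with
k = 1.5 by default, and flagged overall iff any metric flags it. Flagging
is invariant to affine rescaling of a metric and the flagged set shrinks
monotonically in k (both tested). Flagging marks scans for inspection;
**exclusion is an explicit separate input**, mirroring the human visual-QC
stage, which cannot be automated here.

**DSE decomposition.** For mean-centred voxel time series y, the fast and
slow terms at each transition are the voxel-averaged squares of
(y_{t+1} − y_t)/2 and (y_{t+1} + y_t)/2, and the edge term is
(y_1² + y_T²)/2; algebraically ΣA = ΣD + ΣS + ΣE, verified to 1e−6
relative tolerance on every fixture. Per-timepoint percentages are taken
relative to the **mean per-timepoint variance** of the series, so white
noise sits near 50% for both D and S and the slow-share criterion
(default 75%) has a meaningful null reference; global percentages are
shares of total variance and sum to 100. Decomposition applies to the
series as supplied (pre-denoising); a post-denoising table, when available,
is simply a second input. A constant series returns all-zero components
(the float residue of mean-centring is clamped).

## Association screen

**Normalisation.** Every numeric variable — all IDPs, age, head size,
cognition — is mapped to Gaussian scores by rank: Φ⁻¹((r − 0.5)/n) with
average ranks for ties; missing values stay missing; sex remains a raw 0/1
indicator. The offset-rank choice ((r − 0.5)/n vs r/(n + 1)) is immaterial
to rank-based inference but is fixed for reproducibility. All-constant
input is an error (ranks carry no information).

**Models.** Per IDP: age ~ IDP + sex + head size + cognition (OLS; the
cognition covariate isolates age effects not mediated by impairment);
cognition ~ IDP + age + sex + head size (OLS); diagnosis ~ IDP + age +
sex + head size (proportional-odds logistic on the ordered levels
no-DRD < MCI < dementia; the IDP coefficient is a log-odds of higher
diagnostic category per SD, Wald p by default with a likelihood-ratio
option). Complete cases per IDP model; IDPs with fewer than `min_n` usable
rows, rank-deficient designs, or separation-unstable ordinal fits are
skipped and logged. An optional per-IDP extra covariate (the matched
ROI/tract volume) supports the volume-controlled sensitivity variant.

**Hierarchical FDR.** Per outcome, p-values are grouped into modality
families. Stage 1: Simes omnibus p per family (min over i of m·p₍ᵢ₎/i),
then BH across the m family p-values at level q = 0.05 selects R families.
Stage 2: BH within each selected family at level **q·R/m** — the canonical
reading of "a more stringent threshold according to the number of
significant omnibus p-values", strict exactly when R < m. Unselected
families reject nothing; member adjusted p-values are within-family BH
values scaled by m/R so that rejection ⇔ adjusted p ≤ q. The three
outcomes are corrected independently, each with its own hierarchy.
Simulation (2000 replicates, 6 families × 50 tests, signal in 2 families at
~50% power) puts the empirical within-family FDR near 3%, under the nominal
5% — the quantity `scripts/acceptance.py` recomputes.

## Synthetic data: what it emulates, and what it does not

The phantom builds axis-aligned box regions on a small grid (default 32³ at
2 mm isotropic, minimum 16³) with seeded random map values: GM PVE uniform
in [0.2, 0.95] scaled by an atrophy factor, lesions placed to straddle both
deep tract masks and cortical GM (exercising overlap and lesion-masking), a
CSF pocket flooding part of one hippocampus (exercising CSF-masking), an MD
gradient on the skeleton (nonzero PSMD), and tract densities with a
supra-threshold core plus a deliberately sub-threshold 0.003 shell. Every
ground-truth volume, overlap and weighted mean is explicit voxel-count
arithmetic, re-verified in tests by independent triple-loop counters.
Regions are deliberately non-anatomical: exact countable truth, not
realism, is the design goal. No MR contrast, noise physics or artefact
simulation is attempted — passing tests certify the measurement operators
and statistics, not segmentation quality on real scans.

The cohort generator samples covariates independently by default
(age 78 ± 6.2 years, balanced sex, head size 1 ± 0.1, cognition scaled to
a 0–100 total around 74 ± 17 — magnitudes typical of a memory-clinic
population) so that planted coefficients are exact standardised partial
effects; an `ace_age_corr` knob reintroduces the age–cognition correlation
of real clinics when wanted. Planted IDPs are built as
β·(phenotype score) + residual with the residual SD auto-calibrated to
unit total variance (or set explicitly via `noise_sd`). Diagnosis is drawn
from a proportional-odds latent — planted IDP effects plus an age term plus
standard logistic noise — cut at fixed thresholds (−1.0, 0.2) chosen to
give all three levels substantial mass (roughly a quarter, a quarter and a
half, dementia most frequent, as in memory-clinic intake). The default
demo cohort size is 213. Planted effect sizes have no field-established
distribution; the demo defaults (|β| 0.3–0.6 on a handful of IDPs) are
moderate, detectable-but-not-trivial choices and fully configurable.

IQM tables draw each metric from its own Gaussian and push one metric of
each designated outlier scan beyond the 1.5-IQR fences of the remaining
scans by construction. BOLD fixtures are i.i.d. noise plus global-intensity
shifts at chosen interior timepoints (0-based, 1 ≤ t ≤ T−2 so both
adjacent transitions exist).

## Problem sizes and determinism

Default test/demo sizes — 20³–32³ phantoms, 60–213-subject demo cohorts,
2000-replicate FDR simulations, 200-replicate recovery studies at
n = 2000, a 5000-subject global-null uniformity check — run in seconds to a
few minutes on one CPU and give Monte-Carlo error small relative to the
asserted tolerances. All randomness flows through explicit integer seeds
(numpy `default_rng`); identical seeds give bit-identical tables, and
pipeline reruns are byte-identical on disk.

## Known limitations

- The 110-IDP composition is one defensible decomposition of the printed
  total; the exact upstream itemisation is not public.
- Ordinal fits use BFGS maximum likelihood; with very small cohorts or
  near-separation the fit is rejected rather than trusted (error, not
  estimate).
- The within-family FDR guarantee of the two-stage procedure assumes
  independent or positively dependent tests; IDPs sharing voxels are
  positively correlated in practice, which BH tolerates, but adversarial
  dependence is not covered.
- Flag-rate percentages on synthetic IQM tables reflect Gaussian tails,
  not the heavy-tailed quality-metric distributions of real scanners.
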