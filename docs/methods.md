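# Methods

This document specifies the computational methods implemented in
`fcnet`, in pipeline order. The package analyzes resting-state
functional connectomes for three-group studies — normal controls (NC)
and the two stages of subcortical ischemic vascular disease, the
cognitive-impairment-no-dementia stage (SIVCIND) and the dementia
stage (SIVaD) — but every stage is group-label agnostic and works for
any labeled cohort.

## 1. Parcellation

The packaged region table (`fcnet.regions`) covers 90 cerebral regions:
45 homologous region pairs, interleaved left/right as in the standard
automated anatomical labeling (AAL) numbering. Each region carries a
hemisphere label (`L`/`R`) and one of six lobe groups: frontal,
temporal, parietal, medial temporal, occipital, subcortical. Region
indices are 1-based in every file and report; 0-based indices appear
only inside arrays. Users may substitute their own table
(`region_table.csv`) provided it passes validation (unique 1..N
indices, hemisphere in {L, R}, a lobe per region).

## 2. Synthetic cohort generator

Subject-level fMRI for such cohorts is rarely shareable, so the
package generates surrogate cohorts with a known planted answer
(`fcnet.synthetic`). The default `CohortSpec` produces 59 subjects
(NC 19, SIVCIND 20, SIVaD 20), each a 230-timepoint x 90-region
band-limited Gaussian time series at a 2 s sampling interval.

**Population structure.** A block correlation matrix assigns same-lobe
pairs a strong within coupling (a seeded half of each lobe's internal
pairs form a "core" at 0.68, the rest a periphery at 0.40), between-lobe
pairs a weak baseline (0.18), left/right homologue pairs a homotopic
coupling (0.78), and a rich club of 6 hub regions drawn from the
frontal/temporal/parietal lobes, mutually coupled at 0.88 and coupled
to every region at ≥ 0.55. The matrix is projected to the nearest
symmetric positive-definite correlation matrix (eigenvalue clipping
plus diagonal renormalization).

**Disease model.** Each subject carries a degradation factor `g`
(group attenuation 1.00 / 0.90 / 0.75 plus a small per-subject
jitter). Edge `(i, j)` of the base matrix is scaled by `g ** E[i, j]`
where the exponent matrix `E` encodes two mechanisms:

- *Edge tiers.* Between-lobe edges (long association fibers) use
  exponent 1.8; same-lobe periphery edges 0.5; same-lobe core edges
  (short U-fibers) 0.0; all modulated by the mean lobe weight of the
  endpoints (frontal/temporal/parietal 1.0, the others 0.6).
- *Focal node damage.* Every edge adds 2.0 times the summed node
  vulnerability of its endpoints. Hub vulnerabilities are spread
  evenly over 0.3–1.9 so hub failure is progressive across disease
  stages; non-hub regions get a seeded right-skewed draw scaled by
  0.25 and the lobe weight.

A connected 10-edge path through frontal/temporal/parietal regions is
additionally attenuated (factor 0.75) in every subject whose group
factor is below 1, giving the network-based statistic a recoverable
focal target. The anatomical skeleton (core masks, hubs,
vulnerability map) is fixed by internal constants independent of the
cohort seed, so different seeds resample subjects from the same
population.

**Covariates and scores.** Age, gender and education are drawn from
clipped normals. MMSE and MoCA are affine in the degradation factor
(anchored at factor 1.0 → 28.5 / 28.0 and factor 0.70 → 14.2 / 8.9)
plus Gaussian noise, clipped to 0–30; clinical scales (HIS, GDS, CDR,
ADL) are drawn inside group-typical ranges for patients and absent
for controls.

## 3. Connectome construction

(`fcnet.connectome`)

1. **Band-pass filter** 0.01–0.08 Hz via a real FFT mask with a
   raised-cosine transition band (0.005 Hz); the DC component is
   removed.
2. **Pearson correlation** between every pair of region time series.
3. **Fisher r-to-z** transform, `z = atanh(r)`, with correlations
   clipped away from ±1 for numerical safety.
4. **Covariate regression.** Each edge's z-values are regressed on
   centered age, gender and education across subjects (ordinary least
   squares); the analyzed value is residual + intercept, so the
   grand-mean connectivity is preserved while nuisance-related
   variance is removed. Constant covariates are dropped with a
   warning.
5. **Proportional thresholding.** For each sparsity `s` in 0.10–0.40
   step 0.01 (31 levels), the strongest `K = round(s * N(N-1)/2)`
   edges are retained with their weights (round half away from zero;
   ties broken by ascending `(i, j)` for determinism). Negative or
   zero retained weights abort with an error unless absolute-value
   weighting is requested. The 31 graphs are nested by construction
   (a single descending sort, prefix per level).

## 4. Weighted graph metrics

(`fcnet.metrics`) Edge weights are first normalized to mean 1 over
retained edges, making weighted metrics commensurable across subjects
and sparsity levels and reducing exactly to the binary metrics when
all retained weights are equal. Distances are reciprocal weights
`d = 1/w` (default) or literal weights.

- **Clustering coefficient (Cp):** Onnela's weighted form — per node,
  the sum of cube roots of triangle weight products over
  `deg (deg - 1)`; network value is the node mean.
- **Characteristic path length (Lp):** mean shortest-path distance
  over connected ordered pairs (Floyd–Warshall), with a disconnection
  flag.
- **Global efficiency (Eg):** mean inverse shortest-path distance;
  the per-node decomposition is the nodal global efficiency.
- **Local efficiency (Eloc):** per node, the global efficiency of the
  subgraph induced by its neighbors (computed on the neighbor weight
  submatrix); network value is the node mean.

Each metric's 31-point sparsity curve is summarized by its **area
under the curve** (trapezoid rule), a threshold-independent statistic
used for all group inference.

## 5. Network-based statistic (NBS)

(`fcnet.nbs`) Mass-univariate tests on every edge of the
covariate-corrected z matrices (one-way ANOVA across the three
groups, or a one-tailed two-sample t for pairwise contrasts), a
component-forming threshold `p < 0.005`, and family-wise error
control by permutation: group labels are shuffled (sizes preserved),
the maximal supra-threshold component size (in edges) is recorded for
10,000 permutations, and an observed component of size `M` gets
corrected `p = #{null max >= M} / n_perm`. Permutation arithmetic is
batched (group sums via matrix products). Pairwise post hoc contrasts
are restricted to the omnibus-significant edge set. Significant edges
are classified as left-intrahemispheric, right-intrahemispheric or
interhemispheric, and hubs of the difference network are nodes whose
degree exceeds the mean by more than one (population) standard
deviation.

## 6. Group statistics

(`fcnet.stats`) For each AUC metric: a Lilliefors-type
Kolmogorov–Smirnov normality check (seeded Monte-Carlo null for the
estimated-parameter statistic), Levene's test (mean-centered) for
variance homogeneity, and Welch's heteroscedastic one-way ANOVA

    F* = [sum_j w_j (m_j - m_w)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) A],
    w_j = n_j / s_j^2,  A = sum_j (1 - w_j/W)^2 / (n_j - 1),
    df = (k^2 - 1) / (3A).

Significant omnibus tests (after Benjamini–Hochberg adjustment across
the four global metrics as one family; each nodal metric's 90 regions
form their own family) are followed by Games–Howell pairwise
comparisons: Welch standard error and degrees of freedom,
`q = |t| sqrt(2)` referred to the studentized range distribution with
`k` groups. Cognitive scores (MMSE, MoCA) are related to metric AUCs
by Spearman rank correlation in the pooled patient sample, BH-adjusted
as one family. Demographics use chi-squared (gender) and two-sample
t-tests.

## 7. Classification

(`fcnet.classify`) A boosted ensemble of depth-1 decision trees
(multiclass SAMME AdaBoost, 100 rounds) predicts group membership
from the four global AUC features. Generalization is estimated by
leave-one-out cross-validation; per-class sensitivity and specificity
come from the aggregated one-vs-rest confusion matrix.

## 8. Reproducibility

All randomness flows from one master seed through named substreams
(`nbs`, `nbs-posthoc`, `ks`, `classifier`) derived via
`SeedSequence([master, crc32(name)])`. Floats are written with the
`%.17g` format and read back with correctly rounded parsing, so
write/read round trips are lossless and a rerun with the same
configuration reproduces every numeric output byte-identically. Every
output file whose rows or columns refer to regions declares the
1-based numbering convention in a leading `#` comment, and each run
writes a JSON manifest with the config, its hash, and all derived
seeds.
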