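# Methods

## Measurement model

A sample is modeled as a mixture of two subclones with fixed genotypes. A
locus genotype is `(m, T)`: `m` mutant copies of `T` total copies per cell.
Within-subclone copy-number heterogeneity is allowed through a non-integer
`mean_cn` (a subclone whose cells are themselves a mix of copy-number
states); the mutant dose scales proportionally, `md = mean_cn · m/T`, so the
subclone's internal allele frequency stays at the genotype ratio `m/T`.

For mixing fraction `p` (prevalence of subclone 1):

- `CN(p) = p·cn1 + (1−p)·cn2` — affine in `p`;
- `AF(p) = (p·md1 + (1−p)·md2) / CN(p)` — a ratio of affine functions.

The second relation matters: any plot of one measurement against another is a
gently curved arc, not a straight segment, whenever the locus total copy
numbers differ between subclones. Plots of AF against AF are nearly straight
(both numerator and denominator bend together; worst-case deviation for the
default genotypes is below 0.01 AF for ERBB4 vs LRP1B and about 0.04 for MET
vs LRP1B); plots of CN against the anchor AF bend visibly (up to ~0.3 copies
mid-range for the default LRP1B configuration).

## Genotype inference

1. **Endpoint extrapolation.** Every marker is regressed on the anchor AF
   (LRP1B by default) over complete cases, and the fit is evaluated at the
   anchor's two pure-subclone AFs (0.25 and 0). Three evaluation routes are
   provided:
   - `method="ols"` — a single global least-squares line, evaluated at the
     anchor values. This is the classical linear-interpolation read-off. It
     inherits the full chord-vs-curve bias: with default genotypes and
     cohort mixing fractions the extrapolated subclone-2 LRP1B copy number
     converges to ≈1.54 rather than 2.0, which rounds to the wrong total.
   - `method="local"` (default) — the fitted value at each anchor value
     comes from an ordinary line through the k samples nearest that value
     (k = max(10, n/3)). Near the edge of the data this extrapolates the
     local tangent instead of a global chord, cutting the curvature bias
     several-fold at modest variance cost.
   - **Refinement pass** (`fit_two_subclone_model(refine=True)`, default) —
     after first-pass genotypes and fractions are available, every marker is
     re-regressed on the estimated fractions. Copy number is exactly affine
     in the mixing fraction, so this regression is curvature-free; endpoints
     are its values at p = 1 and p = 0.
   Markers with exactly zero spread cannot be regressed; they are treated as
   constant across subclones (both endpoints at the observed mean) and
   flagged, which is the correct reading of a truncal locus and keeps
   noise-free panels fully genotypable. `fit_marker_pair` itself still
   raises on zero variance, as a correlation is undefined there.
2. **Integer calling.** `T = round(CN)` (half away from zero, minimum 1) and
   `m = argmin_{0..T} |AF − m/T|`, ties toward smaller `m`; the residual
   `|AF − m/T|` is kept as a consistency score. `T` is not searched — the
   copy number is measured absolutely, so rounding is the whole inference.
3. **Mixing fractions.** `p = (CN_anchor − T2) / (T1 − T2)`, clipped to
   [0, 1], with the anchor copy number averaged over the anchor gene's CN
   assays (two LRP1B loci in the default panel). Interpolation uses the
   *called integer* totals (the 2 ↔ 4 axis) rather than the non-integer
   regression endpoints: the integers are exact when the calls are right,
   while regression endpoints would re-import extrapolation bias into every
   sample's fraction. `use_mean_cn=True` switches to the non-integer
   endpoints.

Genes with an AF assay but no CN assay cannot have their totals resolved;
they are genotyped under a flagged diploid assumption (`T = 2`), which
preserves the allele-ratio information but not the true copy count. Genes
with only CN assays are reported with `m = 0` ("cn_only"): a copy-number
marker carries no mutant/wild-type contrast.

With the default panel this pipeline is exact on noise-free 47-sample panels
(all CN-resolvable integer genotypes, fractions to machine precision) and,
at the calibrated noise levels below, recovered all CN-resolvable genotypes
in 20/20 seeded replicates with per-sample fraction RMSE ≤ 0.042 (computed
by `tests/test_acceptance.py`).

## Outlier detection

Bottlenecks — takeovers by cell populations outside the two-subclone
mixture — are screened per sample and dimension:

- **Truncal loci** (BRCA2, PTCH1, TP53, CSMD3 where present): median-centered
  z-score `z = (v − median) / sd` with the ordinary n−1 standard deviation
  over all non-missing samples; flagged at strict `|z| > 3`. Because the
  candidate outlier is included in the SD, extreme values partially mask
  themselves; with many samples the effect is small, and the convention
  avoids inventing a robust scale the procedure does not define. A zero SD
  yields all-zero scores.
- **Mixing loci** (ERBB4, MET, SAAL1 vs the anchor AF): perpendicular
  Euclidean distance `D` to the declared mixing line, flagged at strict
  `D > 0.07` (about six-fold the AF measurement SD of 0.011). The infinite
  line is used, not the segment, so samples beyond the pure-subclone
  endpoints are judged by the same rule. Direction (excess vs deficient) is
  the sign of the y-residual, invariant under swapping the line's endpoints.

Missing cells are non-evaluable and never flagged. The per-sample pattern —
the multiset of flagged dimensions and signs — summarizes which populations
a bottleneck favored.

Two geometric caveats, quantified in the test suite: (i) a vertical AF
displacement `d` on a line of slope `b` produces `D = d/√(1+b²)`, so the
steep ERBB4 line (b = 1.32) needs a ~0.12 AF displacement to cross the 0.07
threshold — sub-threshold bottlenecks on that dimension are by design
invisible to this rule; (ii) truncal loci at the AF boundaries (TP53 ≈ 1.0)
cannot display positive excursions, and truncation also skews their noise
distribution, inflating the |z| > 3 tail to ~1% there.

## Cohort statistics

- Pearson correlation matrices with two-sided p-values from the exact t
  transform (n−2 df), complete-case by default (pairwise optional); pairs
  with under 3 usable samples or zero variance are reported missing.
- Welch's unequal-variance t-test for every marker × cohort pair, cohorts
  being treatment arms (optionally pooling the two cisplatin cycles).
  Benjamini–Hochberg correction is applied separately within the AF and CN
  families by default — the two assay types ask different biological
  questions — with a flag for one pooled family.
- Volume association: OLS and Pearson r of % volume change on a marker,
  within a cohort filter.
- Prevalence by cohort: arithmetic mean of mixing fractions, grouped either
  by raw arm or as cisplatin (both cycles) vs non-cisplatin.

## Synthetic data

`simulate_two_subclone_panel` draws, per sample: a treatment arm (round-robin
over vehicle, cisplatin, docetaxel, doxorubicin, cyclophosphamide, cisplatin
retreat), a mixing fraction from the arm's clipped normal — cisplatin arms
N(0.43, 0.15), all others N(0.70, 0.10), centered on the observed cohort
prevalences — then AF values from the exact mixture curve and CN values from
the affine mixture, each with independent Gaussian noise (σ_AF = 0.011,
σ_CN = 0.10, the calibrated ddPCR uncertainties), truncated to the valid
range. Truncation rather than resampling keeps the generator simple; its
bias is negligible at σ_AF = 0.011 except at the AF boundaries (see the
TP53 caveat above). Optional ingredients:

- **Outliers** (`outlier_rate`, default 0 — the clean two-subclone baseline):
  one uniformly chosen AF dimension displaced by ±`outlier_displacement`
  (default 0.15), truncated, and recorded in the ground truth.
- **Cultures** (`crpc_fraction`): bulk cultures mix with a wider fraction
  spread; single-cell clones are pure (p ∈ {0, 1}), so their AFs sit at
  quantized m/T values before noise.
- **Volume coupling**: per-arm linear models of % volume change in the true
  anchor copy number; the cisplatin arms use slope 100%/copy with 30% noise
  (shrinkage at low subclone-1 content), other arms are flat growth/response
  offsets. Volumes are floored at −100%.

Default genotypes reproduce the declared mixing-line endpoints: LRP1B
(1/4 vs 0/2), ERBB4 (1/3 vs 0/1 with mean copies 2.8/1.3 — the subclone-2
non-integer mean models its internal heterogeneity), MET (1/2 vs 2/3), SAAL1
(2/5 vs 1/4), truncal PTCH1 2/3, TP53 3/3, BRCA2 2/4; EPHA3/EPHA5/PTPRD
co-amplified with subclone 1, AR amplified in subclone 2, EXOC4/AKR1B1
diploid controls. SAAL1's and MET's integer representations are one
consistent choice among several compatible with the endpoint AFs and are
configurable.

`simulate_spatial_drift_panel` models the contrasting regime: markers whose
latent cellularity follows independent spatially autocorrelated Gaussian
fields (correlation ρ^distance on a dissection grid), scaled to per-marker
AF ranges (defaults TTN 0–0.164, ERBB4 0–0.194, DNMT3B 0–0.023), plus rare
bottleneck takeovers to AF 0.15–0.20 (~30–40% of cells for a heterozygous
locus) and the same measurement noise. With ρ = 0 the markers are mutually
independent — the no-recurrent-subclone control.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: mixture
geometry, calibrated noise, cohort composition, prevalence separation,
bottleneck outliers, quantized clones, treatment–volume coupling, spatial
drift. It does not simulate tumor growth kinetics, duplicate-well ddPCR
merging, assay dropout patterns, batch effects, or more than two recurrent
subclones. Passing recovery tests therefore demonstrates correctness of the
inference given the stated measurement model — not robustness to real-data
pathologies outside it.

## Numerical choices and degenerate inputs

- Rounding of copy numbers: half away from zero, minimum total 1; genotype
  ties go to fewer mutant copies.
- Extrapolated AF endpoints outside [0, 1] are clipped with a warning
  (silently within 1e-6, which is floating-point noise).
- Strict inequalities at both outlier thresholds, per their definitions.
- Fractions are clipped to [0, 1]; an anchor with equal subclone copy
  numbers is rejected as uninformative.
- CSVs round-trip floats exactly (repr-based formatting); "NA" and empty
  cells are missing. AF given as percentages is rejected, never rescaled.
- All randomness flows through a single seeded generator per simulation
  call; identical config and seed give bit-identical tables.

## Problem sizes

The bundled tests and checks run panels of 47 samples (the cohort-scale
design), 20 seeded replicates for recovery statistics, 10⁴ samples for
false-positive rates, and ~3,400 samples (≈500 injected outliers) for
sensitivity — sizes at which the binomial uncertainty on the asserted rates
is comfortably below the asserted margins.

## Known limitations

- The straight-line endpoint read-off is an approximation to a curved exact
  relation; the local and refinement estimators reduce but do not eliminate
  the residual bias for loci measured only once at high noise.
- Genotypes of AF-only loci are reported under a diploid assumption and are
  flagged, not trusted.
- The z-score rule is non-robust by construction (masking) and miscalibrated
  at AF boundaries (truncation skew).
- Exactly two recurrent subclones plus sporadic outliers; no tree or
  Dirichlet-process inference of deeper clonal structure.
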