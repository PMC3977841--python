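# Methods

## Scope and data model

The package calls heterozygous copy-number losses in three named
subtelomeric target regions and tests their (single and combined)
association with case status. Coordinates are 1-based inclusive on the
NCBI Build 36 assembly; the only half-open conversion happens at the BED
export boundary. The 16q24.2-3 (chr16:86,950,000–88,700,000) and
22q13.31-33 (chr22:44,750,000–49,550,000) bounds are fixed; the 4p16.3
region has no published coordinates, so a placeholder anchored at the
telomere with the documented 1.3-Mb span (chr4:1–1,300,000) is supplied by
configuration and clearly marked as such. Strand is ignored throughout:
array probes are strandless genomic anchors.

Both calling tracks share two primitives: the consecutive-marker rule (a
copy-number call requires ≥ 2 adjacent probes in the same aberrant state;
runs never cross missing-value gaps or chromosome boundaries) and region
dichotomization (a region is "loss" for a subject when some loss call
overlaps it by ≥ 2 supporting probes — the stretch rule re-applied at
region scope, so a single-probe overlap is noise, not a call).

## Bead-array screen

CNVs on the screening platform appear as subjects whose intensity at runs
of CNV probes deviates from the rest of the cohort, so calling is
per probe across subjects, in four stages.

1. **Normalization + GC correction.** The two channels are summed; each
   subject is rescaled so its median probe maps to log2 = 0 (the vendor's
   normalization equation is unpublished; median rescaling is this
   package's documented substitute). Pooled log2 intensities are regressed
   on a quadratic in probe GC fraction and residuals plus the grand mean
   are kept — with a multiplicative (log-linear) GC bias this removes the
   trend exactly. Values stay on the log2 scale, so one deleted copy sits
   near −1 and the downstream mixture means are directly interpretable as
   copy-ratio levels.
2. **Batch removal.** Principal components across subjects are computed on
   probe-centered data and the top k (default 2) are subtracted. Two
   numerical choices matter here, both made because the synthetic manifests
   are CNV-region-dense (carriers are common among the probes, unlike on a
   genome-wide chip where they are a sliver): components are estimated on
   an outlier-trimmed copy of the matrix (per probe, values beyond
   3 × 1.4826·MAD from the probe median are replaced by the median), and
   the quantity subtracted is the rank-k approximation of that trimmed
   matrix rather than the projection of the raw data. Trimming keeps
   carriers from defining the removed axes; subtracting the estimated batch
   structure (not the projection) keeps a batch axis that happens to
   correlate with carrier status from dragging the deletion signal out with
   it. `robust=False` restores the textbook projection, whose residual is
   exactly orthogonal to the removed score vectors.
3. **Mixture calling.** Each probe's values across subjects are fitted with
   univariate Gaussian mixtures (scikit-learn, 10 restarts, seeded per
   probe). The order (1–3 components) is chosen by forward BIC search:
   orders are added while BIC improves. BIC was chosen for its penalty
   against spurious components at cohort size ≈ 200; the forward search
   additionally avoids paying for 3-component fits on the many copy-neutral
   probes.
4. **State labelling.** Components are sorted by mean; the largest-weight
   component is anchored as the two-copy "normal" state. A component is
   loss only if its mean is at least 0.5 below normal (half the one-copy
   shift of −1) and gain only if at least log2(3/2)/2 ≈ 0.29 above;
   components inside that band are splits of the diploid cluster and merge
   back into normal. Without this constraint, an order-selection split of a
   skewed diploid cluster would mislabel its lower half as loss. The
   consecutive-marker rule is then applied per subject.

The pipeline is invariant to subject ordering (per-probe seeds do not
depend on column order) and the whole run is reproducible from one seed.

## Tiling-aCGH validation

Tracks are per-probe log2(test/reference) ratios, missing at gap probes.
Calling is two-class — "unchanged copy number" vs "copy number loss" — with
gains deliberately outside the scheme (none were observed on this
platform).

* **Moving average**: centered, default window 11 probes, truncated at
  track ends; missing probes contribute nothing, and a window with no
  finite value stays missing. Window size is a free choice: 11 is small
  enough to resolve sub-region deletions and large enough to suppress
  probe-level noise.
* **Reference envelope**: per-probe median (center) and per-probe sample SD
  (scale) across a panel of copy-neutral individuals (≥ 3; the cohort's
  controls by default), with the SD floored at 0.05 to avoid zero-width
  bands. Median centering is robust to the occasional carrier inside the
  panel; a mean-centering switch exists. Per-probe SD is the default
  because tiling probes have heterogeneous variance; a pooled-SD switch
  exists.
* **Classification**: a probe is loss iff its smoothed value falls
  *strictly* below center − 1·SD; an exactly-threshold value is unchanged
  (ties resolve toward no call). The envelope scale is estimated from the
  **raw** probe ratios while classification applies to the smoothed track:
  the 1-SD band describes the probe-ratio distribution, and smoothing then
  shrinks a null subject's excursions relative to that fixed band (raw null
  exceedance ≈ Φ(−1) ≈ 15.9% per probe; after window-11 smoothing it is far
  lower). Building the band from smoothed panel tracks instead
  (`envelope_from="smoothed"`) makes the band shrink with the noise and
  leaves the null exceedance at ≈ 16% with spatially correlated runs — it
  is available as a switch but not the default.
* **Segments**: maximal runs of ≥ 2 consecutive loss probes (harmonized
  with the bead-array stretch rule), never merged across missing gaps.

Cross-platform concordance is the fraction of screen-positive
subject-region pairs whose validation status is also loss, per region and
pooled.

## Association statistics

* **Fisher's exact test**, two-sided by the minimum-likelihood rule: all
  tables with the observed margins whose hypergeometric probability is no
  greater than the observed table's (within 1e-9 relative tolerance for
  floating-point ties) are summed. When every admissible table qualifies
  the value is exactly 1. The test suite checks this implementation
  exhaustively against an independent integer-arithmetic enumeration for
  all margins ≤ 30 and against `scipy.stats.fisher_exact`.
* **Odds ratio**: OR = ad/bc with the Woolf log-normal 95% CI,
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) — this convention reproduces the
  reported intervals (1.6–20.4 and 1.7–11.4) exactly at one decimal. A
  zero cell triggers the Haldane–Anscombe +0.5 correction on all cells,
  always flagged, never silent (the all-three-regions 11-vs-0 table is the
  canonical flagged case).
* **Chi-square**: Pearson with Yates continuity correction for 2×2 (this
  reproduces the reported male-proportion P = 0.0011); an uncorrected
  switch exists, and r×c tables are supported uncorrected.
* **Combined loss**: per-subject count of loss regions over a named subset;
  missing statuses never count as loss; the all-loss flag feeds the
  combined cross-tabulation. Clinical characteristics of all-loss vs other
  cases are compared with Welch t-tests for continuous traits (a chi-square
  on means is not defined) and Fisher's exact test for binary traits, which
  is better behaved than chi-square at the small carrier-group sizes
  (n ≈ 11) involved. No multiple-testing correction is applied by default,
  matching the marginal three-region analysis; a Bonferroni option is a
  one-liner away in user code since raw P values are always reported.
* **HbA1c**: stored on the NGSP scale; the JDS conversion is
  NGSP% = JDS% + 0.4.

## Synthetic cohorts

The generator defines the study conditions under which the pipeline is
certified, since the raw arrays are unavailable:

* 100 cases + 100 controls; per-region loss prevalences
  (case, control) = (0.15, 0.03) for 16q24.2-3, (0.22, 0.06) for
  22q13.31-33, (0.11, 0.0) for 4p16.3 — the reported per-region counts out
  of 100, with the all-three carrier count standing in for 4p16.3 in cases.
  These prevalences imply true odds ratios 5.7 and 4.4 for the two fixed
  regions.
* Loss flags are drawn **independently** per region. The reported
  co-occurrence structure (11 of 100 cases carrying all three losses) is
  therefore *not* emulated by the generator; combined-loss statistics are
  exercised on status matrices constructed directly to the printed counts.
  Independence is the least-assumption choice given that only aggregate
  joint counts are reported.
* Deletion spans are uniform over 60–95% of the region length with uniform
  breakpoints (no distribution of extents is reported; uniform is the
  least-assumption choice), giving ≥ 24 probes per deletion at the default
  manifest density.
* Single-copy loss is the only simulated aberration class (no gains were
  observed); the expected log2 shift in deleted spans is −1.
* Probe noise is Gaussian on the log2 scale, SD 0.2 — a plausible aCGH
  magnitude, not a reported value (reported data carry no per-probe noise
  estimate).
* Bead intensities: copy number scales expected total intensity (2 copies →
  baseline 2.0, 1 copy → half); GC bias multiplies raw intensity by
  2^(c0 + c1·gc + c2·gc²), default (0, 0.3, −0.2) — a mild concave trend;
  batch structure is a per-(batch, probe) additive signature of SD 0.05
  shared by subjects of a batch (4 batches, assigned cyclically). A
  probe-uniform batch offset would be annihilated by median normalization,
  which is why the signature is probe-specific — that is also the structure
  PCA removal targets in real data.
* The bead manifest carries 40 probes per target region plus 120 diploid
  backbone probes on an untargeted chromosome. The backbone mirrors the
  fact that a genome-wide chip is mostly non-CNV content and anchors
  per-subject median normalization on the diploid level even for subjects
  deleted in every target region (without it, a subject deleted across all
  three regions would have most probes deleted and the normalization would
  re-center on the single-copy level, inverting their calls). The tiling
  manifest carries 150 probes per region.
* Gap intervals are emitted as explicit missing values, so segmenters must
  handle them; clinical covariates are drawn from group-typical
  distributions (the reported means/SDs/proportions) with physiological
  floors.

What passing synthetic tests does and does not show: the generator's noise
is Gaussian, homoscedastic within probe, and spatially unstructured apart
from batches; real arrays carry wave artifacts, heteroscedastic probes,
segmental-duplication cross-hybridization and reference-sample CNVs, none
of which are emulated. Recovery rates measured here certify the algorithmic
chain (normalization → clustering → stretch rule → association), not
performance on a specific real dataset.

## Problem sizes and numerical choices

The certification suite uses 20 seeded cohorts (100+100 subjects, both
platforms) for recovery and concordance, 100 replicates for
mixture-parameter recovery, and 50 seeded cohorts through the tiling-aCGH
track for the end-to-end odds-ratio reproduction; these sizes give
stable pooled rates while keeping the suite comfortably desk-scale. On the
fixed certification seeds the pooled results are: bead-array sensitivity
1.00 and false-positive rate ≈ 0.003; aCGH sensitivity 1.00 and
false-positive rate ≈ 0.018; cross-platform concordance ≈ 0.98. The aCGH
false positives concentrate in the region with no control carriers, where
the envelope is at its narrowest — this ~2% is the intrinsic null
behaviour of a strict 1-SD band with a 2-probe stretch rule, not an
implementation artifact. Mixture fits are seeded per probe
(seed + probe index, reduced mod 2³¹−1); degenerate zero-variance probes
return a single-component all-normal call; mixture covariances are
regularized at 1e-6. Pipeline stage seeds are spawned deterministically
from one master seed via `numpy.random.SeedSequence`, and identical
configuration + seed reproduces every output file byte for byte.

## Known limitations

* The 4p16.3 coordinates are placeholders; analyses of that region test
  the machinery, not published genomic bounds.
* The generator does not model the co-occurrence of losses across regions,
  linked-SNP B-allele evidence, or gain states (a gain hook exists in the
  mixture labelling but is untested by design).
* The all-three-regions Fisher value computed by enumeration (≈ 7.3×10⁻⁴
  for 11/100 vs 0/100) differs from the reported 7.00×10⁻⁴; the convention
  behind the reported figure is unstated, and no attempt is made to force
  agreement.
* Reported P values for continuous clinical characteristics cannot be
  reproduced under any standard two-sample test; clinical comparisons here
  use Welch t-tests and are not asserted against those figures.
* No liftover, no LOH analysis, no genome-wide discovery beyond
  user-supplied manifests, and no population-stratification correction
  (single-population design).
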