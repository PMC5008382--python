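# Methods

`isomirev` implements an end-to-end analysis for one question: do miRNA
end-variants (isomiRs) in urine extracellular-vesicle (EV) small-RNA data
discriminate prostate cancer where the canonical mature sequences do not?
This note documents the models, the estimators, the synthetic study
conditions, and the numerical and design choices behind them.

## Reads to isomiR calls

**Preprocessing.** Small-RNA reads are 3'-adapter-trimmed (default: the
Illumina TruSeq small-RNA adapter, configurable), filtered to inserts of
at least 15 nt, and collapsed to unique sequences with counts.  Adapter
matching is exact (no mismatches): the insert ends at the leftmost
position where the adapter matches over `min(len(adapter), remaining
read)` bases, with partial matches shorter than `min_overlap` (default 8)
accepted only where the adapter runs off the read's 3' end.  Reads
without an adapter are kept by default (the insert may fill the read);
`discard_untrimmed` drops them.  Quality scores are ignored — at the
insert lengths involved, end-trimming and collapsing dominate any
quality-based filtering.

**Template model.** An isomiR is defined against the precursor hairpin:
each mature arm is an interval `[start, end)` (0-based half-open, 5'→3')
on its hairpin, and the canonical sequence is exactly that substring.
miRBase-style GFF3 (1-based inclusive) can be imported and is converted.

**Alignment.** Each unique read is anchored by its 5' end: candidate
start positions are all offsets within ±5 of an annotated mature start,
and a candidate is accepted when the read's first `seed_len = 16`
nucleotides match the hairpin there with at most one mismatch.  Anchoring
on the seed rather than the full read is deliberate: 3'-modified
molecules (the objects of interest) would otherwise fail to map.  Among
hits, the winner minimizes (mismatches, |5' shift|), with lexicographic
miRNA id as the deterministic tie-break for multi-mapping reads; a
further tie on shift sign resolves to the upstream position.

**Classification.** The *templated span* is the maximal read prefix that
matches the hairpin from the anchored position, tolerating at most one
internal mismatch; a span never ends on a mismatch and never runs past
the hairpin 3' end.  The remaining suffix is the non-templated addition
(NTA) tail — mismatches are permitted only inside the templated span,
never in the tail, because a terminal mismatch *is* the NTA signal.
This yields the full record (d5, d3, tail):

* `d5` = read start − canonical start (negative = 5' extension),
* `d3` = templated 3' end − canonical end (negative = trimming,
  positive = templated elongation),
* `nta_tail` = the non-templated 3' suffix.

One mutually exclusive variant class is then assigned by precedence:
any `d5 ≠ 0` → `fiveprime_mod`; else a non-empty tail → `NTA-X` (X the
tail base if homogeneous, `NTA-other` otherwise); else `d3 < 0` →
`trimming`, `d3 > 0` → `elongation`, else `mature`.  Precedence makes the
occurrence summary well-defined (each feature counts once); the full
(d5, d3, tail) record is always retained so alternative roll-ups remain
possible.  The identity `length = canonical − d5 + d3 + |tail|` holds for
every call and is asserted in tests.  The classifier is verified against
a brute-force enumeration of all (d5, templated-span, tail)
decompositions over every arm-overlapping hairpin substring of length
15–28, with and without appended 3' bases.

## Quantification

Two levels: *isoform* features keyed `mirna|d5|d3|tail` (so `NTA-U` and
`NTA-UU` are distinct features) and *mature_summed* features pooling all
reads of a miRNA.  RPM normalization divides by the sample's
miRNA-mapped total (not the raw read yield) times 1e6; the two levels
share the denominator, so isoform RPMs of a miRNA sum exactly to its
summed-level RPM.  Per-miRNA read-length distributions are count-weighted
frequencies over call lengths.

## Differential abundance

Counts are modelled NB with `Var = μ + φμ²`, log link, and the log
miRNA-mapped total as offset (consistent with the RPM definition; TMM-style
factors can be supplied as alternative totals).

**Dispersion.**  All estimation runs on a shared log-spaced φ grid
(64 points, 1e-6…20), on which per-feature *adjusted profile
log-likelihoods* are evaluated: group means are profiled out by a
vectorized Newton solve of the score equation `Σ (y−μ)/(1+φμ) = 0`
(monotone in the mean, hence globally convergent), and the Cox–Reid
term `−½ log Σ μ/(1+φμ)` per group corrects the downward bias that a
plain profile likelihood has when two means are estimated from a handful
of samples — without it, φ is underestimated by ~20 % at 13 samples and
the test becomes anticonservative.  Then:

* **common** φ maximizes the summed curve;
* **trend** is the maximizer of a sliding-window mean (21 features,
  ranked by mean log2 RPM) — a nonparametric mean–dispersion curve;
* **tagwise** φ_g maximizes `ℓ_g(φ) + w·ℓ̄_window(φ)` with prior weight
  `w = 10` — each feature's own likelihood shrunk toward its abundance
  neighbourhood.

Each maximizer is refined by parabolic interpolation in log φ around the
grid argmax.  These are this package's own estimators; they are of the
same family as, but not bit-compatible with, the qCML/APL machinery in
established count-model packages (which tests use only as an independent
oracle for the GLM fits).

**Testing.**  Per feature, an LRT of the group effect at the tagwise φ:
full model one mean rate per group, null model a single rate, p from
χ²₁.  On null simulations (4 vs 9 samples, φ = 0.2, 2000 features) the
empirical type-I error at p < 0.05 is 0.04–0.06.  All-zero and
non-converged features are flagged untested and excluded from FDR.
`log2FC` (cancer vs control) comes from the fitted group means at the
geometric-mean library size with a +0.5 expected-count moderation, which
keeps zero-count fold changes finite; BH step-up gives the FDR.

**Selection and occurrence.**  Two named candidate presets exist because
the study design distinguishes a lenient discovery filter from a stricter
short-list: `methods` (|log2FC| ≥ 1, p ≤ 0.05) and `results` (≥ 2-fold,
p < 0.02); both accept an additional mean-RPM floor.  The occurrence
summary counts, per variant class, the features with |fold| ≥ 2 and
p ≤ 0.05 — the view in which 3'-truncation emerges as the dominant
changed class under trimming-planted simulations.

## qPCR normalization

Stem-loop RT-qPCR Ct values are referenced per assay to the mean Ct of
the control samples — the in-silico analogue of pooling control cDNA —
and expressed as `ln_expr = (Ct_ref − Ct)·ln 2 = ln(2^−ΔCt)`: one cycle
is exactly ln 2, higher expression is larger.  The natural log of the
fold change (rather than of ΔCt itself) was chosen because it makes
ln_expr affine in Ct; the alternative only rescales logistic
coefficients, not the LOOCV probability ranking.  Missing Ct values
propagate as missing.  No endogenous-control gene enters the
normalization (reference-sample ΔCt only), and amplification-efficiency
correction is out of scope.

## Diagnostic panels

Five logistic models: PSA alone; the three mature-miRNA assays; mature +
PSA; the three isomiR assays (named by their target sequences,
`UAGCUUAUCAGACUGAUGUU` / `UUCCCUUUGUCAUCCUAUGCCUG` /
`UUUGUUCGUUCGGCUCGCGUG`); isomiR + PSA.  PSA enters as ln(PSA) by
default — serum PSA spans ~1–400 ng/ml in a biopsy population and would
dominate a linear predictor by leverage; a raw-PSA switch exists.

Fitting is IRLS with a fixed 1e-8 ridge: under perfect separation the
coefficients stay finite (the ridge caps them near |η| ≈ 16) and a
warning is emitted.  Each sample's disease probability is out-of-fold
(LOOCV); a fold that loses an entire class is an error, which makes
n = 4 (2+2) the smallest evaluable cohort.

ROC curves use the fixed threshold grid 0.01…0.99 (step 0.01, "disease"
when p ≥ t); AUC is the trapezoid over (1−specificity, sensitivity) with
(0,0) and (1,1) appended.  On cohort-sized vectors this tracks the exact
Mann–Whitney AUC within the grid-discretization error (< 0.01 typically,
< 0.02 asserted).  The operating point maximizes Youden's J with ties
broken toward higher specificity; at a cutoff with no predicted
positives, PPV is reported as the prevalence (and NPV as 1 − prevalence),
the no-information values.

**A caveat worth knowing.**  Pooled LOOCV probabilities are
*pessimistically biased under the null*: when coefficients are ≈ 0, the
out-of-fold intercept tracks the training prevalence, which is slightly
lower exactly when the left-out sample is a case — anti-ranking it.  With
74 samples and an uninformative single covariate the permutation-null
AUC mean is ≈ 0.33, not 0.50 (multi-covariate models: 0.42–0.45).  The
bias vanishes when probabilities are held fixed and only labels are
permuted, and is immaterial for informative panels; it is measured and
frozen in the test suite so regressions are visible.

## Synthetic cohorts

The generator produces the study conditions the analysis assumes, with
one integer seed controlling everything (byte-identical regeneration).

* **Reference.** Three fixed hairpin fixtures host the panel:
  miR-21-5p-like (canonical `UAGCUUAUCAGACUGAUGUUGA`), miR-204-5p-like
  (`UUCCCUUUGUCAUCCUAUGCCU`, hairpin continuing with G so the published
  23-nt isomiR is templated +1 elongation), miR-375-like
  (`UUUGUUCGUUCGGCUCGCGUGA`).  Matures sit at [4, 26) with 4-nt flanks;
  decoy hairpins are random 22-mers with flanks whose first 3' base is
  G/C, keeping +1 elongation, NTA-U and NTA-A decidable on every miRNA.
* **Cohorts.** Discovery preset 4 control vs 9 cancer; validation preset
  26 vs 48.  Per-miRNA abundances are lognormal (σ = 1.2) across miRNAs;
  the three panel miRNAs get a fixed 5× abundance boost and the
  Dirichlet-*mean* isoform split — they represent markers selected for
  high abundance with major end-variants, whereas decoys draw their
  six-way (mature, −1, −2 trimming, +1 elongation, NTA-U, NTA-A) splits
  from Dirichlet(10, 3, 1.5, 2, 2, 1.5).
* **Planted effects** multiply an isoform's proportion in cancer without
  renormalizing (the planted fold is exact on that isoform): the
  miR-204-like +1-elongation isoform ×3, the miR-21-like −2 and
  miR-375-like −1 trimmed isomiRs ×0.25.
* **Global decrease.** Cancer samples have their expected miRNA library
  yield scaled by 0.7.  Note this is observable only in raw counts: RPM
  normalizes by the miRNA-mapped total, so a uniform scale cancels —
  exactly as in the real analysis.  Discriminative signal therefore comes
  from the relative isoform shifts, which is the point being modelled.
* **Counts** are NB via gamma–Poisson mixing (φ = 0.2 default);
  reads are emitted as FASTQ (insert + adapter, constant Phred-40) at
  20 000 expected reads/sample — two orders of magnitude below a real
  run, chosen so the full pipeline executes in seconds while keeping the
  planted isoforms at several hundred counts.
* **qPCR**: `Ct = 38 − log2(trueRPM + 1) + N(0, 0.25)` per assay, so a
  doubling of target abundance is one cycle; mature assays target the
  exact mature sequence (matching stem-loop primer specificity), isomiR
  assays their end-variants.  **PSA** is lognormal with
  (μ₀, μ₁, σ) = (1.80, 2.47, 0.90) — medians ≈ 6 vs 12 ng/ml and a
  large-sample PSA-alone AUC near 0.7.

What the generator does *not* emulate: sequencing error, non-miRNA RNA
classes (tRNA/rRNA/Y-RNA background), 5'-isomiR abundance structure,
cross-hybridizing qPCR assays, and between-patient biological covariance
beyond the NB dispersion.  Passing tests therefore demonstrate that the
pipeline recovers the effects it models under realistic count noise —
not that the specific markers would validate in patients.

## Degenerate inputs and determinism

Hard errors with the offending name: annotations off their hairpin,
unknown ids, duplicate (sample, assay) Ct rows, assays without control
Ct, samples with zero miRNA-mapped reads, folds losing a label class,
one-class ROC labels.  Empty read sets, empty p-vectors and all-zero
features degrade gracefully (empty outputs / untested flags).  Every
stage is deterministic given its inputs; call tables are sorted by
(mirna, d5, d3, tail, sequence), and pipeline manifests record a config
hash so reruns are verifiable.

## Problem sizes used in the shipped studies

Null calibration and power studies use 2000 features at 4 vs 9 samples;
the end-to-end discovery run uses 30 miRNAs × 6 isoforms × 13 samples at
20 000 reads/sample; panel evaluation uses the 74-sample validation
preset.  These sizes make every property measurable with comfortable
margins while the whole suite runs in well under a minute.
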