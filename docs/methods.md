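# Methods

This note documents the models implemented in `mirpipe`, the parameter
choices that matter, what the synthetic generators do and do not emulate, and
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Qualitative PCR scoring

Trace-template specimens such as exhaled breath condensate (EBC) yield Ct
values too unstable for quantitative normalization, so the clinical analysis
is strictly qualitative. Because mature microRNAs are nearly identical in
length, product identity in an intercalating-dye assay rests on the melt
temperature. The scoring rule for one well is:

* **positive** iff a melt curve is visible, |Tm − Tm_ref| ≤ `tm_tolerance`
  (default 1.5 °C, inclusive), and Ct < `ct_positive_max` (default 44,
  strict);
* **negative** otherwise (no amplification, no visible melt curve,
  off-temperature product, or late Ct).

A sample-level call is positive when ≥1 of its replicate wells is positive;
the rule generalizes "at least one of two" to any replicate count, which is
recorded in the call. The Ct boundary is strict (a well at exactly Ct = 44
is negative) while the Tm tolerance is inclusive (|ΔTm| = 1.5 °C is still a
match); both conventions follow from which side of the threshold the
negation is phrased on. A missing positive-control Tm for a primerset is a
hard error, never a silent negative.

Two cycling regimes coexist: the clinical panel (45 cycles, Ct < 44) and the
temporal-stability QC sub-analysis (40 cycles, housekeeper validity cutoff
Ct ≤ 35). Both live in `ScoringConfig`; nothing is hard-coded. Non-amplified
wells are encoded as *absent* Ct, not Ct = total cycles — except in the
polyadenylation-specificity screen (`specificity_delta_ct`), where a
non-amplified condition is censored at `total_cycles` and flagged, because
the screen's ΔCt is only meaningful with a numeric stand-in.

The housekeeper defaults to miR-423-3p; miR-423-5p is accepted as an alias
because the two arms are named inconsistently in practice. Neither belongs
in the 24-microRNA analysis panel, and `run_panel_lr` drops housekeeper ids
from any panel with a logged note.

ΔCt cells (`delta_ct_matrix`) average amplified replicate Cts per
(sample, target); a cell is missing when the target never amplified, the
housekeeper never amplified, or the housekeeper Ct exceeds its cutoff. A
sample with no housekeeper wells yields a missing row plus a warning, not a
crash. Amplification-curve *shape* ("clarity of the fluorescence curve") is
not operationalized; scoring uses Ct and Tm only.

## Airway topography similarity

For tissues *a*, *b* and individuals *i* with binary profiles
`d_i, d_i′` over the microRNA panel, the statistic is `SH = Σ_i H(d_i, d_i′)`
with `H` the Hamming distance; smaller SH = more within-individual
similarity. Missing calls are excluded pairwise (an optional strict mode
drops individuals with any missing call); per-individual contributions and
effective comparison lengths are reported.

The permutation null reassigns tissue-b profiles to individuals uniformly at
random with tissue-a fixed. Permuting one side is distributionally identical
to independently permuting profiles within each tissue type: composing the
two sides' relabelings yields a single uniform permutation, so the
single-sided scheme is implemented for efficiency. Internally the test
precomputes the cross-individual distance matrix
`D[i, j] = H(a_i, b_j)`, after which any permutation's SH is a row-indexed
sum — this makes exhaustive enumeration and large Monte-Carlo draws cheap.

Conventions:

* one-sided toward small SH; permuted ties (SH_perm = SH_obs) count as
  "as or more similar", which makes the test conservative for a discrete
  statistic;
* for ≤7 usable individuals (`exhaustive_threshold`) all n! assignments are
  enumerated and the p-value is the exact tie-inclusive fraction;
* otherwise B seeded Fisher–Yates permutations with the add-one estimator
  `p = (count + 1)/(B + 1)` (never exactly 0); the plug-in `count/B` is
  reported alongside;
* results are bit-reproducible given the seed.

Because SH is integer-valued and its permutation distribution has sizeable
atoms at the 12-individual × 13-microRNA scale, the null rejection rate at
α = 0.05 sits visibly *below* 0.05 (the test suite measures ≈ 0.03). This is
the expected behavior of a conservative discrete test — type-I error is
controlled (super-uniform p), but the test cannot be expected to reject at
exactly the nominal rate.

## Case–control discrimination

**Logistic screen.** For each panel microRNA, case/control status is
regressed on the binary call, unadjusted and adjusted for age, gender
(reference female), smoking status (3-level, reference never), pack-years,
quit-years, and underlying-lung-disease group (3-level: carcinogenesis-risk
diseases / sarcoid–bronchiectasis / none-other, reference none-other). The
reported p is the Wald p for the microRNA coefficient; the output table
carries both p columns (`p`, `p.adj`) — these are model-adjustment variants,
not multiplicity corrections. Subjects missing a call are dropped for that
microRNA only. Complete or quasi-separation is flagged (`reliable=False`)
rather than reported as a silent number; a zero-variance microRNA is an
error for the single fit but never aborts the panel. Pack-years are zero for
never-smokers and quit-years zero for non-former smokers (zeros rather than
exclusion).

**Random forests.** `RandomForestClassifier` with 500 trees by default, the
implementation's default feature subsampling (√p per split), no class
weighting, no tuning. Feature sets: clinical (the six adjusted covariates,
dummy-coded), mirs (the 24 binary calls), combined (union). Missing calls
are median-imputed using training-half statistics only (no leakage).
Case-only histology/stage features leak case status by construction and are
excluded by default; `include_histology=True` / `--leaky-histology`
reproduces the fuller published variable list for comparison.

Two evaluations:

* stratified 2-fold CV repeated 20 times; out-of-fold majority-vote
  predictions give accuracy, sensitivity, specificity, PPV, NPV averaged
  over folds (confusion-matrix identities are asserted per fold in tests);
* 100 stratified 50/50 splits; both models train on the identical training
  half and score the identical testing half by case probability, giving two
  100-long ROC-AUC samples compared by a Welch two-sample t-test, with the
  AUC difference reported in percentage points.

The Welch test treats the overlapping resampled splits as independent — it
is implemented as published, but this ignores split-overlap dependence, and
`paired=True` offers a paired alternative on the per-split differences.

**A caveat this package's own null experiments expose.** With all microRNA
odds ratios at 1.0, the combined forest *systematically outperforms* the
clinical-only forest by ~1–2 AUC points (while a clinical-vs-clinical
control shows no difference). The clinical model has only eight features, so
its trees are highly correlated; adding two dozen noise features diversifies
the trees and improves the ranking — a regularization effect of random
forests, not an implementation artifact (it persists at 50, 100 and 500
trees). Consequently a "does the microRNA panel add AUC?" comparison built
on this estimator is biased toward a positive answer under the null, and
small published increments of this size should be interpreted with that in
mind. The corresponding no-inflation check in the acceptance suite is
expected to fail and is retained deliberately as documentation of this
behavior.

## Synthetic generators

`generate_cohort` draws clinical covariates per arm to match the published
cohort's marginals: mean ages 66.93 (cases) / 56.40 (controls), smoking
splits (current, former, never) of (.434, .476, .090) / (.205, .416, .379),
pack-years means 43.43 / 19.21 (ever-smokers), quit-years means 7.33 / 9.40
(former smokers). Spread parameters are package choices, since only means
are published: age SD 10 y, gamma-shaped tobacco dose with CV 0.8.
Underlying-disease group probabilities are normalized approximations
(case ≈ .66/.04/.30, control ≈ .45/.11/.44) because the published category
rates overlap and cannot be read off exactly. MicroRNA calls follow
`logit(p) = logit(baseline) + log(OR)·case` with baseline prevalence 0.35;
the default cohort plants OR = 2.5 on the miR-21, miR-33b and miR-212
analogues. A `smoking_mir_log_or` switch adds smoking-driven confounding for
stress-testing adjustment (off by default so planted ORs stay
interpretable). Missingness is completely at random. Stage and histology are
drawn for cases only.

`generate_tissue_profiles` gives each individual a latent binary lung
profile (prevalence 0.5); each tissue copies each latent call with
probability equal to its *per-tissue concordance* and otherwise draws
independently. Pairwise tissue concordance therefore emerges as roughly the
product of the two per-tissue values (a pair-level parameterization would be
over-determined across five tissues). The defaults
(EBC .5, BAL .5, BB .15, SP .2, MW .3) emulate the observed airway pattern —
EBC strongly shares the deep-lung fingerprint, weakly shares brush/sputum,
marginally shares mouthwash — at a signal strength where the 12×13
permutation test is informative rather than saturated.

`generate_qpcr_plate` draws truth calls at a given prevalence; present
microRNAs amplify in every replicate (Ct ~ N(33, 3) clipped to [20, 43.5],
Tm jittered around the primerset reference), absent ones either fail to
amplify or, with `artifact_prob`, produce an off-temperature artifact
product. Noiseless plates (`tm_jitter_sd=0`, no artifacts) round-trip
exactly through the scorer, which anchors the end-to-end scoring tests.

**What the generators do not emulate:** within-subject correlation between
microRNAs, covariate-dependent missingness, plate/batch effects, Ct–Tm
dependence, oral-contamination gradients, and the discovery-stage selection
of the panel. Passing tests therefore demonstrate the *procedures* are
correct and calibrated under the stated generative model, not that the
published effect sizes hold in real EBC data (the raw clinical dataset is
not publicly deposited, so published AUCs and per-microRNA p-values are not
reproducible targets).

## Problem sizes and numerics

Resampling-heavy checks in the test suite run at reduced inner sizes chosen
for a single-CPU suite: the planted-recovery forest comparison uses 20
splits × 100 trees over 50 replicate cohorts, the null no-inflation check 12
splits × 50 trees over 200 cohorts, and the library analysis defaults remain
100 splits × 500 trees (used by `scripts/acceptance.py`). Monte-Carlo
permutation tests default to B = 1000 with exact enumeration below 8
individuals. All RNG flows through `numpy.random.default_rng` from a single
integer seed per operation; identical inputs and seeds give bit-identical
outputs, including written files.

## Known limitations

* The Welch comparison of resampled AUCs inherits the split-overlap
  dependence of the published procedure (see caveat above).
* The logistic screen reports Wald p-values; profile-likelihood or exact
  tests would behave better at extreme prevalences.
* The topography test conditions on the realized profiles; with heavy
  missingness the permutation null permutes profiles with different
  effective lengths, which is handled pairwise but not reweighted.
* `subgroup_view`'s stage-based filters retain all controls (controls carry
  no stage); any discrepancy with published subgroup control counts due to
  per-subject exclusions elsewhere is not modeled.
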