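# Methods

## Screen normalization

A dual-luciferase well yields a firefly reading (transfection control,
required > 0) and a *Renilla* reading (reporter signal, ≥ 0); the raw
measurement is their ratio. Every plate must carry at least two
empty-vector control wells, and each well's raw ratio is divided by the
mean control ratio of its own plate — the control level is therefore
exactly 1, normalization is idempotent, and rescaling a plate's *Renilla*
channel by any constant leaves normalized ratios unchanged. No cross-plate
control borrowing is allowed: a plate without valid controls fails QC
rather than being rescued, because plate-to-plate transfection efficiency
is the dominant nuisance the design controls for.

Replicates of one (miRNA, reporter) interaction measured on different
plates are pooled by concatenating the normalized ratios, not by averaging
per plate: concatenation preserves the replicate count available to the
*t*-test. Interactions with fewer than two pooled replicates are excluded
and logged. Fold change is the arithmetic mean of an interaction's
normalized ratios (controls ≡ 1), chosen over the median because the design
is triplicates and results are reported as mean ± S.D. The qPCR helper
computes relative expression as 2^−ΔΔCt.

## Hit calling

Two decision rules are computed for every interaction, against the pooled
normalized control ratios of the plates the interaction was measured on:

* **Student's *t*** — classic pooled-variance two-sample *t*, two-sided,
  df = n₁ + n₂ − 2 (not Welch: the named test, and triplicates have equal
  design variance). A positive call requires *P* < α (default 0.05,
  strict inequality) *and* fold change < 1. Significant up-regulation is
  flagged in its own column and never counted positive — the screen's
  readout is repression. No multiple-testing correction enters the calls;
  a Benjamini–Hochberg column is emitted for information only.
* **SSMD** — default estimator is the method-of-moments plug-in
  β̂ = (μ̂_t − μ̂_c)/√(s_t² + s_c²) with ddof-1 variances; a UMVUE-style
  variant (Zhang's correction, dividing the pooled sum of squares by
  K = n₁ + n₂ − 3.48 instead of n₁ + n₂ − 2) is available via
  `estimator="umvue"`. Which specific small-sample SSMD modification to
  use was an open design choice; the method-of-moments form is the
  simplest estimator consistent with the dual-flashlight thresholds and is
  scale-invariant and antisymmetric by construction. Classification:
  β̂ ≤ −3 "extreme", −3 < β̂ ≤ −2 "strong", else "none"; both cuts are
  configurable, non-finite β̂ classifies as "none" with a warning.

Degenerate inputs are resolved explicitly: identical constant groups give
t = 0, p = 1 (and SSMD 0); constant groups with different means give
t = ±∞ with p at the smallest positive float, and SSMD a signed-infinity
sentinel.

## Prediction benchmarking

Per-gene precision of a program is 100 × |validated positive| / |tested|;
cells with nothing tested print 0.0 by report convention. A program's
total precision pools counts across genes (Σ positives / Σ tested) — a
tested-count-weighted mean of the per-gene precisions, not their average.
The cross-program average precision is the unweighted mean of the
per-program totals. Co-prediction precision restricts each gene's tested
set to the intersection of the combined programs' tested sets; validation
labels are program-independent (enforced on identity-level inputs).
Report tables round half-up to one decimal; raw values are kept unrounded
internally. The published 9-program × 7-gene benchmark counts are bundled
as TSVs and reproduced in the test suite. (One printed per-gene cell in
the source table, PTEN/miRanda, is inconsistent with its own counts —
14/48 = 29.2, printed 29.8; the count-derived value is used.)

## MRE windows and conservation profiles

The seed site is the exact reverse complement of miRNA positions 1–8
(default), giving an 8-nt site and, with the 10-nt 5′ flank and 24-nt 3′
flank, a 42-nt window; a 7-nt (positions 2–8) mode is available by
configuration. Sequences are held as DNA (U→T) in one alphabet throughout.
Scanning is exact substring matching, overlapping occurrences kept, every
site producing its own window; windows that would run off a UTR end are
dropped (never padded — padding would bias positional means) and counted
in the log. Missing conservation scores likewise drop the window.

Window positions are labelled site-relatively with the site's first base
at 1, increasing 3′-ward on the UTR: seed-targeted nucleotides occupy 1–8
(the conserved block in real data is 2–8), the 5′ flank is −9..0, and the
3′ flank 9..32 covers the secondary conserved block at 14–25 attributed to
miRNA 3′-end pairing. This follows the display convention of the screen
literature's positional plots; under strictly antiparallel duplex geometry
the miRNA 3′ end would pair upstream of the site, but the labelling is a
display mapping only and does not affect any statistic. The per-group
positional profile is the per-position mean across same-length windows,
so its positional average equals the mean of the window means
(conservation of mass, asserted in the tests). The random group is sampled
uniformly (seeded) as fixed-length windows from supplied background
sequences. Group assignment takes either the *t*-based positive calls
(`pvalue` mode) or the extreme-effect rule SSMD ≤ −3 (`ssmd3` mode).

## Wilcoxon rank-sum test

Group differences in window mean scores use the Wilcoxon rank-sum test
with midranks for ties. Three routes:

* `exact` — enumeration of all C(N, n_A) assignments of the pooled
  midranks, two-sided p = fraction of splits at least as far from the
  null mean n_A(N+1)/2 as observed; automatic for N ≤ 12.
* `edgeworth` (default for N > 12) — continuity-corrected normal
  approximation refined with third- and fourth-cumulant Edgeworth terms.
  The null moments of the rank sum are computed exactly as moments of a
  without-replacement sample sum from the finite midrank population
  (closed forms in the population power sums), so ties are handled
  exactly and no asymptotic variance formula is needed.
* `normal` — the textbook tie-corrected, continuity-corrected normal
  approximation, kept for comparison with standard software.

The Edgeworth refinement exists because the plain normal approximation is
visibly off at reporter-screen group sizes of 3–6 (worst-case error 0.0375
against enumeration over all tie-free configurations up to 6+6) while the
refined route halves that (0.0195, attained only at 3+3; within 0.01 once
both groups reach 5); both sweeps are computed and asserted in the unit
suite. No smooth approximation can do materially
better at 3+3: the exact two-sided p there has only five attainable
values (0.1, 0.2, 0.4, 0.7, 1.0). The same discreteness bounds how closely
the parametric *t* p-value can track its exact 20-split permutation
counterpart at triplicates — typical gaps are 0.05–0.1 per dataset even
though the two agree closely on average by 6+6 (mean |Δp| < 0.01,
asserted in the unit suite). The acceptance battery therefore reports the
measured worst-case agreement at the small sizes rather than asserting an
unachievable one.

## Synthetic-data generator

`gen_screen` emulates the screen's statistical structure: plates of 96
wells led by their own control wells (default 6), all miRNA × reporter
interactions filled plate-by-plate in reporter-major order with an
interaction's triplicate sharing a plate, firefly readings i.i.d. around a
10,000-RLU baseline, and *Renilla* readings = 5,000 RLU × true effect ×
noise. Noise is lognormal and multiplicative on both channels,
independently (reporter RLUs are positive and right-skewed), parameterized
by its coefficient of variation (default 0.1, a typical plateau-phase
luminometer CV). Exactly round(hit_fraction × n) interactions are hits,
each with effect exactly `effect_fold` (a point effect keeps the
truth-table invariant *is_hit ⇔ effect < 1* sharp and recovery rates
interpretable); defaults — 10% hits at 0.5-fold, triplicates — are the
design conditions the recovery tests and the acceptance script use
(200-interaction screens for recovery, 1000-interaction null screens for
type-I calibration; sizes chosen to make binomial noise on the measured
rates small while the whole suite stays fast). The generator deliberately
omits transfection-efficiency covariates, plate-edge effects and spatial
drift; passing recovery tests therefore show correctness of the
statistics under the assumed noise model, not robustness to spatial
artifacts real plates can show.

`gen_sequences` embeds exact seed-complement sites at recorded 0-based
half-open coordinates in every other UTR (non-overlapping, at least one
flank from the ends so the standard window always fits); it does not model
G:U wobble, mismatch sites, or realistic base composition.
`gen_conservation_track` lays Gaussian jitter (σ = 0.02) around a baseline
and adds a fixed boost over true sites at site-relative labels 2–8 and
14–25, clipped to [0, 1] — the two-peak pattern the profiling stage is
expected to recover; expectations hold wherever clipping is inactive
(baseline + boost ≤ 1 is enforced).

All randomness in a generator call flows from one `numpy` generator seeded
by the config, so fixed seeds give byte-identical outputs.

## File formats and pipeline

Tables are header-row TSVs (UTF-8, '.' decimal — bit-diffable); sequences
FASTA via Biopython (duplicate ids rejected, U mapped to T); conservation
tracks fixed-step wiggle (start=1, step=1) or per-base TSV. The umbrella
pipeline writes every artifact with a SHA-256 manifest and echoes the
exact configuration; stage failures abort with a stage-tagged error (CLI
exit codes: 2 parse/config, 3 stage).

## Known limitations

* No background subtraction, plate-edge correction or spatial
  normalization; plates are assumed spatially homogeneous.
* Hit calling treats replicates as exchangeable; no mixed-effects plate
  model, and raw p-values (not FDR) drive calls by design.
* Site scanning is exact-match only; wobble or bulged sites are invisible
  to the MRE stage.
* Precision benchmarking measures precision only — the tested subsets are
  taken as given, so recall/ROC of the programs is out of reach.
* The Edgeworth Wilcoxon route can be inaccurate for heavily tied tiny
  samples (few distinct values), where the exact route should be (and by
  default is) used.
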