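# Methods

## Annotation model

An annotation run takes three inputs sharing one ionisation polarity: an
MS1 peak table (features with m/z, RT, per-sample intensities), MS2
spectra, and a spectral library. The procedure is:

1. **MS2→MS1 pairing.** A spectrum attaches to a feature when its
   precursor m/z lies within ±20 ppm and its RT within ±8 s of the
   feature. When several spectra qualify, the one with the largest
   cumulative intensity of its ten most intense fragments wins (ties
   broken by spectrum id so the result is deterministic). Features
   without a qualifying spectrum are not annotated — MS1-only
   annotation is deliberately not performed.
2. **Candidate search.** Library records within ±25 ppm of the feature
   m/z, ordered by absolute ppm error. The ppm convention is
   (observed − reference)/reference × 10⁶, tolerances applied to the
   absolute value with closed (≤) windows.
3. **Fragment alignment.** Both spectra are restricted to the
   instrument mass window (50–1250 Th) and normalised to base peak 1.
   Library peaks are processed in descending intensity order; each
   takes the nearest unused experimental peak within 10 ppm
   (one-to-one). Greedy assignment is deterministic and standard
   practice; on well-separated spectra it coincides with the
   assignment-optimal matching, which the test suite verifies against
   an exhaustive-search oracle on spectra of ≤ 6 peaks.
4. **Scoring.** Fragments are weighted by `w = intensity × m/z`. The
   forward cosine runs over the union of library and experimental
   peaks; the reverse cosine over matched library peaks only; the MS/MS
   score is their arithmetic mean (symmetric, preserves [0,1]; whether
   the forward/reverse combination should instead be a max or product
   is genuinely open — the mean is the default and the two components
   are exposed separately by `forward_reverse_cosine`). A zero-norm
   vector on either side gives score 0. The RT score is trapezoidal:
   1 below the 30 s minimum tolerance, 0 above the 60 s maximum, linear
   in between; both knots evaluate on the linear branch. The integrated
   score is the weighted sum (defaults 0.8 MS/MS, 0.2 RT; weights are
   renormalised to sum 1 with a warning if they do not).
5. **Filtering and ranking.** Candidates need MS/MS score ≥ 0.6 and
   integrated score ≥ 0.6. Per feature, survivors are ranked by
   descending integrated score, ties by smaller |precursor ppm error|,
   then compound id. When a library record has no RT and RT scoring is
   enabled, the integrated score falls back to the MS/MS score alone
   and the result carries an `rt_fallback` flag — public-library
   records routinely lack retention times and discarding them would be
   worse than flagging.

### Parameters

| parameter | default | unit | role |
|---|---|---|---|
| ms2_ms1_rt_tol | 8 | s | MS2→MS1 pairing RT window |
| ms2_ms1_mz_tol_ppm | 20 | ppm | MS2→MS1 pairing m/z window |
| ms1_mz_tol_ppm | 25 | ppm | precursor candidate window |
| fragment_tol_ppm | 10 | ppm | fragment alignment window |
| rt_tol_min / rt_tol_max | 30 / 60 | s | trapezoid knots |
| weight_msms / weight_rt | 0.8 / 0.2 | — | integration weights |
| msms_score_cutoff / integrate_score_cutoff | 0.6 | — | retention cutoffs |
| msms_mass_range | 50–1250 | Th | fragment mass window |

These defaults describe a QTOF acquisition; all are overridable via
`MatchParameters` or a YAML config on the CLI.

## Consensus library construction

Replicate MS2 acquisitions of one compound (ideally ≥ 16, across
collision energies; fewer triggers a warning) are compared pairwise
with the same m/z-weighted cosine used for annotation (single code
path, forward component only — "DP"). Average-linkage agglomerative
clustering on 1 − DP is cut so that merging requires average DP
*strictly* above the threshold (default 0.8); with all collision
energies pooled, the largest cluster is collapsed into the consensus.
Pooled fragments are grouped greedily along the m/z axis at the
fragment tolerance; a consensus peak is kept when present in ≥ 50% of
members, with intensity-weighted mean m/z and mean intensity (absent
members count 0), then renormalised. The record RT is the median
replicate RT (robust to outlier injections). Consensus of k identical
spectra is exactly the member spectrum for any k. If replicates split
into several clusters the largest wins; the energy list and member
count are stored in the record's provenance and written into the MSP
`Comments:` field.

## Differential analysis and enrichment

Two-group comparison per metabolite: Welch's unequal-variance *t*-test
by default (a pooled Student variant is selectable), log2 fold change
of group means with the groups ordered lexicographically (second over
first), and Benjamini–Hochberg adjusted FDR reported alongside raw p.
The default significance rule is raw p < 0.05 together with
|log2FC| > 1; an FDR-based rule (< 0.01) is selectable. When a group
mean is zero, half the smallest nonzero value in the table is added to
both means so the fold change stays finite without distorting nonzero
data. Metabolites constant in both groups get p = 1 when the constants
agree and p = 0 otherwise (no sampling variability to appeal to either
way; the case only arises on degenerate or synthetic data).

Enrichment is a one-sided hypergeometric over-representation test per
pathway: with K pathway members among the N-metabolite population and k
of the n significant metabolites among them, p = P(X ≥ k). The
population is the set of quantified metabolites that map to at least
one pathway (the standard over-representation background). Pathways
with p < 0.05 are flagged enriched.

## Synthetic data

The generators emulate a QTOF untargeted run. The library draws
precursors uniformly inside the 50–1250 Th window (with margins),
5–20 fragments per compound strictly below the precursor (a product ion
of a singly-charged precursor cannot exceed it), and RTs over a
15-minute gradient. The experiment gives each compound one feature with
Gaussian ppm jitter (default sd 5 ppm) and RT jitter (sd 2 s), and one
MS2 spectrum with 5% multiplicative intensity noise; decoy features sit
≥ 100 ppm from every library precursor. The quant table is log-normal
(per-metabolite log2 means uniform in [10, 20], per-sample noise sd 0.3
log2 units, six samples per group) with injected log2 fold changes
split half-and-half between the groups.

Each generator draws from its own RNG stream derived from the seed via
`SeedSequence` spawn keys (library = 0, experiment = 1, quant = 2), so
outputs are bit-reproducible and adding a generator never perturbs an
existing one.

What the fixtures do **not** emulate: correlated (isotope/adduct)
features, chimeric MS2 spectra, retention-time drift between runs,
intensity-dependent mass error, heteroscedastic or missing quant
values, and batch effects. Passing recovery tests therefore shows the
matching and scoring logic is correct under the stated noise model, not
that real-data identification rates will match.

## Numerical choices and problem sizes

- Scores are clipped at 1 to absorb floating-point overshoot in the
  cosine; all scores live in [0,1] by construction.
- The strict DP cut is implemented as a linkage-distance threshold of
  (1 − DP) − 1e-12, so a pair at exactly the threshold stays separate.
- Exact-duplicate fragment m/z within one spectrum are merged by
  summing intensities before normalisation, keeping the score vectors
  well-defined.
- RT units: seconds internally; peak-table RT columns whose values are
  all ≤ 30 are auto-detected as minutes (overridable), and MGF inputs
  may declare `RTINMINUTES`.
- Test problem sizes: recovery checks run 500 features against a
  500-compound library; the null calibration uses 500 metabolites with
  six samples per group — large enough that the binomial standard error
  of the type-I estimate (≈ 1 pp) sits well inside the 2 pp check.

## Known limitations

- Only [M+H]⁺ / [M−H]⁻ precursor matching; no adduct or isotope
  enumeration, in-silico fragmentation, or formula assignment.
- CSV peak tables only (no XLS), MGF/MSP spectra only (no mzML or
  vendor formats — upstream converters handle those).
- Features without MS2 are never annotated.
- Multivariate views (PCA, PLS-DA, clustering heatmaps), normalisation
  and imputation are out of scope; established packages cover them.
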