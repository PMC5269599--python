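# Methods

## Coordinate conventions and quantification

All coordinates are 0-based, half-open, in transcript space; a transcript
is tiled by contiguous 5′UTR, CDS and 3′UTR intervals and the stop codon
is the final 3 nt of the CDS interval. Coverage is per-nucleotide depth
(footprint 5′ ends for RF; read starts for RNA-seq).

Region counts exclude a deterministic position mask around the start and
stop codons — `[s−9, s) ∪ [s+3, s+18) ∪ [t−15, t) ∪ [t+3, t+18)`, clipped
to the transcript, with the codon trinucleotides themselves always kept
(enforced explicitly, which matters for CDSs shorter than ~21 nt where
the windows would otherwise reach across a codon). The mask is applied to
both assays so the RF/RNA ratio is unbiased; the effective region length
used for RPKM counts only unmasked positions.

CPM uses one library size per (sample, assay): the total exonic counted
reads over the transcripts in the table. After the expression filter
(RPKM ≥ 10 in ≥ 2 samples for both assays, RNA on exonic counts, RF on
CDS counts) the table is renormalized so downstream statistics use
post-filter totals. Note the compositional consequence: a TE shift shared
by all transcripts is absorbed into the RF library size and is not
observable in RPKM ratios; only relative (between-transcript) shifts are.
Differential TE estimates therefore carry a common additive offset when
the planted/true changes do not average out, which is why simulation
checks of estimator accuracy test either a single perturbed transcript
among many or the slope of estimated against planted change.

TE = RF RPKM / RNA RPKM per replicate and region (undefined, not zero,
when RNA RPKM is 0); condition TE is the geometric mean over replicates,
consistent with the log-scale analyses downstream.

## Differential testing

Per transcript and measure (RNA on exonic RPKM, RF on CDS RPKM, TE on the
CDS), log₂ fold change is the difference of treated and control means of
log₂(RPKM + 0.5); the per-replicate log₂ TE is the difference of
pseudocounted log₂ RPKMs, so TE change equals RF change minus RNA change
when computed on the same counts.

The test statistic is the Welch t. With 3 vs 2 replicates, exhaustive
label permutation offers only C(5,3) = 10 distinct splits and can never
reach p < 0.05, so the null is built by resampling with replacement: each
group's values are centered at its mean, the residuals rescaled by
√(n_g/(n_g−1)) to undo the centering bias, pooled, and both groups redrawn
with replacement from this pool B times; p = (1 + #{|t*| ≥ |t|}) / (1 + B).
Among the schemes considered (plain pooled-value resampling, within-group
centered bootstrap, studentized bootstrap-t), this is the one that is
calibrated at small n: under a negative-binomial null with dispersion
0.05 and 3 vs 2 replicates the rejection rate at p < 0.05 is ≈ 0.035–0.047,
and clearly separated groups reach p ≈ 10⁻³ at B = 10⁴. The trade-off is
exact calibration rather than strict conservatism: the empirical CDF of
null p-values can sit slightly above uniform (bounded in tests by a
one-sided KS distance of 0.06). Exhaustive permutation remains available
(`scheme="exhaustive"`). Significance for pattern calls is unadjusted
p < α (default 0.05); BH q-values are reported alongside but not used for
the labels.

Pattern taxonomy (a partition, given the three significance flags and
directions): *forwarded* (RNA and RF significant, same direction, TE not),
*TE-only* (TE significant, RNA not), *homeostatic* (RNA and TE significant
in opposite directions, RF not significant), *synergistic* (RNA and TE
significant in the same direction), otherwise *unclassified*.

Variance-explained estimators: `fc_variance_explained` is the OLS R² of
RF log₂FC on RNA log₂FC with its F-test; `baseline_variance_explained`
fits a Gamma GLM (log link) of RF abundance on log RNA abundance and
reports 1 − SS_err/SS_tot on the response scale.

## Metagene profiles

Each retained transcript (CDS ≥ 2000 nt by default, matching the length
regime where a long interior exists) is normalized to within-transcript
CPM before averaging, so expression level and length do not weight the
mean. Offset 0 is the first nucleotide of the anchor codon; default
windows are −50..+200 (start) and −200..+50 (stop). `peak_score` is the
ratio of mean profile values in disjoint peak and background windows.

## Sequence features

- GC content excludes N; empty/all-N regions are NaN.
- uAUGs: overlapping AUG trinucleotides anywhere in the 5′UTR.
- Upstream Kozak matches: uAUGs with a purine 3 nt before the A and a G
  immediately after the G (the classic −3/+4 strong context, 1-based
  convention). The −3 base must lie in the UTR; the +4 base may come from
  the first nt of the CDS-adjacent context. The pattern is the standard
  minimal strong-context reading and is deliberately simple; it is not
  configurable per-position.
- Secondary structure: a weighted Nussinov dynamic program over
  non-crossing structures (GC = 3, AU = 2, GU = 1, minimum hairpin loop of
  3 unpaired nt) whose negated optimal weight serves as a pseudo-free
  energy. It is exactly testable against brute-force enumeration, which
  the suite does for all short sequences. For feature extraction, regions
  longer than 150 nt are folded in non-overlapping 150-nt tiles and the
  tile scores summed: the O(n³) DP on multi-kilobase regions would cost
  50–200 ms each, and tiling keeps feature extraction linear in length
  while preserving the extensive (≈ linear in length) behaviour that the
  length-normalized feature divides out. Note that the DP score is
  reversal-symmetric but *not* reverse-complement-symmetric (a G·U wobble
  maps to unpairable A·C). An `engine="external"` hook shells out to
  RNAfold for thermodynamic MFEs; the engine used is recorded in the
  table's metadata because scores from different engines are on different
  scales.
- Derived: normalized structure (score/length, NaN for empty regions) and
  a short-3′UTR indicator at < 492 nt.

## TE-change modeling

The response is the log₂ TE fold change of transcripts with significant
TE regulation. The candidate set is the decorrelated predictor list
{n_upstream_kozak, norm_ss_utr5, ss_cds, short_utr3, utr5_gc,
norm_ss_utr3} plus the norm_ss_utr5 × n_upstream_kozak interaction.
Interaction factors are mean-centered before multiplying: the raw product
of a nonzero-mean factor is nearly collinear with the other factor's main
effect and would alias it during selection.

Stepwise selection is bidirectional from the intercept-only model, by
BIC. BIC was chosen over AIC/AICc because selection consistency is what
the planted-recovery guarantees need: with ~600 rows AICc admits each
irrelevant candidate with probability ≈ 0.16 (P(χ²₁ > 2)), so a clean
selected set would be a coin flip across four null candidates, while
BIC's ln(n) penalty keeps spurious inclusion near 1% with essentially no
loss of power at the planted effect sizes. AICc/AIC remain available via
`criterion=`.

A caveat established by simulation: restricting the response to
significantly TE-changed transcripts truncates on the (noisy) response,
which makes the conditional mean nonlinear in the planted linear index;
the square of that index contains the kozak × structure cross term, so
the interaction candidate carries genuine signal in the selected subset
in a minority of data sets — a stepwise fit of the *noiseless* planted
response over the same transcripts selects it in exactly those cases.
Recovery tests therefore score the pipeline against that ground-truth
oracle rather than demanding it beat an estimator with perfect knowledge.

Quartile ANOVA bins a predictor at its sample quartiles (ties to the
lower bin; bins emptied by ties are merged downward with a warning) and
runs a one-way F-test. The direction χ² cross-tabulates TE direction
against Kozak-count bins {0, 1, 2, ≥3}, collapsing high bins while any
expected cell is < 1.

## Gene-set overlap

All sets are intersected with the measurable universe before testing so
unmeasured genes cannot inflate enrichment. The one-tailed p is the
hypergeometric upper tail (identical to one-tailed Fisher); odds ratios
and one-sided 95% lower bounds are conditional-MLE. Overlap is tested at
gene level (transcripts collapse to gene_ids). Scored predictions
(miRNA-style) are filtered at confidence ≥ 80 (inclusive) and BH-adjusted
across the sets that retain at least one measurable target. KS bias
diagnostics compare log₁₀ CDS length and log₁₀ abundance of the query
against the background, because target sets such as CLIP targets of
long-CDS-binding proteins carry length biases that masquerade as
enrichment.

## Synthetic data

The generator defines the study conditions once:

- Replicates: 3 control vs 2 treated (a design where one treated
  replicate was dropped for low library size).
- Counts: negative binomial with variance μ + φμ², φ = 0.05 (typical bulk
  RNA-seq overdispersion); totals are NB per transcript × sample and
  positions multinomial, which preserves NB dispersion at region level.
- RF coverage is confined to 5′UTR (occupancy 0.3 relative to CDS) and
  CDS, with a ×5 multiplicative pause over the start and stop codon
  trinucleotides (magnitude chosen to be detectable at default depth).
  The 3′UTR receives no footprints. Coverage is stored as footprint
  5′-end depth; under that representation the sampled footprint lengths
  (26–34 nt uniform) do not alter any stored value and are not
  materialized.
- Sequences: per-transcript GC drawn from (0.35, 0.65); CDS starts with
  ATG, ends with a stop codon and contains no internal in-frame stops;
  the 5′UTR is scrubbed of background AUGs and then receives a
  Poisson(rate 1.5) number of injected uAUGs, each given strong Kozak
  context with probability 0.5 (context bases are set so that strong and
  weak calls are unambiguous and scrubbing cannot flip them).
- Lengths default to 30–180 (5′UTR), 150–600 (CDS, floored to multiples
  of 3) and 120–900 nt (3′UTR). This is a scaled-down transcriptome —
  chosen so a full study simulates and folds in seconds — with the 3′UTR
  range deliberately straddling the 492-nt indicator threshold. Metagene
  checks use a separate long-CDS configuration (2100–2400 nt).
- Planted effects: 10% of transcripts get +1 and 10% −1 log₂ of
  transcriptional change. Planted log₂ TE change is Σβⱼzⱼ + N(0, σ), with
  zⱼ the z-scores of the realized features named in
  `planted_te_coefficients` (recomputed exactly as `seqfeat` computes
  them, and stored), defaults β = (−0.30 kozak, +0.30 norm_ss_utr5,
  +0.25 short_utr3) and σ = 1.09 so the coefficients explain ≈ 17% of the
  TE-change variance; planted RF change = RNA change + TE change by
  construction. Effects apply to the treated condition only.

What the simulator does *not* emulate: genome coordinates and splice
isoforms, sequencing error, positional/fragment bias, codon-level pause
structure or frame periodicity, batch effects, and any dependence between
replicates beyond shared means. Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful noise model,
not robustness to alignment artefacts or library-preparation biases in
real data.

## Numerical and degenerate-input choices

Pseudocount 0.5 RPKM before log₂ (prevents −∞); TE flagged missing (NaN)
where RNA RPKM is 0; zero-variance groups with equal means give t = 0,
p = 1; empty regions give ss = 0 with NaN normalized structure; CDS
length must be ≥ 6 (hard error) while non-multiple-of-3 lengths only
warn, since real annotations contain incomplete codons and the mask
depends only on the interval ends. Stepwise requires more complete rows
than candidates. Resampling indices are drawn independently per
transcript from a seeded generator; identical seeds give identical
p-values.

## Problem sizes used in the checks

The end-to-end recovery study uses 2000 transcripts × 20 seeds at mean
depth 2000 and B = 1000 resamples; the null calibration 2000 transcripts
at B = 1000; variance-split recovery n = 5000; the folding oracle 200
random sequences of length ≤ 10; the exact-overlap sweep all 2×2 tables
with universe ≤ 60. These sizes were chosen so the planted effects are
estimated with enough precision for the stated tolerances while a full
run of the suite stays fast.
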