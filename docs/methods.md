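# Methods

This note documents the statistical models, conventions and design choices
behind `rarecnv`, in the spirit of a methods supplement: what each stage
computes, which knobs matter, and what the synthetic data can and cannot
tell you about real array data.

## Data model and conventions

Calls live in memory as 0-based half-open intervals `[start, end)` with
`length = end − start`; PLINK CNV text files (`FID IID CHR BP1 BP2 TYPE
SCORE SITES`) are 1-based inclusive and converted only at the I/O boundary
(`start = BP1 − 1`, `end = BP2`), so interval arithmetic is unambiguous and
the read/write round trip is exact. The `TYPE` column is a called copy
number: 0/1 → DEL, 3+ → DUP; 2 is rejected (copy-neutral is not a CNV), and
multi-copy states are collapsed to DEL/DUP — no extra dosage effects are
modeled anywhere downstream, matching the one-event encodings of the
breakpoint scan. Rows with `BP1 == BP2` are rejected as zero-length.
Chromosome X calls are carried through all modules with no sex-specific
dosage handling; that is a documented limitation, not an omission by
accident.

Quality control retains calls strictly longer than 20 kb with at least 10
probes. Rarity is a sample frequency: the carriers of a call are the
distinct samples with a same-type call at ≥ 50% reciprocal overlap
(`min(ov/len_a, ov/len_b)`), the denominator is all samples in the table,
and calls at frequency ≥ 1% are removed (strict `<`). Requiring the type to
match (DEL with DEL) is a choice the underlying publications leave
ambiguous; it is the default here and a natural sensitivity axis.

## Firth regression

All sparse-carrier tests use logistic regression with Firth's Jeffreys-prior
penalty, maximizing `ℓ(β) + ½ log det I(β)` by Newton–Raphson on the
hat-adjusted score `Σ[mᵢ(yᵢ−pᵢ) + hᵢ(½−pᵢ)]xᵢ`, with step-halving so the
penalized likelihood never decreases, convergence at max|score| < 1e-5 or
50 iterations. P-values are penalized likelihood-ratio tests — the
restricted fit keeps the coefficient at zero while the penalty still uses
the full design, as in R's `logistf` — because Wald tests are
anti-conservative under separation. Confidence intervals are profile
penalized likelihood (bracketing + Brent). One-sided p-values are p₂/2 when
the estimate is in the risk direction and 1 − p₂/2 otherwise.

For the single-binary-predictor saturated model the Firth maximum equals
the Haldane +½-corrected cross-ratio; the tests verify this and also check
the fit against an independent grid maximizer of the closed-form penalized
likelihood. The breakpoint scan uses a batched implementation (shared
covariate block, per-column carrier/missing structure handled sparsely,
warm starts from the covariate-only fit and the Haldane log cross-ratio);
it is cross-checked column-by-column against the general fitter.

Samples "missing" under a one-type encoding enter the likelihood with
weight 0. A carrier column collinear with the covariates is flagged rather
than raised; zero-carrier exposures are reported as `unobserved` and not
tested.

## Burden

Five per-sample metrics: total distance (kb), CNV count, distinct
haploinsufficient genes (pHaplo ≥ 0.86) hit ≥ 1 bp by deletions, distinct
triplosensitive genes (pTriplo ≥ 0.94) hit by duplications, and the mean
per-CNV proportion of highly constrained bases (PhyloP ≥ 2.27 mammalian,
PhastCons ≥ 0.96 primate — thresholds that flag ≈ 3.26% of the genome).
Genes are counted once per sample per metric even when hit by several CNVs
("number of deletions intersecting … genes" is ambiguous between counting
CNVs and counting genes; gene-counting is the default). "Average
proportion" averages over a sample's CNVs rather than concatenating bases;
zero-CNV samples have zero burden and proportion 0 and are retained in the
regressions — dropping them would condition on carriership. Missing
annotation inputs omit the corresponding metrics with a warning instead of
zero-filling.

Burden tests are ordinary ML logistic regressions of status on the scaled
metric plus cohort and PC1 (events are not rare at the sample level; the
Firth engine is reserved for locus/breakpoint tests and as a separation
fallback). Total distance is reported per 100 kb. Partitioned burden uses
left-closed length bins [20, 100), [100, 200), [200, 500), [500, ∞) kb and
carrier-count bins from singletons up to the 1% count, each crossed with
CNV type; empty strata are reported as unobserved.

## Locus association

Three annotation rules (type-matched first): syndromic — the call covers
≥ 50% of the locus or ≥ 50% of the call is inside it (the published wording
is ambiguous about the denominator; taking the OR of both clauses covers
either reading); pleiotropic segment — call ≥ 100 kb with ≥ 50% of the call
in the segment, or ≥ 25% of the segment covered; exonic — ≥ 1 bp overlap
with any listed exon (purely intronic events do not count). A sample is a
carrier iff ≥ 1 of its calls annotates; the Firth model treats carriership
as a binary exposure. Syndromic lists are tested two-sided, disease-risk
segment lists one-sided in the risk direction. Bonferroni uses the full
list length (unobserved loci included), and the significance flag is
exactly `p < 0.05/n`; no FDR is used anywhere. Supplementary BMI models are
OLS of lowest BMI on carriership + cohort + PC1 within cases or within
controls; a single carrier is reported but flagged low-information.

## Breakpoint GWAS and CNVRs

Breakpoints are the deduplicated union of call starts and ends. A call
`[s, e)` covers position p iff `s ≤ p ≤ e` — the right end is closed at
breakpoints so every call registers at both of its own endpoints. Under the
duplication-only model a covering duplication makes the sample ALT, a
covering deletion makes it missing, otherwise REF (reciprocal for the
deletion-only model); a sample covered by both types is ALT (the model type
takes precedence — the published encoding table does not cover this case).
Breakpoint frequency is ALT / non-missing; testable rare breakpoints have
0 < frequency < 1%. Each is Firth-tested (status ~ ALT + cohort + PC1,
missing samples excluded); the Bonferroni denominator is the number of rare
breakpoints tested per model.

CNVRs are defined by greedy PLINK-style clumping: candidates are rare
breakpoints with p ≤ 0.05 sorted by ascending p (ties broken by genomic
position); the best remaining candidate becomes a lead, and every
breakpoint within ±300 kb with r² ≥ 0.5 to the lead joins its region and
leaves candidacy. Two deliberate readings: "independent" leads are realized
by greedy removal (the method is not defined operationally in the source),
and the rarity requirement binds the *lead*, not the partners — partners
are drawn from the full breakpoint matrix. The latter matters: the interior
positions of a region are covered by every carrier, so their frequency can
exceed 1% even when each boundary is rare, and restricting partners to rare
breakpoints would make a region exclude its own core. r² is the squared
Pearson correlation of ALT indicators over pairwise-complete samples,
reported as 0 when a column is constant on the shared support. The span is
[min, max] over lead and partners and is kept if ≥ 20 kb, ≥ 10 probes and
the lead OR exceeds 1; regions are annotated with intersecting genes,
maximum PhyloP/PhastCons, the primate constrained-base proportion, a direct
carrier recount (samples with a model-type call overlapping the span by
≥ 1 bp, by status), and a profile-likelihood CI refit at the lead. Mirror
candidates are breakpoint pairs, one per model, within a window (default
300 kb) with p < 0.05 in both models and opposite effect directions.

## Power

`poisson_effect_sd(m, r) = m(r−1)/√m` converts a multiplicative case effect
on a Poisson burden into SD units using the control-group SD — the only
reading under which 2.2 genes/CNV at ratio 1.21 gives ≈ 0.3. Two-sample
power is `Φ(δ/√(1/n₁+1/n₂) − z_α)`; one-sided is the default (burden
hypotheses are directional, and the >80%-at-0.05-SD benchmark holds only
one-sided), with the two-sided variant exposed. A Monte-Carlo checker
simulates the sufficient statistic directly and agrees with the analytic
formula within simulation error.

## Synthetic data: what it emulates and what it does not

The generator targets the observable structure of a post-calling,
post-QC array call set: Poisson background counts (defaults 0.9 dup + 0.7
del per sample), log-normal lengths with median ≈ 102.8 kb (σ_log = 0.7, so
~1% of draws fall under the 20 kb QC bound), boundaries snapped to a
probe map with exponential ~2 kb spacing (a call of ~20 kb then spans ~10
probes, making the two QC rules roughly coincide, as they do on a dense
array), cohort composition matching the two-cohort design, PC1 ~ N(0,1)
with a weak log-linear effect (default 0.05 per SD) on the rate of sub-100 kb
CNVs, sex and lowest-BMI distributions per status, and an optional global
case burden shift in Poisson-SD units (off by default — background burden
is null by construction).

Planted loci draw carrier status retrospectively: controls at
`carrier_freq_controls`, cases with odds multiplied by `odds_ratio`.
Recurrent loci use small endpoint jitter (default sd 2 kb); non-recurrent
risk regions use jitter large relative to the locus (75 kb for the
100 kb reference scenario), producing carrier calls that vary in size and
position like published non-recurrent CNVR hits. This matters
quantitatively: with a strong odds ratio the combined case+control carrier
frequency can exceed 1%, and only the non-recurrent geometry keeps
individual calls (by 50% reciprocal overlap) and individual breakpoints
(by coverage) below the rarity bound, as they are in real non-recurrent
regions. Mirror pairs are two reciprocal-OR loci of opposite type at the
same coordinates.

Annotations are synthetic: genes tiled with exponential gaps/spans, pHaplo
and pTriplo uniform with 16.5% / 6.9% of genes pushed above the 0.86 / 0.94
thresholds (the approximate real proportions of dosage-sensitive genes),
and constraint tracks of random scored intervals covering ≈ 3.26% of the
genome per track. Locus lists contain one syndromic and one ≥ 200 kb
pleiotropic entry per planted locus plus null entries.

Not emulated: raw intensities, wave artifacts, caller disagreement and
batch-specific call quality; linkage between CNVs and SNP ancestry beyond
the single PC1 effect; X-dosage by sex; gene-density/constraint correlation
with CNV placement (background CNVs are placed uniformly). Passing tests
therefore demonstrate the statistical machinery under the stated generative
model, not robustness to array artifacts.

Everything derives from one integer seed through spawned child streams;
identical seeds give byte-identical files.

## Problem sizes and numerical choices

The default simulated genome is six 100 Mb chromosomes — large enough that
background breakpoint coverage at any position stays far below the rarity
bound, small enough to keep replicate studies fast. Calibration studies use
2,000 samples (1,190/810, the study's case:control ratio) over 200
replicates with one designated p-value per test family per replicate
(burden total-kb test; one planted null locus at carrier frequency 0.005;
the highest-ALT rare breakpoint in the null-locus window), compared to the
central 95% binomial region around 5% — pooling every sparse breakpoint
would instead measure the discreteness of near-exact tests, since a
single-carrier column can never reject at 5%. Recovery studies run 50
replicates at the full 7,414/5,044 scale with scans restricted to the
windows around the planted loci; the clumping, filtering and annotation
machinery runs unmodified.

Ties in clumping are broken toward smaller genomic position for
determinism. The batched Firth scanner deduplicates identical
(carrier-set, missing-set) columns — e.g. the two breakpoints of a
singleton call — and fits each pattern once. Probe counts for a call
`[p_i, p_j)` count probes in the half-open interval; CNVR spans count
probes inclusively at both breakpoint endpoints. Degenerate inputs
(all-missing breakpoint columns, constant burden metrics, single-class
outcomes, collinear carriers) are flagged or excluded with warnings rather
than raising mid-pipeline.

## Known limitations

- The breakpoint association engine is the in-repo Firth regression, not a
  mixed-model score test with saddlepoint approximation and a sparse
  genetic relationship matrix; relatedness and fine-scale stratification
  beyond cohort + PC1 are out of scope.
- Set-based (gene-collapsed) breakpoint tests and sex-stratified X models
  are not implemented.
- Curated locus lists (DECIPHER syndromic regions, published
  dosage-sensitive segments) are user-supplied inputs; the package ships
  only synthetic stand-ins for testing.
- The profile-likelihood CI search assumes a unimodal penalized likelihood
  in each coordinate, which holds for logistic designs used here.
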