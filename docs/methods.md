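# Methods

## Scope and coordinate conventions

All intervals are 0-based, half-open internally; GFF3 (1-based, inclusive)
is converted on read. Strand is ignored throughout binning and
state–gene intersection. A genome layout declares chromosome lengths and a
partition of every base into region classes (AUTOSOME, PAR, SDR_FEMALE,
SDR_MALE); AUTOSOME is the default fill, and a gene's region class is taken
from its midpoint. Alignment, duplicate marking, peak calling and
differential-expression fitting are out of scope: the pipeline consumes read
intervals (or bedGraph coverage), count tables and a DE table.

## Binarization

Signal is counted in fixed bins (default 200 bp, trailing partial bin
included), assigning each read to the bin containing its 5′ start — a
deterministic rule that needs no fragment-length estimate. A bin is called
"mark present" when the Poisson upper tail P(X ≥ obs | λ) falls at or below
`p_threshold` (default 1e-4, the common binarizer default).

The background λ is the control track, locally smoothed (centered running
mean, default 11 bins) and scaled to the IP's *background* depth with the
SES factor: bins are ranked by IP signal, the cutoff k\* maximizes the gap
between cumulative control and cumulative IP fractions, and the scale is the
IP/control ratio over bins ranked ≤ k\*. Scaling by the raw total-depth
ratio is available (`control_scaling="total"`) but is biased upward whenever
enriched bins carry a non-negligible share of IP reads, which costs
sensitivity; SES estimates exactly the quantity needed here, so it is the
default. λ is floored at 1 read so sparse controls cannot produce
degenerate calls; without a control, λ is the global mean IP per bin.
Replicates are combined per bin by logical OR (AND available).

SES ratio tracks (IP / scale·control, 0/0 → 0, x/0 capped at 50) are also
exposed for display-style coverage summaries.

## The joint hidden Markov model

One K-state model with multivariate Bernoulli emissions is learned from both
sexes at once: every chromosome of every sex is an independent observation
sequence sharing a single parameter set, so male and female segmentations
are directly comparable state-for-state. Fitting is Baum–Welch with scaled
forward–backward recursions (numba-compiled inner loops); emission
probabilities are clipped to [1e-6, 1−1e-6] to avoid log-domain collapse;
emissions are initialized uniformly in [0.1, 0.9] from a seeded generator
and transitions/initial start uniform, making every fit exactly reproducible
from (data, K, seed). Iteration stops at `max_iter` (200) or when the
log-likelihood improves by less than `tol` (1e-4); the likelihood sequence
is recorded and checked non-decreasing. Posteriors are verified in tests
against exhaustive path enumeration on short sequences.

Decoding assigns each bin its posterior-argmax state (ties to the lowest
state index; Viterbi available) and merges equal-state runs into tiles.
Model size is selected by fitting a `k_max`-state reference (default 17) and
recording, for each smaller k down to `k_min` (default 8), the best Pearson
correlation of each reference state's emission row in the k-state model;
the chosen K is the smallest k whose *minimum* such correlation still
reaches the similarity floor (default 0.9) — the smallest model that has not
yet lost any reference state. The floor is a free parameter: the criterion
in the source analysis is qualitative, so 0.9 is a documented default, not
a derived constant.

## From states to signatures

Fitted state indices carry no meaning, so the state→group map is inferred
from the emission matrix unless an explicit map file is supplied: marks are
assigned roles (TSS-activation: H3K4me3/H3K9ac/H3K27ac; broad activation:
H3K36me3; repressive: H3K79me2/H4K20me3) and a state emitting above 0.5 for
a repressive mark together with any activation mark is MIXED, repressive-only
is SILENT, activation-only states are PERMISSIVE1 when TSS marks dominate and
PERMISSIVE2 when H3K36me3 does, and a state emitting nothing is NULL (the
weakest state is forced NULL if none qualifies). For a canonical 12-state
model this reproduces the conventional grouping E1–E3 / E4–E5 / E6–E8 /
E9–E11 / E12.

A gene's signature is the set of non-null groups among the states whose
tiles overlap its body by ≥ 1 bp (the intersect default; configurable).
The 15 non-empty subsets of {PERMISSIVE1, PERMISSIVE2, MIXED, SILENT} map to
S1–S15 by bitmask (P1 = bit 0, P2 = bit 1, MIXED = bit 2, SILENT = bit 3)
and the empty set — genes overlapping only null-state tiles — is S16.
Signature classes default to: only-permissive subsets ACTIVATION, subsets
mixing a permissive with a repressive group MIXED, permissive-free subsets
REPRESSION, S16 NULL (a 3/9/3/1 split). Published figure-level groupings
use a 5/7/3/1 split whose exact subset order the text does not pin down, so
the class table is a plain TSV config and every class-level output records
which table produced it.

## Expression

TPM = 1e6 · (count/length) / Σ(count/length) per sample. A gene is
expressed when its TPM reaches the sample's 5th percentile (linear
interpolation percentile) in at least one sample ("any"; "all" available).
Transcribed means TPM ≥ 1 in some sample. Breadth uses tau over N ≥ 2
conditions with strict thresholds (tau < 0.25 housekeeping, tau > 0.75
narrow; the boundary profile (8,2,2) with tau = 0.75 is intermediate).
Sex bias is read off a supplied DE table: MALE_BIASED iff log2FC ≥ 1
(male/female orientation, stated in every output header), FDR < 0.05 and
male mean TPM > 1; symmetric for females; everything else, including genes
absent from the DE table, is UNBIASED.

## Matched permutation tests

The question "does gene set T have an unusual signature composition relative
to pool P?" is answered by comparing the observed Pearson chi-square of T's
signature counts against P's proportions with the same statistic for
`n_perm` (default 100,000) random subsamples of |T| genes from P.
Subsample category counts are drawn as multivariate hypergeometric variates
— identical in law to drawing genes without replacement, exact for
stratified matching, and fast. The empirical p-value is (b+1)/(n_perm+1),
never zero.

Each null draw is scored against the proportions of the pool genes *not* in
the draw ("leave-out"). This mirrors the observed statistic, where the
target is disjoint from the reference pool, and is what calibrates the
test: scoring draws against the full pool (offered as
`null_reference="full_pool"`) understates the null variance because the draw
is part of its own reference, and measured type-I error rises to ~0.10 at
α = 0.05, versus ~0.04–0.05 for leave-out.

Matching modes: TE_PREVALENCE stratifies the pool into TE-overlapping and
TE-free genes and forces every draw to contain exactly the target's TE
count; EXPRESSION_WINDOW first restricts the pool to genes whose expression
lies within ±25% of the target's median. Infeasible matching (too few
matched pool genes) raises an error stating the deficit; the pipeline logs
and skips such contrasts rather than aborting. Note that a matched test
answers a conditional question — on the synthetic data the young-gene
contrast is significant unmatched but not after expression matching,
because expression-matched draws already share the repressive skew.

The signature×location expression model is OLS of log2(TPM+1) on signature
indicators (S1 reference), a location indicator (autosome/PAR) and their
interactions. Aliased columns (a signature observed only on one location)
are detected by incremental rank and reported as inestimable rather than
silently dropped. Rank-sum (Mann–Whitney) comparisons of activation- vs
repression-class gene expression are delegated to scipy and surfaced in the
pipeline report; BH adjustment delegates to statsmodels.

## The synthetic dataset

The generator emulates the study design rather than any particular genome:
4 autosomes of 400 kb plus one 400 kb sex chromosome with PAR [0, 320 kb),
SDR_FEMALE [320, 360 kb) and SDR_MALE [360, 400 kb) — the two SDRs share one
chromosome because the layout requires a single region class per base; each
sex's analyses use its own SDR interval. Bin-aligned genes (800–1,200 bp,
200–400 bp gaps; ~1,500 genes over ~2 Mb) are planted with a signature class
per region: autosomes 55/20/15/10% activation/mixed/repression/null, the PAR
with a repression excess (30/20/40/10) and the SDRs 25/25/35/15. TE overlap
(15% autosome, 45% PAR, 60% SDR) and young-gene fractions (5/30/40%) differ
by region as in real UV systems. Within a class, a concrete group subset is
sampled (S3 dominating activation). States are painted over each gene's
bins in contiguous blocks, one per group, with the null state elsewhere, so
re-deriving signatures from the painted states through the signatures module
reproduces the planted truth exactly — an internal consistency oracle the
tests assert.

ChIP reads are Poisson per bin with rate = emission × depth. The depth
default is 15 (enriched bins ≈ 12.8 reads, background ≈ 0.45 against a flat
1×-coverage control), chosen once so that per-replicate binarization
sensitivity exceeds 0.95 under the SES background; two replicates per
sex/mark are OR-combined. Five percent of genes are sex-biased (a minority,
but enough at this scale for stable transition fractions), with planted
|log2FC| in [1.5, 3]; 60% of biased genes switch signature class between
the sexes (activation in the favoured sex) and 5% of unbiased genes switch
for other reasons. Expression is log-normal around class means of
log2(TPM+1) = 6 / 3.5 / 1.5 / 0.5 (activation/mixed/repression/null,
sd 0.8); counts are Poisson around TPM × kb × depth-factor with 10%
log-normal replicate noise. The DE table is written directly from planted
truth (exact fold changes; adjusted p ∈ 10^[−8,−3] for biased, [0.2, 1]
otherwise) because DE fitting is out of scope. Everything is deterministic
given the seed.

What the generator does **not** emulate: mappability and GC bias, fragment
size effects, chromatin-state boundaries inside intergenic regions, overlap
between neighbouring genes, library-composition artefacts, and genuinely
noisy DE statistics. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the assumed generative structure, not
robustness to those real-data complications.

## Problem sizes and numerical choices

Default test and example runs use the ~2 Mb / ~1,500-gene genome (10,000
bins per sex at 200 bp), where a full pipeline run takes well under a
minute on one CPU; parameter-recovery checks use 50,000-bin simulated
sequences. Emission clipping 1e-6; posterior ties broken to the lowest
state index after rounding posteriors to 12 decimals; percentile
thresholds by linear interpolation; division conventions 0/0 → 0 and
x/0 → capped for ratio tracks. All writers emit tab-separated,
newline-terminated, header-bearing text; pipeline tables carry a comment
line naming the producing stage and the run's config hash, and a run log
records versions, seed and config.

## Known limitations

- Signature assignment is set-valued and unweighted: one misdecoded bin can
  add a group to a gene, so signature agreement degrades faster than
  bin-level decoding accuracy on noisy data.
- The HMM assumes conditionally independent marks given the state and a
  single parameter set across sexes and chromosomes.
- Sex-specific domains use an any-overlap criterion with no reciprocal
  fraction; "domains" default to merged footprints of silent-group states
  when no external peak calls are given.
- The permutation test conditions on the realized signature table; it does
  not model uncertainty in the segmentation itself.
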