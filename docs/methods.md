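# Methods

This note records the models, parameter choices and numerical conventions
behind `rrbspipe`, and what the synthetic experiments do and do not
establish about real RRBS data.

## Library simulation

**Genome.** Contigs are i.i.d. uniform A/C/G/T with designated island
blocks (every fifth 200-bp block by default) in which CG dinucleotides are
placed at `cpg_enrichment / 16` per dinucleotide (the background CG rate
under uniform bases is 1/16, so enrichment is a multiplier; capped at
0.45). One extra contig is appended and flagged as the fully unmethylated
spike-in control, the stand-in for lambda DNA. Islands concentrate both
MspI/TaqI sites and CpGs, which is the point of reduced representation:
the assayed fraction is CpG-dense.

**Digestion and size selection.** Cuts are taken at every forward-strand
occurrence of each recognition site at the enzyme's offset (MspI C^CGG,
TaqI T^CGA — both palindromic, so forward scanning is exhaustive), with
the union of cut positions partitioning each contig. Size selection keeps
40–240 bp fragments inclusive. Enzymes are config-overridable
`(name, site, offset)` triples.

**Methylome.** Each CpG dyad draws one baseline level shared by both of
its strands (symmetric maintenance methylation). The default baseline is
Beta(2, 2): real somatic methylomes are bimodal, but a mid-heavy baseline
keeps every simulated site statistically informative at desk-scale
coverage, which is what the power and calibration experiments need;
bimodality can be restored by passing any `baseline_dist`. Non-CpG
cytosines get constant low levels (CHG 0.01, CHH 0.008, matching the
sub-percent non-CpG methylation of mammalian muscle). Spike-in contigs
are zero everywhere.

A `diff_fraction` of dyads is designated differential with an effect of
exactly `delta` percentage points. The direction of the effect is
constant within 20-kb blocks of a contig: differential methylation in
tissues occurs over domain-scale regions, not with site-by-site sign
flips, and this coherence is what makes promoter-level
methylation–expression coupling well defined. A differential baseline
that cannot accommodate the block's direction is redrawn uniformly from
the feasible range so the effect stays exact; only `delta` > 100 can
force clipping (flagged per site). With more than two groups each
differential site is carried by a single group drawn uniformly, so every
pairwise comparison receives signal and F2-inheritance patterns arise
naturally.

**Reads.** Each fragment yields `depth` reads on average (multinomial
across fragments), each read choosing an original strand (OT/OB)
uniformly and reporting the fragment's 5′ end on that strand truncated to
114 bp. Spike-in fragments collectively receive 1% of read mass,
mirroring the 1% spike-in. Per cytosine on the read strand: a methylated
draw always reads C (no over-conversion — no such rate is modelled);
an unmethylated cytosine reads T unless conversion fails (probability
1 − conversion_rate, default 0.005). Uniform substitution errors (default
10⁻³, a typical HiSeq orientation figure; declared, not inferred) are
applied after conversion. Qualities are constant Q40 with an optional
degraded-tail mode used to exercise the quality filter. Untreated reads
for SNP discovery skip conversion and emit the alternate allele with
probability 0.5 per covering read (heterozygote/pool model).

**Expression.** Log2-scale microarray-like values, baseline N(7, 1),
noise SD 0.5, group shift 2.0 for differential genes (4 residual SD —
comfortably detectable at n = 5 vs 5, as a power calculation confirms).
With linkage enabled, a gene whose TSS lies within 10 kb of a designated
differential CpG receives a shift of sign opposite to the methylation
difference between the two modelled groups — promoter methylation
repressing transcription.

## Analysis stages

**Read QC.** Keep a read iff mean Phred > 20 (strict), no N anywhere, and
post-trim length ≥ 30 bp. Trimming removes a 3′ adapter occurrence first
(exact match, minimum overlap 6 — no mismatch tolerance is modelled),
then 2 bp from each end (end-repair fill-in bases carry no genuine
methylation signal). The length check runs after trimming: a shorter
fragment cannot be aligned reliably, so trimming first is the
conservative order. Filtering is idempotent; QC reports conserve counts.

**Alignment.** Unique-best exhaustive scan in C→T space over both
original strands (the directional protocol produces no complementary
strands). Default mismatch budget 2 in converted space. Ties at the best
mismatch count are discarded as multi-mapping. The exhaustive scan is
O(genome × read) and vectorised; it is exact, auditable, and
exchangeable for an indexed aligner with identical output at larger
scales. Mapping efficiency is reported but carries no guarantee — it is
library-dependent.

**Calling.** At every reference cytosine covered on the read's
originating strand, read C increments methylated, T unmethylated,
anything else is ignored (error or SNP). Context comes solely from the
reference: the two downstream bases on the cytosine's strand give CpG /
CHG / CHH; truncation at a contig edge gives CN_unknown. The conversion
rate is estimated as converted / total calls over spike-in cytosines in
all contexts.

**Site filtering.** Order: (1) unite CpG-context sites with coverage
≥ 10× in every sample (strict per-sample semantics); (2) drop
zero-variance sites — per-sample percentages all identical — which
subsumes the all-0% and all-100% cases; (3) remove sites flagged by the
variant screen, including sites whose CpG-partner position is flagged (a
SNP on either side of the dyad corrupts calls on both). Counts reconcile:
united = tested + invariant-removed + SNP-removed.

**Variant screen.** Pileup over uniquely placed untreated reads: flag a
position when coverage ≥ 10, the top non-reference allele reaches 20% of
the pileup and at least 2 reads. These thresholds are a deliberate,
explicit replacement for a black-box caller; they are config keys.

**Per-site test.** The binomial logistic LRT described in the README.
Fitted proportions are clipped to |logit| ≤ 15 under separation, keeping
the statistic finite and conservative. meth_diff uses pooled
(coverage-weighted) within-group proportions. FDR control is
Benjamini–Hochberg; q-value dialects based on p-value–distribution
estimation are intentionally not reproduced, BH being deterministic and
directly verifiable against its definition. Significance is strict on
both thresholds (q < 0.05, |diff| > 25).

**Clustering.** Samples are clustered on 1 − Pearson correlation of
methylation-percentage profiles with Ward linkage via the Lance–Williams
recurrence on squared distances; ties break toward the lowest
cluster-index pair, making merges deterministic for a given sample
order. A constant profile has undefined correlation and raises, naming
the sample.

**Annotation and origin.** Precedence promoter > exon > intron >
intergenic, with promoter = within 2 kb of any TSS on both sides (the
two-sided window is the conventional default; the source phrasing is
sideless). TSS distances are signed on the gene strand, negative
upstream. Origin attribution is the frozen eight-row truth table over the
three F2-vs-purebred differential flags: no-difference to Duroc plus a
difference to at least one Pietrain group ⇒ Duroc-origin; difference to
Duroc plus no-difference to at least one Pietrain group ⇒
Pietrain-origin; anything else unassigned. The "or both" ambiguity in the
Pietrain clause is resolved as a logical OR of negations.

**Integration.** Two-group fixed-effect ANOVA per gene (≡ pooled-variance
t, F on (1, n−2)); zero pooled variance with equal means returns p = 1.
Matching takes every (significant CpG, gene) pair with |site − TSS| ≤
10 kb, both sides. Pearson r between per-sample methylation percentage
and expression is computed over the samples shared by both assays (≥ 3
required; constant vectors are dropped with a warning). The headline
tally is the negatively correlated fraction among pairs whose gene is
differentially expressed at p < 0.05.

## Experiment sizes and calibration

The statistical guarantees are checked on count matrices drawn directly
from the true methylome — Poisson(coverage) reads per sample and site
(floor 1), binomial methylated counts — which is exactly the sampling
model the read-level stages induce at a reference CpG and keeps the
simulation studies at their intended size: ~2,000 CpG dyads (two 10-kb
contigs at 5× CpG enrichment), 5 vs 5 samples, ~30× coverage, five seeds.
Under the null the per-site p-values are near-uniform (mean KS distance
< 0.05) and fewer than 1% of sites pass both significance gates; at
Δ = 30 on 10% of sites, mean sensitivity exceeds 80% with 100% sign
agreement among detections and mean absolute effect error below 10
points. Note that at this design the strict |diff| > 25 gate sits 0.9 SD
below the true effect, so per-seed sensitivity hovers near its floor —
that is a property of the published thresholds at 30×, not of the
implementation. The read-level path (digestion through calling) is
validated separately: every call at ≥ 30× is statistically consistent
with its true level, and conversion-rate estimation from ≥ 10⁴ spike-in
calls at 0.995 recovers > 99%.

## What the synthetic data does not show

Uniform-composition genomes lack repeats, CpG-island shores, SNP linkage
structure and chromosome-scale variation; the aligner therefore faces
less ambiguity than a real pig genome presents. Methylation levels have
no biological within-group variance beyond binomial sampling, so the
logistic model is exactly correctly specified — real data are
overdispersed, and no overdispersion correction is applied (matching the
analysis being emulated). Expression linkage is a constructed
sign-opposition, not a mechanistic model. Passing tests therefore verify
the pipeline's arithmetic, contracts and calibration under its stated
model, not effect sizes on real libraries.

## Known limitations

Indels, soft-clipping, MAPQ and CTOT/CTOB strands are not modelled.
CN/CHN contexts beyond contig-edge truncation are not disambiguated.
Differential testing covers CpG context only, per-site (no tiling), with
no covariates. The exhaustive aligner is quadratic and intended for
desk-scale genomes.
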