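# Methods

This note records the models, estimators and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and
do not emulate, and the design decisions taken where more than one
reasonable construction existed.

## Genotype model and fidelity statistics

Genotypes are alt-allele dosages in {0, 1, 2}; −1 marks a missing call
and is excluded from every pairwise comparison (so discordance
denominators count jointly non-missing SNPs only — a deliberate,
documented convention).  The simulator draws each subject's germline
under Hardy–Weinberg from per-SNP MAFs (default uniform on
[0.05, 0.5]), plants `n_mutations_per_ipsc` somatic mutations in each
iPSC line (copied to its paired MK — these are the "transmitted"
events), and applies a symmetric miscall model: with probability
`error_rate` a call is replaced by one of the two other codes with
equal probability.  The default per-call error rate of 2.5×10⁻⁵ makes
simulated pairwise discordance land in the 10⁻⁴–10⁻² % range observed
for within-donor line pairs on modern arrays; the platform-level 0.37 %
error benchmark quoted in reports is a user-supplied constant derived
from external control samples, not something the pipeline recomputes.

**LD pruning** is greedy and windowed (defaults 50 SNPs, step 5,
r² > 0.3): within each window, while any retained pair's squared
Pearson correlation of dosages (composite LD, computed over jointly
non-missing samples) exceeds the threshold, the member of the worst
pair with the lower MAF is dropped (ties: the later-positioned SNP).
Removing a SNP never changes remaining pairwise r², so each window's
correlation matrix is computed once.

**IBD estimation** is the method of moments: observed
identity-by-state (IBS) counts per pair are matched against their
expectations given IBD state, using the standard conditional
probabilities (e.g. P(IBS=0 | IBD=0) = 2p²q²).  Allele frequencies are
estimated from the founder-like samples (one MNC per subject when
present).  The finite-sample bias correction replaces each frequency
monomial pᵃqᵇ with its unbiased factorial-moment estimator from founder
allele counts — with few founders the plug-in powers are badly biased
and between-subject Z2 drifts upward, which is why small examples use
several subjects.  Solutions are clipped to [0, 1] and renormalized to
sum to one; pairs with fewer than `min_informative` (50) jointly
non-missing markers are flagged rather than estimated.

**Transmitted discordances** count SNPs with all three lineage calls
present where MNC ≠ iPSC and iPSC = MK.  As the rate denominators use
jointly non-missing SNPs, an MNC miscall also presents as a transmitted
event — an acknowledged upward bias of the estimate.  Summary reports
round rates to one significant figure in percent; machine outputs keep
full precision.

## SNP-array signal model and CNV HMM

Per probe the array reports an LRR (total-intensity log2 ratio) and a
BAF in [0, 1].  Both the simulator and the caller share one emission
model: LRR ~ Normal(μ_c, σ) with per-copy-number means
(−3.5, −0.66, 0, 0.40, 0.68) for copy numbers 0–4 (σ defaults: 0.2 in
the simulator, 0.25 in the caller — the caller is deliberately slightly
diffuse); BAF is a mixture over genotype bands at k/c for k B alleles
out of c copies, weighted by Hardy–Weinberg at the probe's MAF, with
Gaussian jitter (sd 0.03) truncated to [0, 1] plus a 1 % uniform
outlier component.  Copy number 0 emits uniform BAF.  The simulator
clips jittered values (reproducing the rails real arrays show at 0 and
1); the caller's density uses renormalized truncated normals, a benign
mismatch at the boundaries.  When a track carries no MAF column the
caller assumes MAF 0.5.

The HMM has five states, uniform initial distribution, and a fixed
per-step state-change probability of 10⁻⁴ split evenly among the four
other states; inter-probe distance is not modelled (adequate for
arm-scale and ≥ 10-probe events; an extension point).  A copy-neutral
LOH state is omitted — only deletions and amplifications are of
interest here.  Decoding is exact Viterbi in log space, per chromosome.
Maximal runs of a constant non-diploid state with ≥ 10 supporting
probes become segments.  Under default noise the decoder's boundaries
wobble by at most a probe or two; consequently a 9-probe aberration can
occasionally be emitted as part of a 10-probe call that recruited one
flanking probe — the support threshold guarantees that no call ever
stands on fewer than 10 probes, not that sub-threshold events leave no
trace.  Parent/daughter call sets are matched by same chromosome, same
gain/loss direction and reciprocal overlap ≥ 50 % (the comparable
published analyses adjudicated such differences manually; the overlap
rule makes the comparison reproducible, and evidence extracts — LRR/BAF
windows around each unmatched call, with flanks — support visual
review).

## Paired differential expression

The IQR filter retains transcripts whose raw-FPKM interquartile range
across **all** samples (both cell types, all replicates) exceeds 1,
with quartiles by linear interpolation (numpy's default, "type 7").
This keeps transcripts silent in iPSCs but modestly expressed in MKs —
exactly the biology of interest — while discarding single-sample
spikes that a mean or variance filter would keep.

Δ is built per subject as the mean over technical replicates of
log2(FPKM_iPSC + 1) − log2(FPKM_MK + 1); the offset of 1 maps FPKM 0 to
exactly 0.  Subjects with a single complete replicate pair use it alone
(flagged); subjects with none are excluded.  Δ keeps the iPSC − MK
orientation internally; user-facing fold changes are reported as
MK − iPSC (= −β₀) so "up in MK" is positive.

**Principal components.**  Scores come from the SVD of the
column-centred Δ (each subject's mean over transcripts removed), no
scaling.  Column centring—rather than per-transcript centring—was a
deliberate choice: per-transcript centring forces subject scores to be
exactly mean-zero, which makes the fitted intercept algebraically
identical with or without the PC covariates, so a batch factor that
shifts whole subjects could never be adjusted out of β₀.  With column
centring the scores retain subject-level offsets and the regression
absorbs them.  The cost is that when transcript-mean spread dominates
(a massive cell-type contrast), the leading component approaches a
constant subject profile — collinear with the intercept and fatal to
identifiability — so components whose score vector is statistically
constant (|mean| > 5 × sd) are skipped in favour of the next ones.
Variance fractions are reported against the total variance of the
centred matrix.  Sign convention: each kept component's
largest-magnitude transcript loading is positive.

**Moderated inference.**  Per transcript, OLS of Δ on [1, PC1, PC2]
(residual df d = n_subjects − 3).  The empirical-Bayes hyperparameters
(d₀, s₀²) are estimated by the canonical moment matching on
log-residual variances: e_g = log s²_g − ψ(d/2) + log(d/2) has excess
variance ψ′(d₀/2), inverted by Newton iteration on the trigamma
function; s₀² follows from the mean.  The posterior variance is
s̃² = (d₀s₀² + d·s²)/(d₀ + d), the moderated t = β̂₀/(s̃·c) with c the
intercept's unscaled SE factor, referred to t with d + d₀ df (normal
when d₀ = ∞, which arises for exactly homoskedastic input).  d₀ = 0
recovers the ordinary per-transcript t exactly; the test suite
cross-checks β₀, t, p, d₀ and s₀² against R limma on a shared fixture.

**q-values** are Storey's, with π̂₀ from a cubic polynomial trend of
π₀(λ) = #{p > λ}/(m(1 − λ)) over λ = 0.05…0.95 evaluated at the largest
λ, clipped to (1/m, 1]; with fewer than 100 p-values the raw estimate
at λ = 0.95 is used.  π₀ = 1 gives Benjamini–Hochberg exactly.  Output
is monotone in p and capped at 1.

A sensitivity mode reruns the whole chain (filter, Δ, PCs, fit,
enrichment) with a sample-exclusion list; excluded samples drag their
paired partner with them, and the report compares the sets of highly
significant (q < 0.001) enriched terms between the full and reduced
runs — top-k lists are not compared because their tails shuffle among
null terms.

## Gene-set enrichment

Per direction, a gene's score is the minimum p over its transcripts
whose β₀ sign matches; genes with no matching transcript score 1.  Per
term, the statistic is the one-sided two-sample KS statistic
D⁺ = sup[F_members − F_others] (positive when member scores are
stochastically smaller), with asymptotic p = exp(−2·mn/(m+n)·D⁺²); an
exact label-permutation mode is available and is validated against
exhaustive enumeration in the tests.  The "Significant" column counts
member genes whose best matching-direction transcript reaches
q < 0.05; "Expected" is the term size times the universe-wide
significant fraction, so Expected/Annotated is constant across terms
by construction.  This is the classic flat-set KS test: **no GO-DAG
decorrelation (topGO-style weighting) is applied**, so ancestor terms
of a true signal co-rank with it; with a real GO catalog the leading
terms should be read as a correlated family, not independent
discoveries.  A term covering the whole universe has no complement and
is reported flagged with p = 1.

## Expression-based arm CNV detection

For two technical replicates of the same line, per-transcript
log2((FPKM_a+1)/(FPKM_b+1)) is computed over the IQR-retained set
(configurable), transcripts are assigned to chromosome arms by start
coordinate (centromere = boundary between the last p and first q
cytoband; acen bands count toward their lettered arm), and the
statistic is the target-arm mean minus the same chromosome's other-arm
mean (whole-transcriptome background by flag).  The published analyses
display this contrast; the label-permutation test
(p = (1 + #{perm ≥ obs})/(n_perm + 1), default 9,999 permutations,
floor 10⁻⁴) makes the visual criterion reproducible.  Expression
under-responds to DNA dosage: a planted DNA factor of 2 yields a mean
log2 fold change around 0.8–0.9, well below 1, for two reasons — the
+1 offset compresses ratios at modest FPKM, and replicate noise
regresses the mean toward 0.  Real data attenuate further through
dosage compensation, which the generator does not model.

## What the generators do and do not emulate

Emulated: lineage structure (MNC + up to two iPSC/MK pairs per
subject, named I/M + subject + A/B), Hardy–Weinberg genotypes, symmetric
miscalls, transmitted mutations, LRR/BAF band structure with outliers,
paired 14-subject × 2-replicate FPKM studies with a dominant cell-type
effect, per-transcript (optionally heteroskedastic) noise, batch
covariate loadings, direction-coherent gene-set signal and a
single-replicate arm duplication.  Not emulated: genotype-calling
physics and cluster artifacts, LD between SNPs (simulated SNPs are
independent, so pruning exercises only the sampling-noise pathway),
GC-wave LRR artifacts, mosaicism, read-level RNA-seq (counts,
transcript-length effects, mapping bias), dosage compensation, and the
GO DAG.  Passing tests therefore demonstrate correctness of the
estimators and decision rules under the stated models, not robustness
to these unmodelled artifacts.

## Problem sizes and determinism

The shipped defaults (6 genotyped subjects × 20,000 SNPs; 6,000 probes;
14 subjects × 3,000 transcripts; 40-term catalogs) are chosen so a full
orchestrated run completes in seconds while every recovery statistic is
comfortably powered; the whole-pipeline checks scale selected pieces up
(946,674 SNPs for the worked example, 80,000 SNPs for IBD, 200 CNV
tracks, 100 enrichment catalogs).  Every source of randomness is a
`numpy.random.default_rng` seeded from one master seed with fixed
per-stage offsets, so reruns are byte-identical; the orchestrator
records a configuration hash alongside the outputs.

## Known limitations

- The HMM omits distance-dependent transitions and a copy-neutral LOH
  state; X/Y chromosomes receive no special handling.
- The IBD estimator assumes unlinked markers; feeding it unpruned data
  inflates the effective-marker count and narrows Z estimates
  artificially.
- π̂₀'s polynomial smoother can be unstable for very small transcript
  sets; below 100 p-values the conservative raw estimate is used.
- Enrichment p-values are asymptotic by default; for terms of fewer
  than ~10 genes the permutation mode is more trustworthy.
- The 0.37 % platform error benchmark is carried through reports
  verbatim; computing it requires external control-sample data.
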