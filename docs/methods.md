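# Methods

`clonemut` implements the downstream mutation-analysis computations used to
quantify deaminase-induced (APOBEC3B-style) genome-wide mutagenesis in
clonal cell lineages, together with a synthetic-lineage generator that
makes every stage testable against planted ground truth. This note
documents the models, the defaults and why they were chosen, the numerical
decisions, and what the simulation-based tests do and do not demonstrate.

## The experimental design being modeled

A clonal "mother" line yields "daughter" clones that are repeatedly pulsed
with either an A3B-eGFP deaminase construct (case) or an eGFP control;
single-cell "granddaughter" subclones are then isolated, so that any
mutation fixed in one daughter cell appears in the granddaughter clone at a
predictable allele fraction set by local ploidy (50% diploid, 33% triploid,
25% tetraploid). The pipeline's job is to measure, per granddaughter:
new base substitutions (from SNP-array genotype differences and from WGS
call sets), their strand-collapsed class and trinucleotide-context
spectrum, the mutational signatures mixing in each clone, enrichment of
cytosine mutations in the deaminase-preferred 5'TC motifs, copy-number
aberrations relative to controls, and replication-strand asymmetry.

## Synthetic lineage generator (`clonemut.simulate`)

Two mutational processes are planted on an i.i.d. random reference:

* **A3B-like**: events at cytosines on either strand. The pyrimidine-
  normalized trinucleotide context is drawn from `a3b_motif_weights`
  (default: TCA 0.35, TCG 0.35, TCT 0.15, TCC 0.10, the remaining 0.05
  spread over non-TC contexts — mass concentrated on the 5'TCR motifs the
  enzyme prefers biochemically); the outcome is C>T/C>G/C>A with
  probability `a3b_ct_cg_t_ratio` (default 0.6/0.3/0.1 — a declared
  simulator policy, since the C>T:C>G ratio of the process is not a
  published constant).
* **MMR-deficiency-like background**: context-independent substitutions
  with class weights defaulting to C>T 0.42, C>A 0.30, T>C 0.14, C>G 0.06,
  T>A 0.04, T>G 0.04 (a predominantly C>A/C>T/T>C mutator spectrum);
  T>C events are placed on leading vs lagging replication-template blocks
  with rate ratio `tC_asymmetry` (default 3.0); indels have lengths
  uniform on [1, 46] bp (only the range is established; the distribution
  within it is simulator policy).

Replication direction is an alternating-block BED written with the
reference (`strand_block_size`, default 20 kb); no replication-timing model
is attempted. Ploidy defaults to a diploid genome with a triploid middle
third, loosely mirroring an aneuploid 293-like karyotype; every planted
variant gets allele fraction 1/CN of its segment. Case clones additionally
receive Poisson(`cna_per_a3b_event` x their A3B SNV count) copy-number
events, each a +-1 copy change over a random interval (floored at CN 1, so
CN-0 exclusions remain a control-side property).

**Scale.** Defaults simulate a 200 kb reference with 3 case + 3 control
clones, ~1,200 background SNVs, ~500 indels and (cases) ~2,250 A3B SNVs per
clone. With the background's cytosine-class mass of 0.78 this plants an
expected case/control cytosine-mutation fold of
(0.78·1200 + 2250)/(0.78·1200) ≈ 3.4. These per-clone mutation loads are
in the range the WGS analyses of such lineages produce; the genome length
and indel count are scaled to desk size (the genome-scale indel load,
>10,000 per clone, would be reproduced proportionally on a full-length
genome). Per-clone realized counts are Poisson draws; per-clone random
streams are derived from the global seed by fixed offsets so adding clones
never reshuffles earlier ones.

Array genotype tables place probes on a fixed random grid **plus a probe at
every truth SNV position** — a deliberate simulator convenience so that
array-calling recovery is testable at desk scale; real arrays observe only
a fixed panel, so absolute array call counts from the simulator should not
be read as genome-wide totals. ~8% of non-truth probes are germline
heterozygous (excluded from calling by design), and ~2% of GenCall scores
fall below the 0.15 reliability cutoff to exercise the filter.

**What the generator does not emulate:** read-level errors (no FASTQ/BAM),
caller-specific error models beyond uniform dropout plus private false
positives, kataegis clustering, subclonal allele fractions, germline SNP
linkage structure, or sequence composition beyond i.i.d. bases. Passing
recovery tests therefore demonstrates correctness of the downstream
arithmetic and filtering logic, not robustness to real sequencing
artifacts.

## Array calling (`clonemut.arraycall`)

Probes with GenCall < 0.15 are discarded per table (scores equal to the
threshold are retained — the discard rule is "below"); only probes passing
in both clones are compared. A call requires a homozygous parent genotype
and a child genotype introducing exactly one new allele; the class is
parent-allele-to-new-allele, reverse-complemented when the parent allele is
a purine, which collapses opposite-strand probe readouts into six classes.
Heterozygous parents are excluded (a het change is ambiguous between
mutation and loss of heterozygosity), child genotypes with two distinct new
alleles are ignored as ambiguous double changes, and a de-novo homozygous
child (C/C -> T/T) is scored as the same class as C/C -> C/T.

## Consensus filtering (`clonemut.consensus`)

Kept = (caller A ∩ caller B), unioned across per-normal runs, then filtered:
allele fraction strictly greater than 0.5 removed (0.5 retained — the rule
is strict), positions inside any mask interval removed. Mask BEDs are
0-based half-open; the 1-based variant position is converted at the
membership test. Records with missing AF are retained and logged. Indels
flow through identically, matched exactly on (chrom, pos, ref, alt) with no
left/right realignment. "Consistent mapping errors" are not operationalized
here; they enter as an extra user-supplied mask.

## Spectra (`clonemut.spectrum`)

Channel order is fixed and written into output headers: class-major
C>A, C>G, C>T, T>A, T>C, T>G with flanking contexts lexicographic, giving
the standard 96 channels; the 48-channel cytosine view is a row selection,
never a recount. Counts are raw observed counts (no genome-composition
normalization). Multi-allelic VCF records are split before counting;
contig-edge SNVs (no full trinucleotide) are skipped with a logged count, so
per-sample channel sums equal the number of context-resolvable SNVs.

## Nonsmooth NMF (`clonemut.nsnmf`)

Model: V ≈ W S(θ) H with S(θ) = (1−θ)I + (θ/q)11ᵀ, q the rank. The fit
minimizes generalized KL divergence D(V‖WSH) — the Brunet-lineage objective
that nonsmooth NMF modifies — by alternating multiplicative updates in
which the H update sees the smoothed basis W·S and the W update the
smoothed coefficients S·H. Each half-step is a standard KL-NMF update with
the other factor frozen, so the recorded objective is non-increasing at
every iteration (asserted in tests). A Frobenius objective is available via
the plain-KL reduction at θ=0 plus scikit-learn-style alternatives being
out of scope; KL is the default and only mode.

Numerical choices: zeros of V receive a 1e-9 pseudocount; initialization is
uniform(0,1) per restart from one seeded generator (default 10 restarts,
tol 1e-6 relative objective change, max_iter 2000); θ defaults to 0.5 (a
conventional middle value — the smoothing degree is not a published
constant) and is exposed everywhere. After convergence W columns are
normalized to sum to 1 with the scale moved into H's rows; for θ>0 this
presentation rescale perturbs W·S·H slightly because S does not commute
with a diagonal rescale — explained variance is always computed from the
stored (W, S, H), and the θ=0 path is exact. Signatures are ordered by
total exposure, descending, to stabilize labels.

**Contribution shares and the smoothing floor/cap.** Reported per-sample
contributions are the column-normalized smoothed exposures S·H — the
effective mixture each sample's reconstruction uses. Because S's columns
sum to 1, every such share is confined to [θ/q, 1−θ+θ/q] (at θ=0.5, q=3:
[1/6, 2/3]): a sample with zero exposure to a signature still shows the
floor θ/q, and no share can exceed the cap. This is an inherent property of
the nonsmooth parameterization, not an estimation error; raw (unsmoothed)
exposure shares are available via `sample_contributions(model,
smoothed=False)` when shares outside that band are of interest. At this
package's cohort scale (96 channels × 6 samples), mixture shares inside the
band are recovered to within a few points on planted data; shares outside
the band saturate at the floor/cap, and the multiplicative estimator at
θ=0, while unconstrained, visibly overfits (162 free parameters for 288
cells) and overstates dominant shares by ~5–10 points. Both behaviors are
exercised in the test suite.

**Rank selection** fits each candidate rank, reporting Frobenius explained
variance (evar = 1 − ‖V−WSH‖²_F/‖V‖²_F) and a restart-stability score (mean
Hungarian-matched cosine of each restart's W against the best restart's),
choosing the smallest rank whose evar exceeds a threshold (default 0.99) —
diagnostics are always returned so the user can override. Rank k+1 receives
one warm-started restart embedding the rank-k best fit with a small-scale
extra column/row; this makes evar non-decreasing in rank at θ=0, and only
approximately so at θ>0, where S changes with the rank and exact embedding
is impossible. "Total variance" is Frobenius evar throughout; a
mean-centered variant is not offered.

## Enrichment statistics (`clonemut.stats`)

`fisher_exact` computes the two-sided p by summing hypergeometric
probabilities (fixed margins) of all tables no more probable than the
observed one, with a (1+1e-7) relative tie tolerance; the pmf is evaluated
by vectorized log-gamma arithmetic. The test suite verifies it against an
exact integer/Fraction enumeration oracle for every table with margins ≤ 30
and against an independent library implementation. The odds ratio is the
sample OR a·d/(b·c), Haldane-corrected (0.5 per cell) only when a cell is
zero so it stays displayable. Type-I calibration is checked on null
hypergeometric tables with large margins (8000/4000/400), where the
discrete p-values are near-uniform; with small margins any exact test is
intrinsically conservative, which is a property of the statistic, not the
implementation.

`motif_enrichment` builds, by default, (mutated cytosines in-motif vs out)
against (genomic cytosine sites in-motif vs out) — the motif may carry
IUPAC flanks (TCW, NCG, ...) — and also reports fold enrichment =
(mutation fraction in motif)/(site fraction in motif). The alternative
"observed vs expected-from-context-frequency" table is available via
`table="expected"`. For clone groups, per-clone context counts are averaged
and rounded to the nearest integer before the single exact test
(`average_mutation_counts`); signature-weighted counts
(`signature_context_counts`) allocate a mutation total over contexts by a
signature's cytosine-channel weights. No multiple-testing correction is
applied by default (raw p-values are reported); Bonferroni and
Benjamini-Hochberg are available via `adjust_pvalues`.

`tcw_transversion_test` compares per-sample C>G proportions in TCW contexts
(TCA, TCT) against the other 14 contexts with a classic equal-variance
Student's t (Welch via `equal_var=False`); whether proportions or counts
are compared is the caller's choice of input, proportions being the
default used by the pipeline. Degenerate zero-variance/equal-mean groups
return t=0, p=1 with a warning.

## CNA differencing and strand asymmetry (`clonemut.cna`)

Case and control segment tables are intersected on the fly into atomic
grid segments (0-based half-open arithmetic; sub-segments inherit their
parent's copy number). A grid segment is excluded when the control clones
are not identical to each other or any control CN is 0 (the stricter of
the two possible readings of the exclusion rule; the alternative —
case-vs-consensus with only CN-0 excluded — is selectable via
`mode="case_vs_consensus"`). Remaining deltas (case − control) are binned
into gains and losses. Burden correlation is ordinary least squares plus
Pearson r (the best-fit-line method is not otherwise specified; OLS is the
default assumption), with constant-y returning slope 0, r 0, and
zero-x-variance an error. Strand asymmetry assigns each pyrimidine-
normalized SNV to its leading/lagging block and reports per-class
log2(leading/lagging) with a Haldane 0.5 correction when a count is zero;
mutations outside annotated blocks are tallied separately.

## Pipeline and reproducibility (`clonemut.pipeline`)

`run_pipeline` chains simulate → array calls → consensus (on simulated
two-caller outputs of each truth catalog) → 96/48-channel spectra → rank-3
θ=0.5 nsNMF → motif tests (per clone group, averaged counts) and the TCW
t-test → CNA differencing, burden correlation and strand asymmetry. The
A3B-like signature is identified as the extracted signature with the most
5'TC cytosine-channel mass. `summary.json` contains no timestamps and is
byte-identical across runs with the same seed; `manifest.json` carries the
config snapshot, package version, SHA-256 digests of every output and the
elapsed time. Plots (a 96-channel bar chart) are opt-in so tabular runs
stay headless.

## Known limitations

* The simulator's i.i.d. reference underestimates context autocorrelation
  (CpG depletion, repeats), so genomic context-site fractions are more
  uniform than in a real genome; motif-test power on real data will differ.
* Consensus filtering trusts the caller outputs' coordinates; no indel
  normalization means equivalent left/right-aligned indel representations
  do not intersect.
* Smoothed contribution shares cannot leave [θ/q, 1−θ+θ/q]; interpret
  shares near those bounds as "at or beyond" the bound.
* The array caller cannot see mutations at heterozygous-parent probes or
  probes failing GenCall in either clone; simulated recovery is defined
  relative to that detectable set.
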