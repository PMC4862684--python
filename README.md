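# clonemut

Mutation-analysis toolkit for clonal cell-lineage mutagenesis experiments —
the kind of study that pulses a daughter clone with an APOBEC3B-style
cytosine deaminase, isolates single-cell granddaughter subclones, and asks
what the enzyme did to the genome on top of the cell line's intrinsic
mutator background.

It is aimed at analysts working with paired clone genotype tables (SNP
arrays), somatic call sets (VCF) and copy-number segment tables who need
the downstream computations:

* **Six-class array calling** — new substitutions between a parent and
  child genotype table, strand-collapsed so a `G/G → G/A` probe readout is
  scored as the same C-to-T event as `C/C → C/T`; probes with GenCall
  < 0.15 are discarded.
* **Consensus somatic filtering** — keep variants found by both callers,
  merge calls made against multiple normals, drop allele fractions > 0.5
  and anything in repetitive/mapping-error masks.
* **Trinucleotide spectra** — the standard 96-channel (6 pyrimidine-
  reference classes × 16 contexts) count matrix and its 48-channel
  cytosine view.
* **Signature extraction by nonsmooth NMF** — V ≈ W·S(θ)·H with
  S(θ) = (1−θ)I + (θ/q)·11ᵀ, fitted by multiplicative updates on the
  generalized Kullback–Leibler divergence D(V‖WSH); explained variance,
  per-sample contributions, rank diagnostics, cosine matching against a
  reference signature catalog.
* **Motif statistics** — Fisher's exact test of mutated cytosines vs
  genomic cytosine sites, in-motif vs out (TCA/TCC/TCG/TCT, IUPAC motifs
  like TCW), fold enrichment, and a Student's t-test for C-to-G
  transversions concentrating in TCW contexts.
* **CNA differencing and strand asymmetry** — gains/losses of a case clone
  on a shared segment grid against controls (control-disagreement and
  control-CN-0 segments excluded), CNA-vs-mutation-burden correlation, and
  per-class leading/lagging replication asymmetry.
* **A synthetic lineage generator** — plants an A3B-like process
  (C→T/C→G at 5'TC, preferring TCA/TCG), an MMR-deficiency-like background
  (C→A/C→T/T→C bias, strand-asymmetric T→C, 1–46 bp indels), ploidy-
  dependent allele fractions and load-linked CNA events, with full ground
  truth on disk — so every stage is testable without any downloads.

## Worked example

The package is used from Python (see `examples/` for one script per
capability); a thin `clonemut` CLI wraps the same stages
(`simulate`, `call-array`, `consensus`, `spectrum`, `signatures`,
`enrich`, `cna`, `asymmetry`, `pipeline`).

```python
from clonemut import SimulationConfig
from clonemut.pipeline import run_pipeline

summary = run_pipeline(SimulationConfig(seed=1), "run/", restarts=5)
```

With the default configuration (3 case + 3 control clones, ~2,250
A3B-like and ~1,200 background SNVs per case clone on a 200 kb
reference) this prints, via `scripts/acceptance.py --seed 1`:

```
cytosine_mutation_fold_case_vs_control  3.396
signature_explained_variance_pct        96.88
a3b_signature_contribution_case_pct     65.5
tca_enrichment_p_case                   1.5e-184
tcg_enrichment_p_case                   1.7e-235
tcg_fold_enrichment_case                4.21
tcw_c_to_g_t_test_p                     6.5e-06
cna_mutation_pearson_r                  0.954
t_to_c_strand_asymmetry_log2            1.543
```

Reading these: case clones carry 3.4× the control clones' cytosine
mutations (the planted excess, recovered); three extracted signatures
reconstruct ~97% of the spectra's variance; the signature with the most
5'TC mass contributes ~65% of case-clone mutations but sits at the
smoothing floor in controls; TCA/TCG motifs are enormously enriched in
cases (fold > 4) and null in controls; C→G transversions concentrate in
TCW contexts; copy-number burden correlates with mutation burden
(r ≈ 0.95); and T→C mutations show the planted ~3:1 leading/lagging
replication bias (log2 ≈ 1.58).

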