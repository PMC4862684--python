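"""Simulate a clone lineage with planted A3B-like and MMR-like processes.

Builds a small mother->daughter->granddaughter cohort: control clones carry
only the background mutator (C-to-A/C-to-T/T-to-C bias, strand-asymmetric
T-to-C, 1-46 bp indels); case clones add deaminase-style cytosine mutations
concentrated at 5'TC motifs plus copy-number events tied to their mutation
load. All ground truth is written to disk (FASTA, VCF, TSV, BED).
"""

import tempfile

from clonemut import SimulationConfig, emit_lineage

config = SimulationConfig(seed=7, genome_length=80_000,
                          a3b_snv_count=900, background_snv_count=480,
                          indel_count=200, n_probes=1500)
truth = emit_lineage(config, tempfile.mkdtemp(prefix="clonemut_"))

print(f"reference: {truth.reference_path} ({len(truth.reference)} bp)")
print(f"{'clone':>6} {'role':>8} {'SNVs':>6} {'indels':>7} {'A3B':>6} {'CNAs':>5}")
for name, cat in truth.catalogs.items():
    n_a3b = int((cat.df["process"] == "a3b").sum())
    print(f"{name:>6} {truth.clone_roles[name]:>8} {len(cat.snvs):>6} "
          f"{len(cat.indels):>7} {n_a3b:>6} {truth.cna_event_counts[name]:>5}")
print("\nCase clones carry the extra A3B-labeled cytosine mutations and CNA")
print("events; every planted variant's allele fraction equals 1/copy-number")
print("of its ploidy segment (e.g. 1/3 in the triploid middle third).")
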