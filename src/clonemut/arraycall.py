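"""SNP-array six-class mutation calling between paired clone genotypes.

A new base substitution is a clear genotype difference between a daughter
(parent) clone and her granddaughter (child) clone at the same probe. Calls
are strand-collapsed: because some array probes read the opposite strand, a
G/G -> G/A change is the same biological event as C/C -> C/T and both are
scored as a C-to-T transition, giving six substitution classes with a
pyrimidine reference (C>A, C>G, C>T, T>A, T>C, T>G).
"""

from __future__ import annotations

import logging

import pandas as pd

from .seqtools import CLASSES, COMPLEMENT

log = logging.getLogger(__name__)

NO_CALLS = {"./.", "NC", "--", "", None}
_VALID = set("ACGT")

#: default GenCall reliability cutoff; probes scoring below it are discarded
DEFAULT_GENCALL_MIN = 0.15


class InvalidGenotypeError(ValueError):
    pass


def _parse_genotype(gt) -> tuple[str, str] | None:
    """Parse 'C/T'-style genotype into a sorted allele pair; None = no-call."""
    if gt is None or (isinstance(gt, float) and pd.isna(gt)) or gt in NO_CALLS:
        return None
    s = str(gt).upper().replace("|", "/")
    alleles = s.split("/") if "/" in s else list(s)
    if len(alleles) != 2:
        raise InvalidGenotypeError(f"genotype {gt!r} is not biallelic")
    if any(a in {".", "N"} for a in alleles):
        return None
    if not all(a in _VALID for a in alleles):
        raise InvalidGenotypeError(f"genotype {gt!r} contains non-base symbols")
    return tuple(sorted(alleles))  # type: ignore[return-value]


def classify_substitution(parent_genotype, child_genotype) -> str | None:
    """Six-class label for a parent->child genotype change, or None.

    Returns None when the genotypes are equal, either is a no-call, the
    parent is heterozygous (a het change is ambiguous between mutation and
    loss of heterozygosity), or the child carries two different new alleles.
    Otherwise the class is ``<parent allele>-to-<new allele>``,
    reverse-complemented when the parent allele is a purine so that the
    reference base of every class is a pyrimidine.
    """
    parent = _parse_genotype(parent_genotype)
    child = _parse_genotype(child_genotype)
    if parent is None or child is None or parent == child:
        return None
    if parent[0] != parent[1]:
        return None  # heterozygous parent: excluded from calling
    ref = parent[0]
    new = [a for a in child if a != ref]
    if not new or len(set(new)) > 1:
        # child hom-ref duplicate is impossible here (child != parent);
        # two distinct new alleles is an ambiguous double change
        return None
    alt = new[0]
    if ref in "AG":  # collapse to the pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def filter_probes(table: pd.DataFrame, threshold: float = DEFAULT_GENCALL_MIN) -> pd.DataFrame:
    """Drop probes whose GenCall score falls below ``threshold``.

    Scores exactly equal to the threshold are retained (the discard rule is
    "below threshold"). The number of discarded probes is logged.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    keep = table["gencall"] >= threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("filter_probes: discarded %d/%d probes below GenCall %.3f",
                 n_dropped, len(table), threshold)
    return table[keep].reset_index(drop=True)


def call_array_mutations(
    parent: pd.DataFrame,
    child: pd.DataFrame,
    threshold: float = DEFAULT_GENCALL_MIN,
) -> tuple[pd.DataFrame, pd.Series]:
    """Call substitutions probe-wise between two genotype tables.

    Both tables are GenCall-filtered; only probes passing in both clones
    are compared (probes present in one table only are dropped with a
    logged count). Returns the call table and a six-class histogram.
    """
    p = filter_probes(parent, threshold)
    c = filter_probes(child, threshold)
    merged = p.merge(c, on="probe_id", suffixes=("_parent", "_child"), how="inner")
    n_unshared = (len(p) - len(merged)) + (len(c) - len(merged))
    if n_unshared:
        log.info("call_array_mutations: %d probes not shared after filtering", n_unshared)
    if merged.empty and (len(parent) or len(child)):
        if not set(parent["probe_id"]) & set(child["probe_id"]):
            raise ValueError("no shared probes between parent and child tables")

    rows = []
    for row in merged.itertuples(index=False):
        cls = classify_substitution(row.genotype_parent, row.genotype_child)
        if cls is not None:
            rows.append({
                "probe_id": row.probe_id,
                "chrom": row.chrom_parent,
                "pos": row.pos_parent,
                "class": cls,
                "parent_genotype": row.genotype_parent,
                "child_genotype": row.genotype_child,
            })
    calls = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "class",
                                        "parent_genotype", "child_genotype"])
    hist = calls["class"].value_counts().reindex(CLASSES, fill_value=0).astype(int)
    hist.name = "count"
    return calls, hist
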