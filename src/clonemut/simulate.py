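"""Synthetic clone-lineage generator with planted mutational processes.

Emulates the study design the pipeline is built for: a mother -> daughter ->
granddaughter 293-like lineage in which case clones were pulsed with an
APOBEC3B-like deaminase and control clones carry only the cell line's
intrinsic mutator background. Two processes are planted with known ground
truth:

* an A3B-like process: C-to-T and C-to-G (minor C-to-A) at cytosines, with
  context probabilities concentrated on 5'TC motifs (TCA/TCG preferred,
  matching the enzyme's biochemical 5'TCR preference);
* an MMR-deficiency-like background: context-independent substitutions
  biased toward C-to-A / C-to-T / T-to-C, a replication-strand asymmetry of
  T-to-C events, and many 1-46 bp indels.

Case clones additionally receive copy-number alteration events at a rate
proportional to their A3B mutation load, and every planted SNV is assigned
the allele fraction 1/copy-number of its local ploidy segment (a fixed
heterozygous mutation is expected at 50% in diploid and 33% in triploid
regions of a clonal population).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .io import (
    write_bed,
    write_fasta,
    write_genotype_table,
    write_segments,
    write_vcf,
)
from .seqtools import (
    BASES,
    CLASSES,
    COMPLEMENT,
    CYTOSINE_CONTEXTS,
    cytosine_context_codes,
    encode,
    pyrimidine_sites,
)

log = logging.getLogger(__name__)

CONTIG = "chr1"

#: default A3B context weights: mass concentrated on the 5'TCR motifs
#: (TCA, TCG) the enzyme prefers biochemically, some on the other TCN
#: contexts, a small spread over non-TC contexts.
DEFAULT_A3B_MOTIF_WEIGHTS = {
    "TCA": 0.35, "TCG": 0.35, "TCT": 0.15, "TCC": 0.10,
    **{c: 0.05 / 12 for c in CYTOSINE_CONTEXTS if not c.startswith("T")},
}

#: default background class weights, qualitatively matching an MMR-deficient
#: spectrum (predominantly C-to-T, C-to-A and T-to-C).
DEFAULT_BACKGROUND_CLASS_WEIGHTS = {
    "C>T": 0.42, "C>A": 0.30, "T>C": 0.14, "C>G": 0.06, "T>A": 0.04, "T>G": 0.04,
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the lineage simulator.

    Counts are expected values per clone; per-clone realized counts are
    Poisson draws so clones vary the way real granddaughter clones do.
    """

    seed: int = 1
    genome_length: int = 200_000
    gc_fraction: float = 0.41
    n_case_clones: int = 3
    n_control_clones: int = 3
    #: expected A3B SNVs per case clone; with the default background this
    #: plants an expected 3.4-fold case excess of cytosine mutations
    a3b_snv_count: int = 2250
    background_snv_count: int = 1200
    a3b_motif_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_A3B_MOTIF_WEIGHTS))
    #: P(C-to-T), P(C-to-G), P(C-to-A) given an A3B deamination event
    a3b_ct_cg_t_ratio: tuple[float, float, float] = (0.6, 0.3, 0.1)
    background_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_CLASS_WEIGHTS))
    indel_count: int = 500
    indel_length_range: tuple[int, int] = (1, 46)
    #: leading/lagging rate ratio of background T-to-C events
    tC_asymmetry: float = 3.0
    #: list of (start, end, copy_number), 0-based half-open; None -> a
    #: mostly-diploid genome with a triploid middle third
    ploidy_segments: list[tuple[int, int, int]] | None = None
    #: expected CNA events per planted A3B SNV
    cna_per_a3b_event: float = 0.02
    n_probes: int = 4000
    strand_block_size: int = 20_000

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        lo, hi = self.indel_length_range
        if not (1 <= lo <= hi <= 46):
            raise ValueError("indel_length_range must lie within [1, 46]")
        for name, weights in (("a3b_motif_weights", self.a3b_motif_weights),
                              ("background_class_weights", self.background_class_weights)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} has negative weights")
        if abs(sum(self.a3b_ct_cg_t_ratio) - 1.0) > 1e-9:
            raise ValueError("a3b_ct_cg_t_ratio must sum to 1")
        for count in (self.a3b_snv_count, self.background_snv_count, self.indel_count,
                      self.n_case_clones, self.n_control_clones):
            if count < 0:
                raise ValueError("counts must be >= 0")
        if self.ploidy_segments is None:
            third = self.genome_length // 3
            self.ploidy_segments = [
                (0, third, 2),
                (third, 2 * third, 3),
                (2 * third, self.genome_length, 2),
            ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["a3b_ct_cg_t_ratio"] = list(self.a3b_ct_cg_t_ratio)
        d["indel_length_range"] = list(self.indel_length_range)
        d["ploidy_segments"] = [list(s) for s in self.ploidy_segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "a3b_ct_cg_t_ratio" in d:
            d["a3b_ct_cg_t_ratio"] = tuple(d["a3b_ct_cg_t_ratio"])
        if "indel_length_range" in d:
            d["indel_length_range"] = tuple(d["indel_length_range"])
        if d.get("ploidy_segments") is not None:
            d["ploidy_segments"] = [tuple(s) for s in d["ploidy_segments"]]
        return cls(**d)


@dataclass
class TruthSet:
    """Ground truth for one simulated lineage (in memory + on disk)."""

    config: SimulationConfig
    reference: str
    reference_path: Path
    strand_bed_path: Path
    catalogs: dict[str, MutationCatalog]
    segments: dict[str, pd.DataFrame]
    genotype_parents: dict[str, pd.DataFrame]
    genotype_children: dict[str, pd.DataFrame]
    clone_roles: dict[str, str]  # clone -> "case" | "control"
    cna_event_counts: dict[str, int]
    paths: dict[str, dict[str, Path]]

    @property
    def case_clones(self) -> list[str]:
        return [c for c, r in self.clone_roles.items() if r == "case"]

    @property
    def control_clones(self) -> list[str]:
        return [c for c, r in self.clone_roles.items() if r == "control"]


# ---------------------------------------------------------------- reference

def generate_reference(length: int, gc_fraction: float, seed: int) -> str:
    """Draw an i.i.d. reference sequence with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[c] for c in codes)


def strand_blocks(genome_length: int, block_size: int) -> pd.DataFrame:
    """Alternating leading/lagging replication-template blocks as a BED frame."""
    rows = []
    for i, start in enumerate(range(0, genome_length, block_size)):
        end = min(start + block_size, genome_length)
        rows.append((CONTIG, start, end, "leading" if i % 2 == 0 else "lagging"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _copy_number_at(positions: np.ndarray, ploidy_segments) -> np.ndarray:
    starts = np.array([s for s, _, _ in ploidy_segments])
    cns = np.array([cn for _, _, cn in ploidy_segments])
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = np.clip(idx, 0, len(cns) - 1)
    return cns[idx]


# ---------------------------------------------------------------- processes

def plant_a3b_process(
    reference: str,
    config: SimulationConfig,
    seed: int | None = None,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    exclude: set[int] | None = None,
) -> MutationCatalog:
    """Plant A3B-like deamination SNVs at cytosines (either strand).

    Contexts are drawn from ``config.a3b_motif_weights`` (pyrimidine
    normalized), outcomes from ``config.a3b_ct_cg_t_ratio``. Positions with
    positive weight but no matching site in the reference trigger a warning
    and renormalization over the contexts that are present.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = config.a3b_snv_count if n is None else n
    exclude = exclude if exclude is not None else set()

    pos, ctx_codes = cytosine_context_codes(reference)
    available = {}
    for i, ctx in enumerate(CYTOSINE_CONTEXTS):
        sites = pos[ctx_codes == i]
        sites = sites[~np.isin(sites, list(exclude))] if exclude else sites
        available[ctx] = sites

    weights = {c: w for c, w in config.a3b_motif_weights.items() if w > 0}
    absent = [c for c in weights if len(available.get(c, ())) == 0]
    if absent:
        warnings.warn(
            f"A3B contexts absent from reference, renormalizing: {absent}",
            stacklevel=2,
        )
        weights = {c: w for c, w in weights.items() if c not in absent}
        if not weights:
            raise ValueError("no weighted A3B context present in the reference")
    ctxs = list(weights)
    probs = np.array([weights[c] for c in ctxs])
    probs = probs / probs.sum()

    drawn = rng.multinomial(n, probs)
    codes = encode(reference)
    records = []
    for ctx, k in zip(ctxs, drawn):
        sites = available[ctx]
        if k > len(sites):
            raise ValueError(
                f"requested {k} A3B events in context {ctx} but only "
                f"{len(sites)} sites are available"
            )
        chosen = rng.choice(sites, size=k, replace=False)
        outcomes = rng.choice(3, size=k, p=np.asarray(config.a3b_ct_cg_t_ratio))
        for p0, out in zip(chosen, outcomes):
            pyr_alt = "TGA"[out]  # C-to-T, C-to-G, C-to-A
            if reference[p0] == "C":
                ref_b, alt_b = "C", pyr_alt
            else:  # G site: event on the opposite strand
                ref_b, alt_b = "G", COMPLEMENT[pyr_alt]
            records.append({"chrom": CONTIG, "pos": int(p0) + 1, "ref": ref_b,
                            "alt": alt_b, "kind": "snv", "process": "a3b"})
    cn = _copy_number_at(np.array([r["pos"] - 1 for r in records], dtype=int),
                         config.ploidy_segments) if records else np.array([])
    for rec, c in zip(records, cn):
        rec["af"] = 1.0 / int(c)
    return MutationCatalog.from_records("a3b", records)


def plant_background_process(
    reference: str,
    config: SimulationConfig,
    seed: int | None = None,
    n: int | None = None,
    n_indels: int | None = None,
    rng: np.random.Generator | None = None,
    exclude: set[int] | None = None,
) -> MutationCatalog:
    """Plant the MMR-deficiency-like background: biased SNVs + 1-46 bp indels.

    SNV classes are drawn context-independently from
    ``config.background_class_weights``; T-to-C events are placed on
    leading vs lagging replication blocks with rate ratio
    ``config.tC_asymmetry``; indel lengths are uniform on
    ``config.indel_length_range``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = config.background_snv_count if n is None else n
    n_indels = config.indel_count if n_indels is None else n_indels
    exclude = set(exclude) if exclude is not None else set()

    L = len(reference)
    block = config.strand_block_size
    c_sites = pyrimidine_sites(reference, "C")
    t_sites = pyrimidine_sites(reference, "T")
    if exclude:
        excl = np.array(sorted(exclude), dtype=int)
        c_sites = c_sites[~np.isin(c_sites, excl)]
        t_sites = t_sites[~np.isin(t_sites, excl)]
    leading_mask = (t_sites // block) % 2 == 0
    t_leading = t_sites[leading_mask]
    t_lagging = t_sites[~leading_mask]

    classes = list(config.background_class_weights)
    probs = np.array([config.background_class_weights[c] for c in classes])
    drawn = rng.multinomial(n, probs / probs.sum())

    used: set[int] = set()

    def _pick(sites: np.ndarray, k: int) -> np.ndarray:
        sites = sites[~np.isin(sites, list(used))] if used else sites
        if k > len(sites):
            raise ValueError("not enough sites for requested background events")
        return rng.choice(sites, size=k, replace=False)

    records = []
    r = config.tC_asymmetry
    p_leading = r / (1.0 + r)
    for cls, k in zip(classes, drawn):
        pyr_ref, pyr_alt = cls[0], cls[2]
        if cls == "T>C":
            n_lead = rng.binomial(k, p_leading)
            chosen = np.concatenate([_pick_tc(t_leading, n_lead, used, rng),
                                     _pick_tc(t_lagging, k - n_lead, used, rng)])
        else:
            chosen = _pick(c_sites if pyr_ref == "C" else t_sites, k)
        for p0 in chosen:
            used.add(int(p0))
            if reference[p0] == pyr_ref:
                ref_b, alt_b = pyr_ref, pyr_alt
            else:
                ref_b, alt_b = COMPLEMENT[pyr_ref], COMPLEMENT[pyr_alt]
            records.append({"chrom": CONTIG, "pos": int(p0) + 1, "ref": ref_b,
                            "alt": alt_b, "kind": "snv", "process": "background"})

    lo, hi = config.indel_length_range
    for _ in range(n_indels):
        length = int(rng.integers(lo, hi + 1))
        is_del = bool(rng.integers(2))
        for _attempt in range(100):
            p0 = int(rng.integers(1, L - hi - 2))
            if p0 not in used:
                break
        used.add(p0)
        anchor = reference[p0]
        if is_del:
            ref_b = reference[p0 : p0 + length + 1]
            alt_b = anchor
        else:
            ins = "".join(BASES[c] for c in rng.integers(0, 4, size=length))
            ref_b = anchor
            alt_b = anchor + ins
        records.append({"chrom": CONTIG, "pos": p0 + 1, "ref": ref_b,
                        "alt": alt_b, "kind": "indel", "process": "background"})

    snv_pos = np.array([rec["pos"] - 1 for rec in records], dtype=int)
    cn = _copy_number_at(snv_pos, config.ploidy_segments) if records else np.array([])
    for rec, c in zip(records, cn):
        rec["af"] = 1.0 / int(c)
    return MutationCatalog.from_records("background", records)


def _pick_tc(sites: np.ndarray, k: int, used: set[int], rng: np.random.Generator) -> np.ndarray:
    sites = sites[~np.isin(sites, list(used))] if used else sites
    if k > len(sites):
        raise ValueError("not enough T sites on the requested strand class")
    chosen = rng.choice(sites, size=k, replace=False)
    used.update(int(p) for p in chosen)
    return chosen


# ---------------------------------------------------------------- CNA events

def apply_cna_events(
    baseline: list[tuple[int, int, int]],
    n_events: int,
    rng: np.random.Generator,
    genome_length: int,
    min_len: int = 500,
) -> tuple[pd.DataFrame, int]:
    """Apply ``n_events`` single-copy gain/loss events to a baseline ploidy.

    Each event adds or subtracts one copy over a random interval (copy
    number floored at 1 so control-side CN-0 exclusions stay a control
    property). Returns the resulting non-overlapping segment table and the
    number of events actually applied.
    """
    # breakpoint representation: CN delta per position via an event list
    events = []
    for _ in range(n_events):
        length = int(rng.integers(min_len, max(min_len + 1, genome_length // 20)))
        start = int(rng.integers(0, genome_length - length))
        delta = 1 if rng.integers(2) else -1
        events.append((start, start + length, delta))

    points = sorted({0, genome_length,
                     *[s for s, _, _ in baseline], *[e for _, e, _ in baseline],
                     *[s for s, _, _ in events], *[e for _, e, _ in events]})
    rows = []
    for a, b in zip(points[:-1], points[1:]):
        cn = next(c for s, e, c in baseline if s <= a < e)
        for s, e, d in events:
            if s <= a < e:
                cn += d
        rows.append((CONTIG, a, b, max(cn, 1)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number"])
    # merge adjacent equal-CN runs
    keep = [0] + [i for i in range(1, len(df)) if df.copy_number.iloc[i] != df.copy_number.iloc[i - 1]]
    merged = df.iloc[keep].copy()
    ends = list(merged["start"].iloc[1:]) + [genome_length]
    merged["end"] = ends
    return merged.reset_index(drop=True), len(events)


# ---------------------------------------------------------------- lineage

def _clone_seed(base_seed: int, index: int) -> int:
    # fixed offsets so adding clones never reshuffles earlier clones
    return (base_seed * 1009 + 101 * index + 17) % (2**31 - 1)


def emit_lineage(config: SimulationConfig, outdir: str | Path) -> TruthSet:
    """Simulate the full mother->daughter->granddaughter cohort to ``outdir``.

    Writes reference.fa, strands.bed and, per clone: a truth VCF, parent and
    child genotype TSVs, and a segment TSV. Control clones carry only the
    background process; case clones add the A3B process and CNA events at an
    expected rate of ``cna_per_a3b_event`` per planted A3B SNV.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    reference = generate_reference(config.genome_length, config.gc_fraction, config.seed)
    ref_path = outdir / "reference.fa"
    write_fasta(ref_path, CONTIG, reference)
    strands = strand_blocks(config.genome_length, config.strand_block_size)
    strands_path = outdir / "strands.bed"
    write_bed(strands, strands_path)

    baseline = [(s, e, c) for s, e, c in config.ploidy_segments]
    baseline_df = pd.DataFrame(
        [(CONTIG, s, e, c) for s, e, c in baseline],
        columns=["chrom", "start", "end", "copy_number"],
    )

    clones = [(f"CG{i+1}", "control") for i in range(config.n_control_clones)]
    clones += [(f"CA{i+1}", "case") for i in range(config.n_case_clones)]

    catalogs: dict[str, MutationCatalog] = {}
    segments: dict[str, pd.DataFrame] = {}
    cna_counts: dict[str, int] = {}
    roles: dict[str, str] = {}

    for idx, (name, role) in enumerate(clones):
        rng = np.random.default_rng(_clone_seed(config.seed, idx))
        n_bg = rng.poisson(config.background_snv_count)
        n_ind = rng.poisson(config.indel_count)
        bg = plant_background_process(reference, config, n=n_bg, n_indels=n_ind, rng=rng)
        used = set(bg.df["pos"].to_numpy() - 1)
        cat = MutationCatalog(name, bg.df)
        n_a3b = 0
        if role == "case":
            n_a3b = rng.poisson(config.a3b_snv_count)
            a3b = plant_a3b_process(reference, config, n=n_a3b, rng=rng, exclude=used)
            cat = cat.concat(MutationCatalog(name, a3b.df))
            cat.sample = name
        catalogs[name] = MutationCatalog(name, cat.df)
        roles[name] = role

        if role == "case":
            n_cna = rng.poisson(config.cna_per_a3b_event * n_a3b)
            seg, applied = apply_cna_events(baseline, n_cna, rng, config.genome_length)
            segments[name] = seg
            cna_counts[name] = applied
        else:
            segments[name] = baseline_df.copy()
            cna_counts[name] = 0

    genotype_parents, genotype_children = _genotype_tables(
        reference, config, catalogs, roles)

    contigs = {CONTIG: config.genome_length}
    paths: dict[str, dict[str, Path]] = {}
    clonedir = outdir / "clones"
    clonedir.mkdir(exist_ok=True)
    for name in catalogs:
        p = {
            "vcf": clonedir / f"{name}.truth.vcf",
            "genotype_parent": clonedir / f"{name}.genotype_parent.tsv",
            "genotype_child": clonedir / f"{name}.genotype_child.tsv",
            "segments": clonedir / f"{name}.segments.tsv",
        }
        write_vcf(catalogs[name], p["vcf"], contigs)
        write_genotype_table(genotype_parents[name], p["genotype_parent"])
        write_genotype_table(genotype_children[name], p["genotype_child"])
        write_segments(segments[name], p["segments"])
        paths[name] = p

    summary = {
        "config": config.to_dict(),
        "clones": {
            name: {
                "role": roles[name],
                "n_snv": int(len(catalogs[name].snvs)),
                "n_indel": int(len(catalogs[name].indels)),
                "n_a3b": int((catalogs[name].df["process"] == "a3b").sum()),
                "cna_events": cna_counts[name],
            }
            for name in catalogs
        },
    }
    (outdir / "truth_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return TruthSet(
        config=config, reference=reference, reference_path=ref_path,
        strand_bed_path=strands_path, catalogs=catalogs, segments=segments,
        genotype_parents=genotype_parents, genotype_children=genotype_children,
        clone_roles=roles, cna_event_counts=cna_counts, paths=paths,
    )


def _genotype_tables(reference, config, catalogs, roles):
    """Array genotype tables: shared probe grid + probes at truth SNVs.

    The probe universe is a fixed random grid plus a probe at every truth
    SNV position (a simulator convenience so array recovery is testable at
    desk scale). Parent (daughter) tables are homozygous-reference except
    for a shared set of germline heterozygous probes; child (granddaughter)
    tables flip the clone's own truth SNVs to heterozygous ref/alt.
    """
    rng = np.random.default_rng(_clone_seed(config.seed, 10_000))
    L = len(reference)
    truth_pos = sorted({int(p) for cat in catalogs.values()
                        for p in cat.snvs["pos"]})
    grid = rng.choice(np.arange(2, L), size=min(config.n_probes, L - 4), replace=False)
    all_pos = np.array(sorted(set(grid.tolist()) | set(truth_pos)))
    probe_ids = [f"probe{i:06d}" for i in range(len(all_pos))]

    truth_set = set(truth_pos)
    # germline het probes: non-truth positions only
    non_truth = np.array([p for p in all_pos if p not in truth_set])
    n_het = int(0.08 * len(all_pos))
    het_pos = set(rng.choice(non_truth, size=min(n_het, len(non_truth)), replace=False).tolist())

    alt_by_pos: dict[int, str] = {}
    for cat in catalogs.values():
        for row in cat.snvs.itertuples(index=False):
            alt_by_pos.setdefault(int(row.pos), row.alt)

    base_rows = []
    for pid, pos in zip(probe_ids, all_pos):
        ref_b = reference[pos - 1]
        if pos in alt_by_pos:
            other = alt_by_pos[pos]
        else:
            other = rng.choice([b for b in BASES if b != ref_b])
        if pos in het_pos:
            parent_gt = "/".join(sorted((ref_b, other)))
        else:
            parent_gt = f"{ref_b}/{ref_b}"
        base_rows.append((pid, CONTIG, int(pos), ref_b, other, parent_gt))
    base = pd.DataFrame(base_rows, columns=["probe_id", "chrom", "pos",
                                            "allele_a", "allele_b", "parent_gt"])

    parents, children = {}, {}
    for idx, name in enumerate(catalogs):
        crng = np.random.default_rng(_clone_seed(config.seed, 20_000 + idx))
        n = len(base)
        gencall_p = np.where(crng.random(n) < 0.02,
                             crng.uniform(0.0, 0.149, n), crng.uniform(0.2, 1.0, n))
        gencall_c = np.where(crng.random(n) < 0.02,
                             crng.uniform(0.0, 0.149, n), crng.uniform(0.2, 1.0, n))
        clone_muts = {int(r.pos): r.alt for r in catalogs[name].snvs.itertuples(index=False)}
        child_gt = []
        for row in base.itertuples(index=False):
            if row.pos in clone_muts and row.parent_gt == f"{row.allele_a}/{row.allele_a}":
                child_gt.append("/".join(sorted((row.allele_a, clone_muts[row.pos]))))
            else:
                child_gt.append(row.parent_gt)
        parent = base.rename(columns={"parent_gt": "genotype"}).copy()
        parent["gencall"] = np.round(gencall_p, 4)
        child = base.drop(columns="parent_gt").copy()
        child["genotype"] = child_gt
        child["gencall"] = np.round(gencall_c, 4)
        parents[name] = parent[["probe_id", "chrom", "pos", "allele_a", "allele_b",
                                "genotype", "gencall"]]
        children[name] = child[["probe_id", "chrom", "pos", "allele_a", "allele_b",
                                "genotype", "gencall"]]
    return parents, children


# ------------------------------------------------- simulated caller outputs

def simulate_caller_outputs(
    catalog: MutationCatalog,
    reference_length: int,
    seed: int,
    dropout: float = 0.05,
    n_false_positives: int = 40,
):
    """Emulate two variant callers run on one clone.

    Each caller reports the truth catalog minus an independent random
    dropout, plus its own private false positives at positions absent from
    the truth — so intersecting the two callers removes every
    single-caller false positive while the union of per-normal runs
    recovers dropout losses.
    Returns ``(calls_a, calls_b)`` as :class:`~clonemut.consensus.CallSet`.
    """
    from .consensus import CallSet

    rng = np.random.default_rng(seed)
    truth_pos = set(int(p) for p in catalog.df["pos"])
    fp_used: set[int] = set()  # caller-private FPs never collide across callers

    def one(caller: str) -> CallSet:
        keep = rng.random(len(catalog.df)) >= dropout
        df = catalog.df[keep].copy()
        fp_rows = []
        while len(fp_rows) < n_false_positives:
            pos = int(rng.integers(2, reference_length - 1))
            if pos in truth_pos or pos in fp_used:
                continue
            fp_used.add(pos)
            ref = rng.choice(list(BASES))
            alt = rng.choice([b for b in BASES if b != ref])
            fp_rows.append({"chrom": CONTIG, "pos": pos, "ref": ref, "alt": alt,
                            "af": float(rng.uniform(0.05, 0.5)), "kind": "snv",
                            "process": "false_positive"})
        df = pd.concat([df, pd.DataFrame(fp_rows)], ignore_index=True)
        df = df.drop_duplicates(["chrom", "pos", "ref", "alt"])
        df = df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        return CallSet(sample=catalog.sample, normal="sim_normal", caller=caller,
                       df=df.reset_index(drop=True))

    return one("callerA"), one("callerB")


def digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
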