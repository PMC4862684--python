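"""Consensus somatic-call filtering.

Reduces per-sample caller outputs to one high-confidence somatic catalog
with three rules: keep only variants detected by both callers; merge calls
made against multiple "normal" genomes (union) to recover coverage-specific
dropouts; then remove variants with allele fraction above 0.5 (a fixed
clonal mutation cannot exceed the heterozygous fraction) or falling inside
user-supplied masks of repetitive or systematically misaligned regions.
Indels flow through the same rules, matched exactly on
(chrom, pos, ref, alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .catalog import MutationCatalog
from .io import read_bed

log = logging.getLogger(__name__)

KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class CallSet:
    """One caller's somatic calls for one sample against one normal."""

    sample: str
    normal: str
    caller: str
    df: pd.DataFrame  # columns: chrom, pos (1-based), ref, alt, af [, ...]

    def __post_init__(self) -> None:
        if self.df.duplicated(KEY).any():
            raise ValueError("duplicate (chrom, pos, ref, alt) records in call set")
        if "af" in self.df.columns:
            af = self.df["af"].dropna()
            if ((af < 0) | (af > 1)).any():
                raise ValueError("allele fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class FilterConfig:
    """Exclusion rules applied after consensus and merging."""

    af_max: float = 0.5
    region_masks: list[pd.DataFrame] = field(default_factory=list)

    @classmethod
    def from_bed_paths(cls, paths: list[str | Path], af_max: float = 0.5) -> "FilterConfig":
        return cls(af_max=af_max, region_masks=[read_bed(p) for p in paths])


def intersect_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Variants reported by both callers; allele fractions taken from `a`."""
    if a.sample != b.sample:
        raise ValueError(f"cannot intersect call sets of different samples "
                         f"({a.sample!r} vs {b.sample!r})")
    keys_b = set(map(tuple, b.df[KEY].itertuples(index=False, name=None)))
    mask = [tuple(k) in keys_b for k in a.df[KEY].itertuples(index=False, name=None)]
    out = a.df[mask].reset_index(drop=True)
    log.info("intersect: %d & %d -> %d records", len(a), len(b), len(out))
    return CallSet(a.sample, a.normal, f"{a.caller}&{b.caller}", out)


def merge_against_normals(callsets: list[CallSet]) -> CallSet:
    """Union of one sample's calls made against different normals.

    De-duplicated on (chrom, pos, ref, alt); the first occurrence wins for
    auxiliary columns such as the allele fraction.
    """
    if not callsets:
        raise ValueError("merge_against_normals requires at least one call set")
    samples = {cs.sample for cs in callsets}
    if len(samples) > 1:
        raise ValueError(f"call sets belong to different samples: {sorted(samples)}")
    df = pd.concat([cs.df for cs in callsets], ignore_index=True)
    df = df.drop_duplicates(KEY).sort_values(KEY, kind="mergesort").reset_index(drop=True)
    normals = "+".join(dict.fromkeys(cs.normal for cs in callsets))
    return CallSet(callsets[0].sample, normals, callsets[0].caller, df)


def _mask_trees(masks: list[pd.DataFrame]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for mask in masks:
        for row in mask.itertuples(index=False):
            if row.end > row.start:
                trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def apply_filters(cs: CallSet, cfg: FilterConfig) -> CallSet:
    """Remove high-AF variants and variants inside masked regions.

    The AF rule is strict: fraction > ``af_max`` removed, == retained.
    Records with a missing allele fraction are retained and logged. Mask
    membership converts the 1-based variant position to the masks'
    0-based half-open coordinates (pos-1 tested against [start, end)).
    """
    trees = _mask_trees(cfg.region_masks)
    df = cs.df
    missing_af = df["af"].isna() if "af" in df.columns else pd.Series(False, index=df.index)
    if missing_af.any():
        log.info("apply_filters: %d records with missing AF retained", int(missing_af.sum()))
    af_keep = missing_af | (df["af"] <= cfg.af_max)
    in_mask = pd.Series(
        [bool(trees.get(c, IntervalTree())[p - 1]) for c, p in zip(df["chrom"], df["pos"])],
        index=df.index,
    )
    removed_af = int((~af_keep).sum())
    removed_mask = int((af_keep & in_mask).sum())
    log.info("apply_filters: removed %d by AF > %.3g, %d by region masks",
             removed_af, cfg.af_max, removed_mask)
    out = df[af_keep & ~in_mask].reset_index(drop=True)
    return CallSet(cs.sample, cs.normal, cs.caller, out)


def consensus_pipeline(
    caller_a: list[CallSet],
    caller_b: list[CallSet],
    cfg: FilterConfig,
) -> MutationCatalog:
    """intersect (per normal) -> merge across normals -> filter.

    ``caller_a[i]`` and ``caller_b[i]`` must be the two callers' outputs
    against the same normal.
    """
    if len(caller_a) != len(caller_b):
        raise ValueError("caller_a and caller_b must pair up per normal")
    merged = merge_against_normals(
        [intersect_callsets(a, b) for a, b in zip(caller_a, caller_b)])
    filtered = apply_filters(merged, cfg)
    return MutationCatalog(filtered.sample, filtered.df.copy())
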