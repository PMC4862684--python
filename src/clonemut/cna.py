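"""Copy-number-aberration differencing and replication-strand asymmetry.

CNA burden of a case clone is counted against control clones on a shared
segment grid: grid segments where the controls disagree with each other, or
where any control has copy number 0, are excluded; elsewhere the case-minus-
control delta is binned into gains (delta > 0) and losses (delta < 0).
Strand asymmetry assigns each strand-collapsed SNV to a leading or lagging
replication-template block and reports per-class log2(leading/lagging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import MutationCatalog
from .seqtools import CLASSES, COMPLEMENT


@dataclass
class CnaResult:
    gains: int
    losses: int
    deltas: pd.DataFrame  # per grid segment: chrom,start,end,case_cn,control_cn,delta,status


def _breakpoints(tables: list[pd.DataFrame], chrom: str) -> np.ndarray:
    pts = set()
    for t in tables:
        sub = t[t["chrom"] == chrom]
        pts.update(sub["start"].tolist())
        pts.update(sub["end"].tolist())
    return np.array(sorted(pts))


def _cn_at(table: pd.DataFrame, chrom: str, start: int, end: int):
    sub = table[(table["chrom"] == chrom) & (table["start"] <= start) & (table["end"] >= end)]
    if sub.empty:
        return None
    return int(sub["copy_number"].iloc[0])


def diff_cna(
    case: pd.DataFrame,
    controls: list[pd.DataFrame],
    mode: str = "strict",
) -> CnaResult:
    """Count case gains/losses relative to control clones.

    ``mode="strict"`` (default): exclude grid segments where the controls
    are not identical to each other or any control CN is 0.
    ``mode="case_vs_consensus"``: the alternative reading — only CN-0
    control segments are excluded; control disagreement is resolved by the
    per-segment control median.
    Segments not covered by every table are reported with status
    ``outside`` and never counted.
    """
    if mode not in {"strict", "case_vs_consensus"}:
        raise ValueError("mode must be 'strict' or 'case_vs_consensus'")
    if not controls:
        raise ValueError("at least one control segment table is required")
    tables = [case, *controls]
    chroms = sorted(set().union(*[set(t["chrom"]) for t in tables]))
    rows = []
    for chrom in chroms:
        pts = _breakpoints(tables, chrom)
        for a, b in zip(pts[:-1], pts[1:]):
            case_cn = _cn_at(case, chrom, a, b)
            ctrl_cns = [_cn_at(c, chrom, a, b) for c in controls]
            if case_cn is None or any(c is None for c in ctrl_cns):
                rows.append((chrom, a, b, case_cn, None, None, "outside"))
                continue
            if any(c == 0 for c in ctrl_cns):
                rows.append((chrom, a, b, case_cn, None, None, "excluded_cn0"))
                continue
            if mode == "strict" and len(set(ctrl_cns)) > 1:
                rows.append((chrom, a, b, case_cn, None, None, "excluded_disagreement"))
                continue
            ctrl = int(np.median(ctrl_cns)) if mode == "case_vs_consensus" else ctrl_cns[0]
            delta = case_cn - ctrl
            rows.append((chrom, a, b, case_cn, ctrl, delta, "included"))
    deltas = pd.DataFrame(rows, columns=["chrom", "start", "end", "case_cn",
                                         "control_cn", "delta", "status"])
    if deltas[deltas["status"] != "outside"].empty:
        raise ValueError("empty shared segment grid between case and controls")
    included = deltas[deltas["status"] == "included"]
    gains = int((included["delta"] > 0).sum())
    losses = int((included["delta"] < 0).sum())
    return CnaResult(gains=gains, losses=losses, deltas=deltas)


def cna_mutation_correlation(cna_counts, mutation_counts) -> tuple[float, float, float]:
    """OLS best-fit line and Pearson r of CNA burden vs mutation burden.

    Returns ``(slope, intercept, r)``. Requires >= 3 clones; zero variance
    in the mutation counts (x) leaves the fit undefined; constant CNA
    counts (y) give slope 0 and r 0.
    """
    x = np.asarray(mutation_counts, dtype=float)
    y = np.asarray(cna_counts, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need matched counts for >= 3 clones")
    if np.var(x) == 0:
        raise ValueError("undefined fit: zero variance in mutation counts")
    if np.var(y) == 0:
        return 0.0, float(np.mean(y)), 0.0
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


@dataclass
class AsymmetryResult:
    per_class: pd.DataFrame  # class x (leading, lagging, log2_ratio)
    outside: int             # mutations outside annotated blocks


def strand_asymmetry(
    catalog: MutationCatalog,
    strand_blocks: pd.DataFrame,
) -> AsymmetryResult:
    """Per-class leading/lagging counts and log2 ratios.

    ``strand_blocks`` is a BED-style frame (chrom, start, end, name) whose
    name column is ``leading`` or ``lagging``. Each SNV is pyrimidine-
    normalized for its class label and assigned by position to its block;
    log2(leading/lagging) uses a Haldane 0.5 correction when either count
    is 0. Mutations outside annotated blocks are tallied separately.
    """
    bad = set(strand_blocks["name"]) - {"leading", "lagging"}
    if bad:
        raise ValueError(f"strand annotation names must be leading/lagging, got {sorted(bad)}")
    blocks: dict[str, list[tuple[int, int, str]]] = {}
    for row in strand_blocks.itertuples(index=False):
        blocks.setdefault(row.chrom, []).append((row.start, row.end, row.name))
    for chrom in blocks:
        blocks[chrom].sort()

    counts = pd.DataFrame(0, index=CLASSES, columns=["leading", "lagging"], dtype=int)
    outside = 0
    annotated = 0
    for row in catalog.snvs.itertuples(index=False):
        ref, alt = row.ref.upper(), row.alt.upper()
        if ref in "AG":
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        cls = f"{ref}>{alt}"
        pos0 = int(row.pos) - 1
        label = None
        for start, end, name in blocks.get(row.chrom, ()):
            if start <= pos0 < end:
                label = name
                break
        if label is None:
            outside += 1
            continue
        annotated += 1
        counts.loc[cls, label] += 1
    if annotated == 0:
        raise ValueError("strand annotation covers no mutation in the catalog")

    lead = counts["leading"].to_numpy(dtype=float)
    lag = counts["lagging"].to_numpy(dtype=float)
    corr = (lead == 0) | (lag == 0)
    log2_ratio = np.log2((lead + 0.5 * corr) / (lag + 0.5 * corr))
    per_class = counts.copy()
    per_class["log2_ratio"] = log2_ratio
    return AsymmetryResult(per_class=per_class, outside=outside)
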