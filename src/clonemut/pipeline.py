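"""End-to-end pipeline over a simulated (or user-supplied) clone cohort.

Runs simulate -> array calling -> consensus filtering -> spectrum ->
signature extraction -> motif enrichment -> CNA differencing and strand
asymmetry, and writes per-stage TSVs plus one machine-readable
``summary.json``. The summary is deterministic for a fixed seed (no
timestamps); provenance with digests and timestamps goes to
``manifest.json`` alongside it.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arraycall import call_array_mutations
from .catalog import MutationCatalog
from .cna import cna_mutation_correlation, diff_cna, strand_asymmetry
from .consensus import FilterConfig, consensus_pipeline
from .nsnmf import explained_variance, nsnmf_decompose, sample_contributions
from .simulate import SimulationConfig, TruthSet, digest, emit_lineage, simulate_caller_outputs
from .spectrum import (
    CYTOSINE_CLASSES,
    build_spectrum,
    context_counts,
    cytosine_view,
    spectrum_class_totals,
    write_spectrum,
)
from .stats import average_mutation_counts, motif_enrichment, tcw_transversion_test
from .seqtools import genomic_context_counts

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1
A3B_MOTIFS = ["TCA", "TCC", "TCG", "TCT"]


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    rank: int = 3,
    theta: float = 0.5,
    restarts: int = 5,
    plots: bool = False,
) -> dict:
    """Execute every stage on a freshly simulated lineage; return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    log.info("stage simulate: seed=%d", config.seed)
    truth = emit_lineage(config, outdir / "sim")
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "clones": {name: role for name, role in truth.clone_roles.items()},
    }

    summary["array"] = _stage_array(truth, outdir)
    catalogs = _stage_consensus(truth, outdir)
    spectrum96 = _stage_spectrum(catalogs, truth, outdir)
    summary["cytosine_mutations"] = _cytosine_counts(spectrum96, truth)
    summary["signatures"] = _stage_signatures(spectrum96, truth, rank, theta,
                                              restarts, config.seed, outdir)
    summary["enrichment"] = _stage_enrichment(spectrum96, truth)
    summary["cna"] = _stage_cna(truth, summary["cytosine_mutations"])
    summary["asymmetry"] = _stage_asymmetry(catalogs, truth)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "digests": {
            str(p.relative_to(outdir)): digest(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if plots:
        _stage_plots(spectrum96, outdir)
    return summary


# ---------------------------------------------------------------- stages

def _stage_array(truth: TruthSet, outdir: Path) -> dict:
    rows = {}
    for name in truth.catalogs:
        calls, hist = call_array_mutations(
            truth.genotype_parents[name], truth.genotype_children[name])
        calls.to_csv(outdir / f"array_calls.{name}.tsv", sep="\t", index=False)
        rows[name] = {cls: int(n) for cls, n in hist.items()}
        log.info("stage call-array: %s -> %d calls", name, len(calls))
    return rows


def _stage_consensus(truth: TruthSet, outdir: Path) -> dict[str, MutationCatalog]:
    cfg = FilterConfig(af_max=0.5, region_masks=[])
    catalogs = {}
    for i, name in enumerate(truth.catalogs):
        a, b = simulate_caller_outputs(
            truth.catalogs[name], truth.config.genome_length,
            seed=(truth.config.seed * 7919 + i) % (2**31 - 1))
        catalogs[name] = consensus_pipeline([a], [b], cfg)
        log.info("stage consensus: %s -> %d records", name, len(catalogs[name]))
    return catalogs


def _stage_spectrum(catalogs, truth: TruthSet, outdir: Path) -> pd.DataFrame:
    spectrum96 = build_spectrum(list(catalogs.values()), truth.reference)
    write_spectrum(spectrum96, outdir / "spectrum96.tsv")
    write_spectrum(cytosine_view(spectrum96), outdir / "spectrum48.tsv")
    return spectrum96


def _cytosine_counts(spectrum96: pd.DataFrame, truth: TruthSet) -> dict:
    totals = spectrum_class_totals(spectrum96)
    cyto = totals.loc[CYTOSINE_CLASSES].sum()
    per_clone = {name: int(cyto[name]) for name in cyto.index}
    case = [per_clone[c] for c in truth.case_clones]
    ctrl = [per_clone[c] for c in truth.control_clones]
    fold = float(np.mean(case) / np.mean(ctrl)) if ctrl and np.mean(ctrl) > 0 else float("nan")
    return {"per_clone": per_clone, "case_mean": float(np.mean(case)) if case else None,
            "control_mean": float(np.mean(ctrl)) if ctrl else None,
            "case_control_fold": fold}


def _stage_signatures(spectrum96, truth, rank, theta, restarts, seed, outdir) -> dict:
    model = nsnmf_decompose(spectrum96, rank=rank, theta=theta,
                            restarts=restarts, seed=seed)
    model.W.to_csv(outdir / "signatures_W.tsv", sep="\t")
    model.H.to_csv(outdir / "signatures_H.tsv", sep="\t")
    contrib = sample_contributions(model)
    contrib.to_csv(outdir / "signature_contributions.tsv", sep="\t")

    # the A3B-like signature is the one with the most 5'TC cytosine mass
    tc_mass = {
        sig: float(model.W.loc[[ch for ch in model.W.index
                                if ch[0] == "T" and "[C" in ch], sig].sum())
        for sig in model.W.columns
    }
    a3b_sig = max(tc_mass, key=tc_mass.get)
    case_contrib = float(contrib.loc[a3b_sig, truth.case_clones].mean()) \
        if truth.case_clones else None
    ctrl_contrib = float(contrib.loc[a3b_sig, truth.control_clones].mean()) \
        if truth.control_clones else None
    return {
        "rank": rank, "theta": theta,
        "explained_variance": explained_variance(model),
        "a3b_like_signature": a3b_sig,
        "tc_mass": tc_mass,
        "a3b_like_contribution_case_mean": case_contrib,
        "a3b_like_contribution_control_mean": ctrl_contrib,
        "contributions": {s: {k: float(v) for k, v in contrib[s].items()}
                          for s in contrib.columns},
    }


def _stage_enrichment(spectrum96, truth: TruthSet) -> dict:
    genomic = genomic_context_counts(truth.reference)
    cyto48 = cytosine_view(spectrum96)
    ctx_by_sample = {
        s: pd.Series(
            cyto48[s].groupby([ch[0] + "C" + ch[-1] for ch in cyto48.index]).sum())
        for s in cyto48.columns
    }
    out: dict = {}
    for role, clones in (("case", truth.case_clones), ("control", truth.control_clones)):
        if not clones:
            continue
        avg = average_mutation_counts([ctx_by_sample[c] for c in clones])
        out[role] = {}
        for motif in A3B_MOTIFS:
            test = motif_enrichment(avg, motif, genomic_counts=genomic)
            out[role][motif] = {"p": test.p_value, "odds_ratio": test.odds_ratio,
                                "fold_enrichment": test.fold_enrichment}
    # C-to-G in TCW vs other contexts, per-sample proportions
    cg = context_counts(spectrum96, "C>G")
    props = cg / cg.sum(axis=0).replace(0, np.nan)
    try:
        t, p = tcw_transversion_test(props)
        out["tcw_c_to_g"] = {"t": t, "p": p}
    except ValueError as exc:
        out["tcw_c_to_g"] = {"error": str(exc)}
    return out


def _stage_cna(truth: TruthSet, cytosine: dict) -> dict:
    controls = [truth.segments[c] for c in truth.control_clones]
    per_clone = {}
    for name in truth.catalogs:
        if truth.clone_roles[name] == "case":
            res = diff_cna(truth.segments[name], controls)
        else:
            others = [truth.segments[c] for c in truth.control_clones if c != name]
            res = diff_cna(truth.segments[name], others or controls)
        per_clone[name] = {"gains": res.gains, "losses": res.losses,
                           "total": res.gains + res.losses}
    out: dict = {"per_clone": per_clone}
    names = list(per_clone)
    if len(names) >= 3:
        muts = [cytosine["per_clone"][n] for n in names]
        cnas = [per_clone[n]["total"] for n in names]
        try:
            slope, intercept, r = cna_mutation_correlation(cnas, muts)
            out["correlation"] = {"slope": slope, "intercept": intercept, "pearson_r": r}
        except ValueError as exc:
            out["correlation"] = {"error": str(exc)}
    return out


def _stage_asymmetry(catalogs, truth: TruthSet) -> dict:
    from .io import read_bed

    blocks = read_bed(truth.strand_bed_path)
    out = {}
    for name, cat in catalogs.items():
        res = strand_asymmetry(cat, blocks)
        out[name] = {cls: {"leading": int(res.per_class.loc[cls, "leading"]),
                           "lagging": int(res.per_class.loc[cls, "lagging"]),
                           "log2_ratio": float(res.per_class.loc[cls, "log2_ratio"])}
                     for cls in res.per_class.index}
    return out


def _stage_plots(spectrum96: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(14, 4))
    spectrum96.plot.bar(ax=ax, width=0.8)
    ax.set_xlabel("channel")
    ax.set_ylabel("mutations")
    ax.tick_params(axis="x", labelsize=4)
    fig.tight_layout()
    fig.savefig(outdir / "spectrum96.png", dpi=150)
    plt.close(fig)
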