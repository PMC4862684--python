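"""Motif-enrichment and transversion-context statistics.

The headline questions these answer: are cytosine mutations concentrated in
the deaminase-preferred 5'TC trinucleotides (Fisher's exact test of mutated
cytosines vs genomic cytosine sites, in-motif vs out-of-motif), and are
C-to-G transversions specifically enriched in TCW contexts (W = A or T)
relative to the other trinucleotides (two-sample Student's t on per-sample
context proportions)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqtools import CYTOSINE_CONTEXTS, expand_iupac_motif, genomic_context_counts

TCW_CONTEXTS = ["TCA", "TCT"]


class UndefinedTestError(ValueError):
    pass


def _hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """Hypergeometric pmf over ``k`` via log-gamma (fast, vectorized)."""
    from scipy.special import gammaln

    def logc(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    logp = logc(c1, k) + logc(n - c1, r1 - k) - logc(n, r1)
    return np.exp(logp)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table.

    The p-value sums the hypergeometric probabilities (margins fixed) of
    every table whose probability does not exceed the observed table's
    (with a (1 + 1e-7) relative tolerance for floating-point ties). The
    odds ratio is the sample OR a*d / (b*c); when a cell is zero a
    Haldane-corrected OR (0.5 added to every cell) is returned instead so
    the value stays displayable.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        raise UndefinedTestError("a margin of the 2x2 table is zero")

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)

    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


@dataclass
class MotifTest:
    """Fisher motif-enrichment result for one cytosine-centered motif."""

    motif: str
    mutations_in_motif: int
    mutations_out_motif: int
    sites_in_motif: int
    sites_out_motif: int
    odds_ratio: float
    p_value: float
    fold_enrichment: float

    @property
    def table(self):
        return [[self.mutations_in_motif, self.mutations_out_motif],
                [self.sites_in_motif, self.sites_out_motif]]


def motif_enrichment(
    mutation_context_counts: pd.Series,
    motif: str,
    reference: str | None = None,
    genomic_counts: pd.Series | None = None,
    table: str = "genomic",
) -> MotifTest:
    """Test enrichment of cytosine mutations in a motif vs the genome.

    Parameters
    ----------
    mutation_context_counts:
        Integer counts of (cytosine-class) mutations per NCN context,
        indexed by the 16 contexts (e.g. from a 48-channel spectrum column
        summed over classes, or from a catalog tally).
    motif:
        A cytosine-centered triplet, IUPAC flanks allowed (TCG, TCW, NCG..).
    reference / genomic_counts:
        Genomic cytosine-site composition; give either the sequence or a
        precomputed per-context site count.
    table:
        ``"genomic"`` (default): mutated cytosines vs genomic cytosine
        sites, in-motif vs out. ``"expected"``: observed in/out mutation
        counts vs the counts expected if mutations followed the genomic
        context frequency.
    """
    if genomic_counts is None:
        if reference is None:
            raise ValueError("provide reference or genomic_counts")
        genomic_counts = genomic_context_counts(reference)
    genomic_counts = genomic_counts.reindex(CYTOSINE_CONTEXTS, fill_value=0)
    muts = mutation_context_counts.reindex(CYTOSINE_CONTEXTS, fill_value=0)

    members = expand_iupac_motif(motif)
    g_in = int(genomic_counts[members].sum())
    g_out = int(genomic_counts.sum()) - g_in
    if g_in == 0:
        raise UndefinedTestError(f"motif {motif} absent from the genome")
    m_in = int(muts[members].sum())
    m_out = int(muts.sum()) - m_in
    if m_in + m_out == 0:
        raise UndefinedTestError("no cytosine mutations to test")

    if table == "expected":
        total = m_in + m_out
        frac = g_in / (g_in + g_out)
        e_in = int(round(total * frac))
        contingency = [[m_in, m_out], [e_in, total - e_in]]
    elif table == "genomic":
        contingency = [[m_in, m_out], [g_in, g_out]]
    else:
        raise ValueError("table must be 'genomic' or 'expected'")

    odds, p = fisher_exact(contingency)
    mut_frac = m_in / (m_in + m_out)
    site_frac = g_in / (g_in + g_out)
    return MotifTest(
        motif=motif,
        mutations_in_motif=m_in, mutations_out_motif=m_out,
        sites_in_motif=g_in, sites_out_motif=g_out,
        odds_ratio=odds, p_value=p,
        fold_enrichment=mut_frac / site_frac,
    )


def average_mutation_counts(per_sample_counts: list[pd.Series]) -> pd.Series:
    """Mean per-context count across clones, rounded to the nearest integer.

    This is how a single exact test is run on a clone group: the group's
    average observed counts, integerized.
    """
    stacked = pd.concat(per_sample_counts, axis=1)
    return stacked.mean(axis=1).round().astype(int)


def signature_context_counts(w_column: pd.Series, total_mutations: float) -> pd.Series:
    """Allocate a mutation total over the 16 contexts by a signature's
    cytosine-channel weights, rounded to integers.

    ``w_column`` is one signature over 96 or 48 labeled channels; only
    cytosine-class channels contribute.
    """
    cyto = w_column[[ch for ch in w_column.index if "[C" in ch]]
    ctx = [ch[0] + "C" + ch[-1] for ch in cyto.index]
    per_ctx = cyto.groupby(ctx).sum().reindex(CYTOSINE_CONTEXTS, fill_value=0.0)
    if per_ctx.sum() == 0:
        raise UndefinedTestError("signature has no cytosine-channel mass")
    return (per_ctx / per_ctx.sum() * total_mutations).round().astype(int)


def tcw_transversion_test(
    cg_context_props: pd.DataFrame,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Student's t: C-to-G proportions in TCW contexts vs the other 14.

    ``cg_context_props`` is a 16-context x samples table of per-sample
    C-to-G proportions (rows indexed by NCN contexts). All (sample,
    TCW-context) values form one group, all remaining (sample, context)
    values the other. Equal-variance Student's t by default; Welch with
    ``equal_var=False``.
    """
    props = cg_context_props.reindex(CYTOSINE_CONTEXTS)
    g1 = props.loc[TCW_CONTEXTS].to_numpy().ravel()
    g2 = props.drop(index=TCW_CONTEXTS).to_numpy().ravel()
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(g1) == 0 and np.var(g2) == 0 and np.mean(g1) == np.mean(g2):
        warnings.warn("degenerate zero-variance groups with equal means; p = 1",
                      stacklevel=2)
        return 0.0, 1.0
    t, p = sps.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def adjust_pvalues(p_values, method: str | None = None) -> np.ndarray:
    """Optional multiple-testing correction ('bonferroni' or 'bh')."""
    p = np.asarray(p_values, dtype=float)
    if method is None:
        return p
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError("method must be None, 'bonferroni' or 'bh'")
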