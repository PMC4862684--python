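"""Fisher exact test vs exact oracles; motif enrichment; TCW t-test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from clonemut.seqtools import genomic_context_counts
from clonemut.stats import (
    UndefinedTestError,
    adjust_pvalues,
    average_mutation_counts,
    fisher_exact,
    motif_enrichment,
    signature_context_counts,
    tcw_transversion_test,
)


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by Fraction-arithmetic enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, r1)
    weights = {k: Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), denom)
               for k in range(lo, hi + 1)}
    w_obs = weights[a]
    return float(sum(w for w in weights.values() if w <= w_obs))


class TestFisherExact:
    def test_proportional_table(self):
        odds, p = fisher_exact([[10, 90], [100, 900]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_enumeration(self):
        # [[5,0],[0,5]]: only 2 of the C(10,5)=252 tables are as extreme
        _, p = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedTestError):
            fisher_exact([[0, 0], [3, 4]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])

    def test_haldane_odds_when_zero_cell(self):
        odds, _ = fisher_exact([[5, 0], [2, 5]])
        assert odds == pytest.approx((5.5 * 5.5) / (0.5 * 2.5))

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_exact_oracle_and_scipy(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
        assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-9)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_under_transpose_and_double_swap(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        _, p = fisher_exact([[a, b], [c, d]])
        assert fisher_exact([[a, c], [b, d]])[1] == pytest.approx(p, rel=1e-12)
        assert fisher_exact([[d, c], [b, a]])[1] == pytest.approx(p, rel=1e-12)

    def test_type_i_error_near_nominal(self):
        """Null hypergeometric tables: rejection rate ~ alpha at alpha=0.05.

        Margins are large so the discrete test's p-values are near-uniform;
        with tiny margins any exact test is visibly conservative. The
        p-value depends only on the drawn cell, so it is cached per value.
        """
        rng = np.random.default_rng(12345)
        n_rep, alpha = 2000, 0.05
        N, r1, c1 = 8000, 4000, 400
        cache: dict[int, float] = {}
        rejections = 0
        for a in rng.hypergeometric(c1, N - c1, r1, size=n_rep):
            a = int(a)
            if a not in cache:
                cache[a] = fisher_exact(
                    [[a, r1 - a], [c1 - a, N - r1 - c1 + a]])[1]
            rejections += cache[a] <= alpha
        sigma = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) <= 3 * sigma


class TestMotifEnrichment:
    def _uniform_counts(self, per_context):
        from clonemut.seqtools import CYTOSINE_CONTEXTS
        return pd.Series(per_context, index=CYTOSINE_CONTEXTS)

    def test_all_mutations_in_motif_fold(self):
        # genomic fraction of TCA sites = 0.25 -> fold enrichment 4
        genomic = self._uniform_counts(0)
        genomic[:] = 10
        genomic["TCA"] = 10  # total 160, TCA fraction 1/16
        muts = self._uniform_counts(0)
        muts["TCA"] = 50
        t = motif_enrichment(muts, "TCA", genomic_counts=genomic)
        assert t.fold_enrichment == pytest.approx((50 / 50) / (10 / 160))

    def test_proportional_counts_null(self):
        genomic = self._uniform_counts(100)
        muts = self._uniform_counts(5)
        t = motif_enrichment(muts, "TCG", genomic_counts=genomic)
        assert t.fold_enrichment == pytest.approx(1.0)
        assert t.p_value == pytest.approx(1.0)
        assert t.odds_ratio == pytest.approx(1.0)

    def test_tcw_iupac_expansion(self):
        genomic = self._uniform_counts(100)
        muts = self._uniform_counts(0)
        muts["TCA"] = 30
        muts["TCT"] = 30
        t = motif_enrichment(muts, "TCW", genomic_counts=genomic)
        assert t.mutations_in_motif == 60
        assert t.sites_in_motif == 200

    def test_absent_motif_undefined(self):
        genomic = self._uniform_counts(100)
        genomic["TCG"] = 0
        muts = self._uniform_counts(1)
        with pytest.raises(UndefinedTestError):
            motif_enrichment(muts, "TCG", genomic_counts=genomic)

    def test_complement_fold_conservation(self, medium_reference):
        """If the motif is enriched, its complement set is depleted."""
        genomic = genomic_context_counts(medium_reference)
        muts = genomic.copy() * 0
        muts["TCA"] = 80
        muts["ACA"] = 20
        t_in = motif_enrichment(muts, "TCA", genomic_counts=genomic)
        assert t_in.fold_enrichment >= 1
        # complement = all contexts but TCA: its mutation fraction must be
        # under-represented relative to its genomic fraction
        comp_mut_frac = 20 / 100
        comp_site_frac = 1 - genomic["TCA"] / genomic.sum()
        assert comp_mut_frac / comp_site_frac <= 1

    def test_simulation_power_case_vs_background(self, medium_reference):
        """A3B-planted catalogs show TCA/TCG enrichment; background does not."""
        from clonemut.simulate import SimulationConfig, plant_a3b_process, plant_background_process
        from clonemut.spectrum import normalize_to_pyrimidine

        genomic = genomic_context_counts(medium_reference)
        cfg = SimulationConfig()

        def ctx_counts(df):
            idx = genomic.index
            out = pd.Series(0, index=idx)
            for row in df.itertuples(index=False):
                cls, tri = normalize_to_pyrimidine(row, medium_reference)
                if cls.startswith("C"):
                    out[tri] += 1
            return out

        case = plant_a3b_process(medium_reference, cfg, seed=31, n=800)
        bg = plant_background_process(medium_reference, cfg, seed=32, n=400, n_indels=0)
        for motif in ("TCA", "TCG"):
            p_case = motif_enrichment(ctx_counts(case.df), motif,
                                      genomic_counts=genomic).p_value
            p_bg = motif_enrichment(ctx_counts(bg.snvs), motif,
                                    genomic_counts=genomic).p_value
            assert p_case < 1e-3
            assert p_bg > 1e-3

    def test_average_counts_rounded_integer(self):
        s1 = pd.Series([1, 2], index=["TCA", "TCG"])
        s2 = pd.Series([2, 5], index=["TCA", "TCG"])
        avg = average_mutation_counts([s1, s2])
        assert list(avg) == [2, 4]  # 1.5 rounds to 2 (banker's), 3.5 to 4

    def test_signature_context_counts_allocation(self):
        w = pd.Series([0.6, 0.4], index=["T[C>T]G", "A[C>A]A"])
        counts = signature_context_counts(w, 100)
        assert counts["TCG"] == 60 and counts["ACA"] == 40


class TestTcwTransversionTest:
    def _props(self, tcw_value, other_value, n_samples=3):
        from clonemut.seqtools import CYTOSINE_CONTEXTS
        df = pd.DataFrame(other_value, index=CYTOSINE_CONTEXTS,
                          columns=[f"s{i}" for i in range(n_samples)],
                          dtype=float)
        df.loc[["TCA", "TCT"]] = tcw_value
        return df

    def test_identical_groups_t_zero(self):
        from clonemut.seqtools import CYTOSINE_CONTEXTS
        rng = np.random.default_rng(1)
        base = rng.uniform(0.5, 1.5, size=(16, 3))
        df = pd.DataFrame(base, index=CYTOSINE_CONTEXTS, columns=list("abc"))
        df.loc[["TCA", "TCT"]] = df.drop(index=["TCA", "TCT"]).to_numpy()[:2]
        # groups built from the same pool of values have equal means only in
        # expectation; use the exact degenerate construction instead
        t, p = tcw_transversion_test(self._props(0.5, 0.5))
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = tcw_transversion_test(self._props(0.5, 0.5))
        assert (t, p) == (0.0, 1.0)

    def test_pooled_variance_hand_computation(self):
        """{2.1, 2.0, 1.9} vs {1.0, 1.1, 0.9}: t = sqrt(150)."""
        from clonemut.seqtools import CYTOSINE_CONTEXTS
        df = pd.DataFrame(np.nan, index=CYTOSINE_CONTEXTS, columns=["a", "b", "c"])
        df.loc["TCA"] = [2.1, 2.0, 1.9]
        df.loc["ACA"] = [1.0, 1.1, 0.9]
        t, p = tcw_transversion_test(df)
        assert t == pytest.approx(np.sqrt(150))
        # cross-check with the textbook pooled formula
        g1, g2 = np.array([2.1, 2.0, 1.9]), np.array([1.0, 1.1, 0.9])
        sp2 = (g1.var(ddof=1) * 2 + g2.var(ddof=1) * 2) / 4
        t_hand = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand)

    def test_enriched_tcw_detected(self, lineage):
        from clonemut.spectrum import build_spectrum, context_counts

        cats = [lineage.catalogs[c] for c in lineage.case_clones]
        spec = build_spectrum(cats, lineage.reference)
        cg = context_counts(spec, "C>G")
        props = cg / cg.sum(axis=0)
        t, p = tcw_transversion_test(props)
        assert t > 0 and p < 0.05

    def test_too_few_observations(self):
        from clonemut.seqtools import CYTOSINE_CONTEXTS
        df = pd.DataFrame(np.nan, index=CYTOSINE_CONTEXTS, columns=["a"])
        df.loc["TCA", "a"] = 1.0
        with pytest.raises(ValueError, match=">= 2"):
            tcw_transversion_test(df)


class TestAdjustPvalues:
    def test_bonferroni_and_bh(self):
        p = [0.01, 0.02, 0.04]
        assert np.allclose(adjust_pvalues(p, "bonferroni"), [0.03, 0.06, 0.12])
        bh = adjust_pvalues(p, "bh")
        assert np.allclose(bh, [0.03, 0.03, 0.04])
        assert adjust_pvalues(p) is not None  # default: untouched
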