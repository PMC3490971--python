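import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from afenrich.stats import (
    ENRICHED_HIGHER,
    ENRICHED_LOWER,
    NOT_ENRICHED,
    binomial_tail_p,
    classify_enrichment,
    fst_multilocus,
    fst_two_populations,
    hudson_fst,
    scan_enrichment,
    storey_qvalues,
    summarize_enrichment,
)


def exact_binomial_tail(x: int, n: int, p: Fraction, direction: str) -> Fraction:
    """Independent oracle: exact rational term-by-term tail summation."""
    ks = range(x, n + 1) if direction == "higher" else range(0, x + 1)
    return sum(
        Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k) for k in ks
    )


class TestBinomialTail:
    def test_all_alternate_alleles_closed_form(self):
        assert binomial_tail_p(14, 14, 0.5, "higher") == pytest.approx(0.5**14, rel=1e-12)

    def test_degenerate_null(self):
        assert binomial_tail_p(0, 14, 0.0, "lower") == 1.0
        assert binomial_tail_p(0, 14, 0.0, "higher") == 1.0
        assert binomial_tail_p(14, 14, 1.0, "higher") == 1.0

    def test_worked_tail(self):
        # oracle: sum_{k=8}^{14} C(14,k) 0.2^k 0.8^(14-k)
        expected = float(exact_binomial_tail(8, 14, Fraction(1, 5), "higher"))
        assert expected == pytest.approx(2.397208739840002e-3, rel=1e-12)
        assert binomial_tail_p(8, 14, 0.20, "higher") == pytest.approx(expected, rel=1e-10)

    def test_matches_enumeration_oracle_on_grid(self):
        for n in (1, 5, 14, 20):
            for x in range(n + 1):
                for tens in range(11):
                    p = Fraction(tens, 10)
                    for direction in ("higher", "lower"):
                        exact = float(exact_binomial_tail(x, n, p, direction))
                        got = binomial_tail_p(x, n, float(p), direction)
                        assert abs(got - exact) < 1e-12, (x, n, p, direction)

    @given(st.integers(1, 30), st.integers(0, 30), st.floats(0, 1))
    def test_tails_partition_exactly(self, n, x, p):
        """P(X >= x) + P(X <= x-1) = 1 for x >= 1."""
        x = min(x, n)
        if x < 1:
            return
        hi = binomial_tail_p(x, n, p, "higher")
        lo = binomial_tail_p(x - 1, n, p, "lower")
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_exclusive_tail_option(self):
        assert binomial_tail_p(8, 14, 0.2, "higher", inclusive=False) == pytest.approx(
            float(exact_binomial_tail(9, 14, Fraction(1, 5), "higher")), rel=1e-10
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail_p(15, 14, 0.5, "higher")
        with pytest.raises(ValueError):
            binomial_tail_p(1, 14, 1.5, "higher")
        with pytest.raises(ValueError):
            binomial_tail_p(1, 14, 0.5, "sideways")


def wc_theta_oracle(x1, n1, x2, n2):
    """Independent transcription of the two-deme Weir-Cockerham estimator,
    written as the ANOVA on allele indicators rather than via mean squares."""
    p1, p2 = x1 / n1, x2 / n2
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    # among- and within-population sums of squares of the 0/1 allele variable
    ss_among = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    ss_within = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
    ms_among = ss_among / 1.0
    ms_within = ss_within / (n1 + n2 - 2)
    n_c = 2 * n1 * n2 / (n1 + n2)
    sigma_a = (ms_among - ms_within) / n_c
    return sigma_a / (sigma_a + ms_within)


class TestFst:
    def test_equal_frequencies_clamp_to_zero(self):
        raw, clamped = fst_two_populations(5, 14, 5, 14)
        assert raw < 0 and clamped == 0.0

    def test_fixed_difference_approaches_one(self):
        raw, _ = fst_two_populations(1000, 1000, 0, 1000)
        assert raw == pytest.approx(1.0, abs=1e-2)

    def test_against_independent_transcription(self):
        cases = [(8, 14, 152, 758), (3, 14, 50, 592), (10, 12, 100, 370)]
        for x1, n1, x2, n2 in cases:
            raw, _ = fst_two_populations(x1, n1, x2, n2)
            assert raw == pytest.approx(wc_theta_oracle(x1, n1, x2, n2), rel=1e-12)
            # Hudson's estimator must agree in sign and order of magnitude
            h = hudson_fst(x1, n1, x2, n2)
            assert np.sign(h) == np.sign(raw) or abs(raw) < 0.01
        raw, _ = fst_two_populations(8, 14, 152, 758)
        assert raw == pytest.approx(0.2792839295414349, rel=1e-12)

    def test_monomorphic_both_same_allele_flagged(self):
        raw, clamped = fst_two_populations(0, 14, 0, 758)
        assert np.isnan(raw) and clamped == 0.0

    @given(
        st.integers(2, 400),
        st.integers(2, 400),
        st.data(),
    )
    def test_symmetry_and_allele_relabeling(self, n1, n2, data):
        """Swapping populations or relabeling ref/alt leaves theta unchanged."""
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        raw, _ = fst_two_populations(x1, n1, x2, n2)
        swapped, _ = fst_two_populations(x2, n2, x1, n1)
        relabeled, _ = fst_two_populations(n1 - x1, n1, n2 - x2, n2)
        if np.isnan(raw):
            assert np.isnan(swapped) and np.isnan(relabeled)
        else:
            assert swapped == pytest.approx(raw, rel=1e-9, abs=1e-12)
            assert relabeled == pytest.approx(raw, rel=1e-9, abs=1e-12)

    def test_multilocus_is_ratio_of_sums(self):
        x1 = np.array([8, 3, 10])
        n1 = np.array([14, 14, 12])
        x2 = np.array([152, 50, 100])
        n2 = np.array([758, 592, 370])
        got = fst_multilocus(x1, n1, x2, n2)
        assert 0 < got < 1


class TestStoreyQvalues:
    def test_single_pvalue(self):
        assert storey_qvalues([0.03], "fixed_1").qvalues[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        res = storey_qvalues([0.01, 0.02, 0.03, 0.5], "fixed_1")
        np.testing.assert_allclose(res.qvalues, [0.04, 0.04, 0.04, 0.5])

    def test_ties_all_equal(self):
        res = storey_qvalues([0.2] * 5, "fixed_1")
        np.testing.assert_allclose(res.qvalues, 0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_fixed_pi0_equals_benjamini_hochberg(self, pvals):
        """With pi0=1 the q-values are exactly the BH adjusted p-values."""
        from statsmodels.stats.multitest import multipletests

        q = storey_qvalues(pvals, "fixed_1").qvalues
        bh = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=0, atol=1e-14)

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=300))
    def test_qvalues_monotone_in_rank_and_bounded(self, pvals):
        res = storey_qvalues(pvals, "smoother")
        q = np.asarray(res.qvalues)
        assert 0 < res.pi0 <= 1.0
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_smoother_shrinks_qvalues_under_signal(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1e-4, 300), rng.uniform(0, 1, 700)])
        smooth = storey_qvalues(p, "smoother")
        fixed = storey_qvalues(p, "fixed_1")
        assert smooth.pi0 < 1.0
        assert (smooth.qvalues <= fixed.qvalues + 1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])
        with pytest.raises(ValueError):
            storey_qvalues([])


class TestEnrichmentCall:
    @pytest.mark.parametrize(
        "fst, q_hi, q_lo, expected",
        [
            (0.30, 0.01, 0.99, ENRICHED_HIGHER),
            (0.30, 0.10, 0.99, NOT_ENRICHED),
            (0.10, 0.001, 0.99, NOT_ENRICHED),
            (0.30, 0.99, 0.01, ENRICHED_LOWER),
            (0.25, 0.01, 0.99, NOT_ENRICHED),  # strict: fst must exceed 0.25
            (0.30, 0.05, 0.99, NOT_ENRICHED),  # strict: q must be below 0.05
        ],
    )
    def test_combined_thresholds(self, fst, q_hi, q_lo, expected):
        assert classify_enrichment(fst, q_hi, q_lo) == expected

    def test_both_directions_warns_and_prefers_higher(self):
        with pytest.warns(RuntimeWarning):
            call = classify_enrichment(0.9, 0.001, 0.001)
        assert call == ENRICHED_HIGHER


def _mini_table(rows):
    return pd.DataFrame(
        rows,
        columns=["site_index", "continent", "call"],
    )


class TestSummarizeEnrichment:
    def test_empty(self):
        out = summarize_enrichment(pd.DataFrame(columns=["site_index", "continent", "call"]).iloc[0:0])
        assert out["union"] == 0 and out["per_continent"] == {}

    def test_hand_counted_union(self):
        rows = [
            (0, "EUR", ENRICHED_HIGHER),
            (0, "ASN", NOT_ENRICHED),
            (1, "EUR", ENRICHED_HIGHER),
            (1, "ASN", ENRICHED_HIGHER),
            (2, "EUR", NOT_ENRICHED),
            (2, "ASN", NOT_ENRICHED),
        ]
        out = summarize_enrichment(_mini_table(rows))
        assert out["union"] == 2
        assert out["per_continent"] == {"ASN": 1, "EUR": 2}
        assert out["by_n_continents"] == {1: 1, 2: 1}

    def test_enriched_versus_all_continents(self):
        rows = [(7, c, ENRICHED_HIGHER) for c in ("EUR", "ASN", "AFR", "AMR")]
        rows += [(8, c, ENRICHED_LOWER) for c in ("EUR", "ASN", "AFR", "AMR")]
        rows += [(9, c, NOT_ENRICHED) for c in ("EUR", "ASN", "AFR", "AMR")]
        out = summarize_enrichment(_mini_table(rows))
        assert out["by_n_continents"][4] == 2
        assert out["higher_vs_all"] == 1
        assert out["lower_vs_all"] == 1


class TestScan:
    def test_novel_sites_excluded_and_reported(self, small_dataset):
        from afenrich.genotype_io import all_allele_stats

        panel = small_dataset.panel_table
        freq = panel.freq.copy()
        freq[5, :] = np.nan  # site unseen in every panel
        freq[6, 0] = np.nan  # absent in one continent only
        panel2 = type(panel)(
            continents=panel.continents,
            sites=panel.sites,
            freq=freq,
            n_alleles=panel.n_alleles,
        )
        x, n = all_allele_stats(small_dataset.cohort)
        table, novel = scan_enrichment(x, n, panel2)
        assert novel == [5]
        assert 5 not in set(table["site_index"])
        eur_sites = set(table.loc[table["continent"] == "EUR", "site_index"])
        assert 6 not in eur_sites
        assert 6 in set(table.loc[table["continent"] == "ASN", "site_index"])

    def test_pooled_directions_one_family(self, small_dataset):
        from afenrich.genotype_io import all_allele_stats

        x, n = all_allele_stats(small_dataset.cohort)
        sep, _ = scan_enrichment(x, n, small_dataset.panel_table, pool_directions=False)
        pooled, _ = scan_enrichment(x, n, small_dataset.panel_table, pool_directions=True)
        eur_sep = sep[sep["continent"] == "EUR"]
        eur_pool = pooled[pooled["continent"] == "EUR"]
        family = np.concatenate([eur_sep["p_higher"], eur_sep["p_lower"]])
        expected = storey_qvalues(family, "fixed_1").qvalues
        np.testing.assert_allclose(eur_pool["q_higher"], expected[: len(eur_sep)])
        np.testing.assert_allclose(eur_pool["q_lower"], expected[len(eur_sep) :])

    def test_misaligned_input_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            scan_enrichment(
                np.zeros(3, dtype=int), np.zeros(3, dtype=int), small_dataset.panel_table
            )
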