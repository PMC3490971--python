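import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from afenrich.genotype_io import (
    MISSING,
    CohortGenotypes,
    VariantSite,
    VcfParseError,
    all_allele_stats,
    cohort_allele_stats,
    genotype_concordance,
    read_cohort_vcf,
    read_panel_frequencies,
    round_half_up,
    write_cohort_vcf,
    write_panel_frequencies,
)


def _cohort(calls, n_sites=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_sites = n_sites or calls.shape[1]
    sites = [VariantSite("1", 100 + i, "A", "G", f"rs{i}") for i in range(n_sites)]
    return CohortGenotypes(
        samples=[f"S{i}" for i in range(calls.shape[0])], sites=sites, calls=calls
    )


class TestVariantSite:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1", pos=0, ref="A", alt="G"),
            dict(chrom="1", pos=5, ref="A", alt="A"),
            dict(chrom="1", pos=5, ref="AT", alt="G"),
            dict(chrom="1", pos=5, ref="N", alt="G"),
        ],
    )
    def test_invalid_sites_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantSite(**kwargs)


class TestAlleleStats:
    @pytest.mark.parametrize(
        "column, x, n, display",
        [
            # 1 alt/alt + 6 het -> 8 of 14 alleles, prints 0.57
            ([2, 1, 1, 1, 1, 1, 1], 8, 14, "0.57"),
            # 1 het + 6 ref/ref -> 1 of 14, prints 0.07
            ([1, 0, 0, 0, 0, 0, 0], 1, 14, "0.07"),
            # failed genotype drops both alleles from the denominator
            ([MISSING, 1, 1, 0, 0, 0, 0], 2, 12, "0.17"),
        ],
    )
    def test_missing_aware_counts(self, column, x, n, display):
        g = _cohort(np.array(column)[:, None])
        s = cohort_allele_stats(g, 0)
        assert (s.x, s.n_called) == (x, n)
        assert s.freq == pytest.approx(x / n)
        assert s.display_freq == display

    def test_all_missing_is_undefined_not_zero(self):
        g = _cohort(np.full((3, 1), MISSING))
        s = cohort_allele_stats(g, 0)
        assert s.n_called == 0 and np.isnan(s.freq)

    def test_site_index_bounds(self):
        g = _cohort([[0], [1]])
        with pytest.raises(IndexError):
            cohort_allele_stats(g, 1)

    @given(
        hnp.arrays(
            np.int8,
            st.tuples(st.integers(1, 8), st.integers(1, 12)),
            elements=st.sampled_from([MISSING, 0, 1, 2]),
        )
    )
    def test_frequency_identity(self, calls):
        """freq == (hets + 2*homalt) / (2*called), exactly, at every site."""
        g = _cohort(calls)
        x, n = all_allele_stats(g)
        for j in range(calls.shape[1]):
            col = calls[:, j]
            hets = (col == 1).sum()
            homalt = (col == 2).sum()
            called = (col != MISSING).sum()
            assert x[j] == hets + 2 * homalt
            assert n[j] == 2 * called
            s = cohort_allele_stats(g, j)
            if called:
                assert s.freq == (hets + 2 * homalt) / (2 * called)


class TestVcfRoundTrip:
    def test_roundtrip_matches_generator_truth(self, tmp_path):
        from afenrich.simulate import SimulationConfig, simulate_dataset

        ds = simulate_dataset(SimulationConfig(n_sites=20, seed=5))
        path = tmp_path / "cohort.vcf"
        write_cohort_vcf(ds.cohort, path)
        back = read_cohort_vcf(path)
        assert back.samples == ds.cohort.samples
        assert [s.key for s in back.sites] == [s.key for s in ds.cohort.sites]
        np.testing.assert_array_equal(back.calls, ds.cohort.calls)

    def test_half_missing_becomes_missing(self, tmp_path):
        vcf = tmp_path / "half.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/.\t./.\t0/1\n"
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/.\t1/1\t0/0\n"
        )
        g = read_cohort_vcf(vcf)
        np.testing.assert_array_equal(g.calls[:, 0], [MISSING, MISSING, 1])
        np.testing.assert_array_equal(g.calls[:, 1], [MISSING, 2, 0])
        assert g.sites[1].rsid is None

    def test_multiallelic_rejected_or_strict(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        g = read_cohort_vcf(vcf, multiallelic="reject")
        assert g.n_sites == 1 and g.n_rejected_records == 1
        with pytest.raises(VcfParseError):
            read_cohort_vcf(vcf, multiallelic="strict")

    def test_sex_chromosomes_excluded(self, tmp_path):
        vcf = tmp_path / "xy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n##contig=<ID=X>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
            "X\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
        )
        g = read_cohort_vcf(vcf)
        assert [s.chrom for s in g.sites] == ["1"]


class TestConcordance:
    def test_identical_sets_concord(self):
        g = _cohort([[0, 1], [2, 1]])
        assert genotype_concordance(g, g).discordance == 0.0

    def test_fully_discordant(self):
        a = _cohort([[0, 0], [0, 0]])
        b = _cohort([[1, 2], [2, 1]])
        assert genotype_concordance(a, b).discordance == 1.0

    def test_rate_arithmetic_and_symmetry(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(4, 100)).astype(np.int8)
        other = calls.copy()
        other[0, 0] = (other[0, 0] + 1) % 3
        other[3, 99] = (other[3, 99] + 1) % 3
        a, b = _cohort(calls), _cohort(other)
        rep = genotype_concordance(a, b)
        assert (rep.n_compared, rep.n_discordant) == (400, 2)
        assert rep.discordance == 0.005
        rev = genotype_concordance(b, a)
        assert rev.discordance == rep.discordance

    def test_missing_cells_excluded(self):
        a = _cohort([[0, MISSING], [1, 1]])
        b = _cohort([[0, 1], [MISSING, 1]])
        rep = genotype_concordance(a, b)
        assert rep.n_compared == 2 and rep.n_discordant == 0

    def test_empty_intersection_errors(self):
        a = _cohort([[0]])
        b = CohortGenotypes(["OTHER"], [VariantSite("2", 5, "C", "T")], np.array([[0]], np.int8))
        with pytest.raises(ValueError):
            genotype_concordance(a, b)


class TestPanelFrequencies:
    def test_continental_row(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\trsid\tEUR_freq\tEUR_n\tASN_freq\tASN_n\t"
            "AFR_freq\tAFR_n\tAMR_freq\tAMR_n\n"
            "3\t41877414\tT\tC\trs3774372\t0.20\t758\t0.15\t592\t0.23\t370\t0.15\t484\n"
        )
        t = read_panel_frequencies(path)
        assert t.continents == ["EUR", "ASN", "AFR", "AMR"]
        np.testing.assert_allclose(t.freq[0], [0.20, 0.15, 0.23, 0.15])
        assert t.n_alleles[0].tolist() == [758, 592, 370, 484]

    def test_empty_cell_is_absent_not_zero(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tEUR_freq\tEUR_n\tASN_freq\tASN_n\n"
            "1\t100\tA\tG\t0.5\t100\t\t\n"
        )
        t = read_panel_frequencies(path)
        assert np.isnan(t.freq[0, 1]) and t.freq[0, 0] == 0.5

    def test_out_of_range_frequency_errors(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("chrom\tpos\tref\talt\tEUR_freq\tEUR_n\n1\t100\tA\tG\t1.2\t100\n")
        with pytest.raises(ValueError, match="outside"):
            read_panel_frequencies(path)

    def test_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "panel.tsv"
        write_panel_frequencies(small_dataset.panel_table, path)
        back = read_panel_frequencies(path)
        np.testing.assert_allclose(back.freq, small_dataset.panel_table.freq)
        np.testing.assert_array_equal(back.n_alleles, small_dataset.panel_table.n_alleles)


@pytest.mark.parametrize(
    "value, nd, expected",
    [(0.5, 0, 1.0), (4.76, 0, 5.0), (0.5714, 2, 0.57), (0.075, 2, 0.08), (-0.5, 0, -1.0)],
)
def test_round_half_up(value, nd, expected):
    assert round_half_up(value, nd) == expected
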