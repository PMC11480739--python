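"""Per-site QC tags, exact HWE/ExcHet, filter expressions, LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hwe_oracle
from snpdesk.errors import DomainError, FilterParseError
from snpdesk.site_stats import (
    FilterExpression,
    compute_site_stats,
    cumulative_filter_curve,
    eval_filter,
    genotype_vs_allele_freq,
    hwe_exact,
    ld_prune,
)
from snpdesk.synth_fixtures import PopulationSpec, simulate_genotypes
from snpdesk.vcf_model import GenotypeMatrix, SiteEntry


def column_matrix(*cols):
    """Matrix from per-site code columns (samples inferred from length)."""
    codes = np.array(cols, dtype=np.int8).T
    n = codes.shape[0]
    sites = [SiteEntry("chr1", 100 * (j + 1), "A", ("G",)) for j in range(codes.shape[1])]
    return GenotypeMatrix([f"s{i}" for i in range(n)], sites, codes)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 0, 0), (1.0, 1.0)),  # monomorphic convention
            ((0, 2, 0), (1.0, 2 / 3)),  # enumeration over het in {0, 2}
            ((1, 0, 1), (1 / 3, 1.0)),
        ],
    )
    def test_small_enumerations(self, counts, expected):
        p = hwe_exact(*counts)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            hwe_exact(-1, 0, 1)
        with pytest.raises(DomainError):
            hwe_exact(0, 0, 0)

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact(a, h, b) == pytest.approx(hwe_oracle(a, h, b), rel=1e-9)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_in_homozygote_classes(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact(a, h, b) == pytest.approx(hwe_exact(b, h, a), rel=1e-12)


class TestComputeSiteStats:
    def test_direct_counting(self):
        m = column_matrix([0, 0, 1])
        (s,) = compute_site_stats(m)
        assert s.call_rate == 1.0
        assert s.af == pytest.approx(1 / 6)
        assert s.maf == pytest.approx(1 / 6)
        assert s.frac_het == pytest.approx(1 / 3)

    def test_missingness_and_fixed_alt(self):
        m = column_matrix([-1, -1, 2])
        (s,) = compute_site_stats(m)
        assert s.call_rate == pytest.approx(1 / 3)
        assert s.af == 1.0
        assert s.maf == 0.0
        assert (s.hwe_p, s.exchet_p) == (1.0, 1.0)  # monomorphic among called

    def test_balanced_site_hwe(self):
        m = column_matrix([0, 1, 2, 1])
        (s,) = compute_site_stats(m)
        assert s.maf == 0.5
        assert s.frac_het == 0.5
        assert s.hwe_p == pytest.approx(hwe_oracle(1, 2, 1)[0])

    def test_call_rate_plus_f_missing_is_one(self):
        m = simulate_genotypes(
            PopulationSpec(n_samples=40, n_sites=30, seed=11, missing_rate=0.2)
        )
        for s in compute_site_stats(m):
            assert s.call_rate + s.f_missing == pytest.approx(1.0)
            assert s.maf == pytest.approx(min(s.af, 1 - s.af))

    def test_depth_and_qual_passthrough(self):
        m = column_matrix([0, 1])
        depths = np.array([[10.0], [np.nan]])
        (s,) = compute_site_stats(m, depths=depths, quals=[123.0])
        assert s.mean_dp == 10.0
        assert s.qual == 123.0


class TestFilterExpressions:
    def test_single_comparison(self):
        m = column_matrix([0, 0, 1], [0, 1, 1], [1, 1, 2])
        stats = compute_site_stats(m)
        mask = eval_filter(stats, "MAF>0.2")
        assert mask.tolist() == [np.float64(s.maf) > 0.2 for s in stats]

    def test_portal_style_expression(self):
        from snpdesk.site_stats import SiteStats

        s = SiteStats(
            call_rate=0.8, f_missing=0.2, af=0.3, maf=0.3, frac_het=0.2,
            hwe_p=0.1, exchet_p=0.6, qual=2e5,
        )
        expr = "(F_MISSING<0.5 & MAF>0.2 & QUAL>100000 & (ExcHet>0.5 | HWE>0.5))"
        assert eval_filter([s], expr).tolist() == [True]

    def test_absent_tag_comparison_is_false(self):
        from snpdesk.site_stats import SiteStats

        s = SiteStats(
            call_rate=1.0, f_missing=0.0, af=0.5, maf=0.5, frac_het=0.5,
            hwe_p=1.0, exchet_p=1.0, qual=None,
        )
        assert eval_filter([s], "QUAL>0").tolist() == [False]
        assert eval_filter([s], "QUAL>0 | MAF>0.2").tolist() == [True]

    def test_unknown_tag_rejected_at_parse_time(self):
        with pytest.raises(FilterParseError):
            FilterExpression("FOO>1")

    def test_conjunction_equals_elementwise_and(self):
        m = simulate_genotypes(
            PopulationSpec(n_samples=30, n_sites=50, seed=5, maf=("uniform", 0.05, 0.5),
                           missing_rate=0.1)
        )
        stats = compute_site_stats(m)
        left = eval_filter(stats, "MAF>0.2")
        right = eval_filter(stats, "F_MISSING<0.1")
        both = eval_filter(stats, "MAF>0.2 & F_MISSING<0.1")
        assert np.array_equal(both, left & right)

    def test_flipped_constant_side(self):
        m = column_matrix([0, 1, 1, 2])
        stats = compute_site_stats(m)
        assert np.array_equal(
            eval_filter(stats, "0.2<MAF"), eval_filter(stats, "MAF>0.2")
        )


class TestLdPrune:
    def test_identical_nearby_sites_pruned(self):
        m = column_matrix([0, 1, 2, 0], [0, 1, 2, 0])
        assert ld_prune(m, r2_max=0.8, window_bp=100_000) == [0]

    def test_outside_window_both_retained(self):
        sites = [
            SiteEntry("chr1", 1_000, "A", ("G",)),
            SiteEntry("chr1", 201_000, "A", ("G",)),
        ]
        codes = np.array([[0, 0], [1, 1], [2, 2], [0, 0]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c", "d"], sites, codes)
        assert ld_prune(m, r2_max=0.8, window_bp=100_000) == [0, 1]

    def test_hand_computed_r2_pattern(self):
        # site2 ~ site1 (r2 > 0.8); site3 nearly uncorrelated with site1
        c1 = [0, 0, 1, 1, 2, 2]
        c2 = [0, 0, 1, 2, 2, 2]
        c3 = [0, 2, 2, 0, 0, 2]
        m = column_matrix(c1, c2, c3)
        r12 = np.corrcoef(c1, c2)[0, 1] ** 2
        r13 = np.corrcoef(c1, c3)[0, 1] ** 2
        assert r12 > 0.8 > r13
        assert ld_prune(m, r2_max=0.8, window_bp=100_000) == [0, 2]

    def test_zero_variance_sites_retained_and_inert(self):
        m = column_matrix([1, 1, 1, 1], [0, 1, 2, 0], [0, 1, 2, 0])
        assert ld_prune(m, r2_max=0.5, window_bp=10_000) == [0, 1]

    def test_invariant_no_retained_pair_above_threshold(self):
        m = simulate_genotypes(
            PopulationSpec(n_samples=40, n_sites=80, seed=21,
                           maf=("uniform", 0.1, 0.5), missing_rate=0.05)
        )
        # duplicate some columns to create strong LD
        codes = m.codes.copy()
        codes[:, 1::7] = codes[:, 0::7][:, : codes[:, 1::7].shape[1]]
        m = GenotypeMatrix(m.samples, m.sites, codes)
        kept = ld_prune(m, r2_max=0.6, window_bp=2_000)
        for x, i in enumerate(kept):
            for j in kept[x + 1:]:
                si, sj = m.sites[i], m.sites[j]
                if si.chrom != sj.chrom or sj.pos - si.pos > 2_000:
                    continue
                a, b = m.codes[:, i], m.codes[:, j]
                mask = (a >= 0) & (b >= 0)
                if mask.sum() < 2 or a[mask].std() == 0 or b[mask].std() == 0:
                    continue
                r2 = np.corrcoef(a[mask], b[mask])[0, 1] ** 2
                assert r2 <= 0.6 + 1e-12

    def test_bad_threshold_rejected(self, toy_matrix):
        with pytest.raises(DomainError):
            ld_prune(toy_matrix, r2_max=1.5)


class TestCumulativeCurve:
    def test_counting_example(self):
        hist, cum = cumulative_filter_curve(
            [0.1, 0.5, 0.9], direction="max_relaxed", bin_edges=[0, 0.25, 0.75, 1]
        )
        assert hist.tolist() == [1, 1, 1]
        assert cum.tolist() == [3, 2, 1, 0]

    def test_min_relaxed_mirror(self):
        _, cum = cumulative_filter_curve(
            [0.1, 0.5, 0.9], direction="min_relaxed", bin_edges=[0, 0.25, 0.75, 1]
        )
        assert cum.tolist() == [0, 1, 2, 3]

    def test_all_equal_values_single_bin(self):
        hist, cum = cumulative_filter_curve(
            [0.5] * 4, direction="max_relaxed", bin_edges=[0, 0.4, 0.6, 1]
        )
        assert hist.tolist() == [0, 4, 0]
        assert cum.tolist() == [4, 4, 0, 0]

    def test_uniform_values_near_linear(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, 1000)
        edges = np.linspace(0, 1, 11)
        _, cum = cumulative_filter_curve(vals, "max_relaxed", edges)
        expected = 1000 * (1 - edges)
        assert np.all(np.abs(cum - expected) <= 50)  # +-5% of total

    def test_monotone_from_total_to_zero(self):
        _, cum = cumulative_filter_curve([1, 2, 3, 4], "max_relaxed", [0, 2, 3, 5])
        assert cum[0] == 4
        assert all(x >= y for x, y in zip(cum, cum[1:]))


class TestGenotypeVsAlleleFreq:
    def test_all_het_site(self):
        m = column_matrix([1, 1, 1, 1])
        obs, exp = genotype_vs_allele_freq(m)
        assert obs[0].tolist() == [0.5, 0.0, 1.0, 0.0]
        assert exp["f_het"][0] == pytest.approx(0.5)

    def test_exact_hwe_proportions_match_expectation(self):
        m = column_matrix([0] + [1, 1] + [2])
        obs, exp = genotype_vs_allele_freq(m)
        assert obs[0, 1:] == pytest.approx(
            [exp["f_homref"][0], exp["f_het"][0], exp["f_homalt"][0]]
        )

    def test_inbreeding_depresses_heterozygosity(self):
        m = simulate_genotypes(
            PopulationSpec(n_samples=2000, n_sites=5, seed=17, maf=0.5, inbreeding=0.5)
        )
        obs, _ = genotype_vs_allele_freq(m)
        # E(f_het) = 2pq(1 - F) = 0.25; 3 sigma of binomial(2000, .25) ~ 0.029
        assert obs[:, 2].mean() == pytest.approx(0.25, abs=0.03)
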