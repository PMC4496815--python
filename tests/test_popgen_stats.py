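"""Allele-frequency statistics: FST, homozygosity, Tajima's D, Fay-Wu H."""

import itertools
import math

import numpy as np
import pytest

from apisweep.io_formats import OutgroupAlleles
from apisweep.neutral_sim import island_fixture
from apisweep.popgen_stats import (
    allele_freqs,
    fay_wu_h_norm,
    faywu_h_norm_from_spectrum,
    fst_group_randomization,
    fst_overall,
    fst_per_snp,
    homozygosity_scores,
    reich_fst,
    tajima_d_for_sites,
    variance_constants,
    window_stats,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent scalar oracles, written from the published definitions
# ---------------------------------------------------------------------------

def oracle_tajima_constants(n):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, a2, c1 / a1, c2 / (a1**2 + a2)


def oracle_tajima_d(n, S, pi):
    a1, _, e1, e2 = oracle_tajima_constants(n)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_h_norm(n, sfs):
    """Zeng-normalized Fay-Wu H from an unfolded spectrum, scalar-style."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    bn1 = sum(1.0 / i**2 for i in range(1, n + 1))
    S = sum(sfs)
    pi = sum(2.0 * i * (n - i) * sfs[i - 1] for i in range(1, n)) / (n * (n - 1))
    theta_l = sum(i * sfs[i - 1] for i in range(1, n)) / (n - 1)
    theta_w = S / a1
    theta_sq = S * (S - 1) / (a1**2 + a2)
    var = theta_w * (n - 2) / (6.0 * (n - 1)) + theta_sq * (
        18.0 * n * n * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n * n - 13 * n + 6)
    ) / (9.0 * n * (n - 1) ** 2)
    return (pi - theta_l) / math.sqrt(var)


def oracle_reich_fst(a1, n1, a2, n2):
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    return num, num + h1 + h2


# ---------------------------------------------------------------------------
# allele frequencies and homozygosity
# ---------------------------------------------------------------------------

class TestAlleleFreqs:
    def test_counting(self):
        table = make_table([[0, 1, 2], [2, 2, -1], [-1, -1, -1]])
        f = allele_freqs(table, table.sample_ids)
        assert (f.a[0], f.n[0]) == (3, 6)
        assert (f.a[1], f.n[1]) == (4, 4)
        assert not f.defined[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            allele_freqs(make_table([[1]]), [])


class TestHomozygosity:
    def test_known_scores(self):
        table = make_table([[2, 2], [1, 1], [1, 2]])  # p = 1, 0.5, 0.75
        track = homozygosity_scores(table, allele_freqs(table, table.sample_ids))
        assert track.scores == pytest.approx([1.0, 0.0, 0.25])

    def test_score_is_one_iff_monomorphic(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(200, 4)).astype(np.int8)
        table = make_table(geno)
        f = allele_freqs(table, table.sample_ids)
        track = homozygosity_scores(table, f)
        mono = (f.a == 0) | (f.a == f.n)
        assert np.all((track.scores == 1.0) == mono[f.defined])
        assert np.all((track.scores >= 0) & (track.scores <= 1))


# ---------------------------------------------------------------------------
# Reich-Patterson FST
# ---------------------------------------------------------------------------

class TestReichFst:
    def test_reciprocally_fixed_difference_is_exactly_one(self):
        for n1, n2 in itertools.product(range(2, 11), repeat=2):
            num, den = reich_fst(n1, n1, 0, n2)
            assert num / den == 1.0
            num, den = reich_fst(0, n1, n2, n2)
            assert num / den == 1.0

    def test_matches_direct_formula(self):
        num, den = reich_fst(3, 6, 5, 10)
        enum, eden = oracle_reich_fst(3.0, 6.0, 5.0, 10.0)
        assert num == pytest.approx(enum, abs=1e-12)
        assert den == pytest.approx(eden, abs=1e-12)
        assert num / den < 0  # equal sample frequencies -> negative estimate

    def test_per_snp_track_skips_undefined(self):
        # site 0: reciprocally fixed; site 1: both monomorphic-ref (den = 0)
        table = make_table([[2, 2, 0, 0], [0, 0, 0, 0]])
        track = fst_per_snp(table, ["s1", "s2"], ["s3", "s4"])
        assert len(track) == 1 and track.scores[0] == 1.0

    def test_overall_is_ratio_of_sums(self):
        table = make_table([[2, 2, 0, 0]])
        assert fst_overall(table, ["s1", "s2"], ["s3", "s4"]) == 1.0
        # ratio-of-sums differs from mean-of-ratios on heterogeneous sites
        table = make_table([[2, 2, 0, 0], [1, 1, 1, 1]])
        a, b = ["s1", "s2"], ["s3", "s4"]
        nums, dens = [], []
        for row in table.genotypes:
            n, d = reich_fst(row[:2].sum(), 4, row[2:].sum(), 4)
            nums.append(float(n)), dens.append(float(d))
        assert fst_overall(table, a, b) == pytest.approx(sum(nums) / sum(dens))

    def test_panmictic_overall_is_near_zero(self):
        table, spec = island_fixture((3, 5), 10_000, 0.0, seed=1)
        assert abs(fst_overall(table, spec["A"], spec["B"])) < 0.01


class TestGroupRandomization:
    def test_counting_rule_and_determinism(self):
        table, spec = island_fixture((3, 5), 2_000, 0.4, seed=2)
        obs, p, null = fst_group_randomization(
            table, spec["A"], spec["B"], reps=999, seed=3
        )
        # +1 counting rule: p can never be zero and counts ties as hits
        assert p == (1 + int(np.sum(null >= obs))) / 1000
        # strong structure: only regroupings recovering the deme split tie it
        assert p < 0.05
        assert np.all(null <= obs)
        _, _, null2 = fst_group_randomization(
            table, spec["A"], spec["B"], reps=999, seed=3
        )
        assert np.array_equal(null, null2)

    def test_p_value_calibration_under_the_null(self):
        """When the observed grouping is itself random (panmictic data),
        p <= 0.05 should occur at ~5% of trials."""
        table, spec = island_fixture((3, 5), 2_000, 0.0, seed=4)
        hits = 0
        for trial in range(50):
            _, p, _ = fst_group_randomization(
                table, spec["A"], spec["B"], reps=59, seed=100 + trial
            )
            hits += p <= 0.05
        # binomial 95% band around 0.05 for 50 trials
        assert hits / 50 <= 0.05 + 1.96 * math.sqrt(0.05 * 0.95 / 50)


# ---------------------------------------------------------------------------
# Tajima's D and Fay-Wu H
# ---------------------------------------------------------------------------

class TestVarianceConstants:
    @pytest.mark.parametrize("n", [4, 10, 22])
    def test_against_independent_script(self, n):
        k = variance_constants(n)
        a1, a2, e1, e2 = oracle_tajima_constants(n)
        assert k.a1 == pytest.approx(a1, abs=1e-12)
        assert k.a2 == pytest.approx(a2, abs=1e-12)
        assert k.e1 == pytest.approx(e1, abs=1e-12)
        assert k.e2 == pytest.approx(e2, abs=1e-12)
        assert k.a1 > 0


class TestWindowStats:
    def test_tajima_d_matches_oracle_on_singleton_case(self):
        # n = 4 haplotypes (2 diploids), 3 singleton sites
        table = make_table([[1, 0], [0, 1], [1, 0]], pos=[10, 20, 30])
        (w,) = window_stats(table, table.sample_ids, 100, {"chr1": 100})
        assert w.S == 3
        assert w.pi == pytest.approx(1.5)
        assert w.theta_w == pytest.approx(3 / (11 / 6))
        assert w.tajima_d == pytest.approx(oracle_tajima_d(4, 3, 1.5), abs=1e-9)

    def test_monomorphic_window_is_undefined(self):
        table = make_table([[2, 2]], pos=[10])
        (w,) = window_stats(table, table.sample_ids, 100, {"chr1": 100})
        assert w.S == 0 and math.isnan(w.tajima_d)

    def test_pi_equals_brute_force_pairwise_differences(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        table = make_table(geno, pos=np.arange(40))
        (w,) = window_stats(table, table.sample_ids, 100, {"chr1": 100})
        # expand to pseudo-haplotypes (allele placement is irrelevant per site)
        haps = np.zeros((10, 40), dtype=int)
        for s in range(5):
            haps[2 * s] = geno[:, s] >= 1
            haps[2 * s + 1] = geno[:, s] == 2
        diffs = [
            np.sum(haps[i] != haps[j]) for i, j in itertools.combinations(range(10), 2)
        ]
        assert w.pi == pytest.approx(np.mean(diffs))

    def test_incomplete_sites_excluded_by_default(self):
        table = make_table([[1, -1], [1, 0]], pos=[10, 20])
        (w,) = window_stats(table, table.sample_ids, 100, {"chr1": 100})
        assert w.S == 1  # the half-missing site is dropped, n stays 2x2


class TestTajimaForSiteMasks:
    def test_consistency_with_windows_and_pooling(self):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        table = make_table(geno, pos=np.arange(60) * 3)
        windows = window_stats(table, table.sample_ids, 90, {"chr1": 180})
        mask0 = np.asarray(table.pos) < 90
        d0 = tajima_d_for_sites(table, table.sample_ids, mask0)
        assert d0 == pytest.approx(windows[0].tajima_d, abs=1e-12)
        # pooling all sites equals the union mask
        d_all = tajima_d_for_sites(table, table.sample_ids, np.ones(60, bool))
        assert np.isfinite(d_all)

    def test_rare_nonsynonymous_class_more_negative(self):
        # 'nonsynonymous' sites as singletons, 'synonymous' at midrange
        nonsyn = [[1, 0, 0, 0, 0, 0]] * 12
        syn = [[1, 1, 1, 2, 0, 1]] * 12
        geno = np.array(nonsyn + syn, dtype=np.int8)
        table = make_table(geno, pos=np.arange(24))
        mask_non = np.arange(24) < 12
        d_non = tajima_d_for_sites(table, table.sample_ids, mask_non)
        d_syn = tajima_d_for_sites(table, table.sample_ids, ~mask_non)
        assert d_non < d_syn

    def test_empty_mask_rejected(self):
        table = make_table([[1, 0]])
        with pytest.raises(ValueError, match="empty"):
            tajima_d_for_sites(table, table.sample_ids, np.zeros(1, bool))


class TestFayWuH:
    def test_high_frequency_derived_site_matches_oracle(self):
        # n = 10, one site with derived count 9: pi = 0.2, theta_L = 1
        sfs = np.zeros(9)
        sfs[8] = 1
        h = faywu_h_norm_from_spectrum(10, sfs)
        assert h == pytest.approx(oracle_h_norm(10, list(sfs)), abs=1e-9)
        assert h < 0

    def test_windowed_polarization(self):
        # 5 diploids; derived = alt where outgroup matches ref, else n - a
        geno = np.array([[1] + [2] * 4, [1] + [0] * 4], dtype=np.int8)
        table = make_table(geno, pos=[10, 20])
        og = OutgroupAlleles(alleles=np.array(["A", "G"], dtype="<U1"))
        (w,) = fay_wu_h_norm(table, table.sample_ids, og, 100, {"chr1": 100})
        assert w.S == 2
        # site 1: outgroup=ref, derived count 9; site 2: outgroup=alt, derived 10-1=9
        assert w.sfs[8] == 2
        assert w.faywu_h_norm == pytest.approx(
            oracle_h_norm(10, [0] * 8 + [2]), abs=1e-9
        )

    def test_no_polarizable_sites_is_undefined(self):
        table = make_table([[1, 1]], pos=[10])
        og = OutgroupAlleles(alleles=np.array(["."], dtype="<U1"))
        (w,) = fay_wu_h_norm(table, table.sample_ids, og, 100, {"chr1": 100})
        assert math.isnan(w.faywu_h_norm)
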