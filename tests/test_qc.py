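"""Genotype and sample QC: filters, HWE exact test, pruning, MDS, pi-hat."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossqtl import qc
from crossqtl.simcohort import simulate_genotypes
from crossqtl.types import CohortSpec, DosageMatrix


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-fraction enumeration over all heterozygote counts."""
    from math import factorial

    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (rare - h) // 2
        AA = n - aa - h
        weights[h] = Fraction(2**h * factorial(n),
                              factorial(AA) * factorial(h) * factorial(aa))
    total = sum(weights.values())
    obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestSnpFilter:
    def test_reason_codes_match_planted_violations(self, snp_table):
        out = qc.filter_snps(snp_table)
        assert list(out["reasons"]) == list(snp_table["expected_reasons"])
        assert list(out["kept"]) == [r == "" for r in snp_table["expected_reasons"]]

    def test_idempotent_and_order_independent(self, snp_table):
        once = qc.filter_snps(snp_table)
        twice = qc.filter_snps(once.drop(columns=["kept", "reasons"]))
        assert list(once["reasons"]) == list(twice["reasons"])
        shuffled = qc.filter_snps(snp_table.sample(frac=1, random_state=0))
        merged = shuffled.set_index("snp_id").loc[snp_table["snp_id"]]
        assert list(merged["reasons"]) == list(once["reasons"])


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 1), 1 / 3), ((0, 2, 0), 1.0), ((10, 0, 0), 1.0)],
    )
    def test_small_table_values(self, counts, expected):
        assert qc.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 60))
            n_aa = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_aa + 1))
            n_AA = n - n_aa - n_Aa
            assert qc.hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
            )

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 2, 3)

    def test_equilibrium_counts_not_extreme(self):
        # counts at HWE proportions: observed het count is the modal one
        assert qc.hwe_exact_test(81, 18, 1) > 0.5

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_valid_probability_and_allele_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        p = qc.hwe_exact_test(a, h, b)
        assert 0.0 < p <= 1.0
        # swapping allele labels swaps homozygote classes only
        assert p == pytest.approx(qc.hwe_exact_test(b, h, a), abs=1e-12)


def _dosage_from_matrix(x, chrom="1"):
    m = x.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "B",
            "maf": x.mean(axis=0) / 2,
        }
    )
    return DosageMatrix(x, [f"i{k}" for k in range(x.shape[0])], snps)


class TestLdPrune:
    def test_duplicate_snp_pair_keeps_one(self, rng):
        base = rng.binomial(2, 0.3, 400).astype(float)
        x = np.column_stack([base, base, rng.binomial(2, 0.3, 400)])
        kept = qc.ld_prune(_dosage_from_matrix(x))
        assert kept == ["s0", "s2"]

    def test_independent_snps_mostly_survive(self, small_cohort):
        dosages, _ = small_cohort
        kept = qc.ld_prune(dosages)
        assert len(kept) > 0.95 * dosages.n_snps

    def test_window_schedule_never_co_windows_distant_pair(self, rng):
        # SNPs 51-55 correlate with SNP 1 (r^2 ~ 0.3) but not with each other;
        # under window 50 / step 5 they never share a window with SNP 1.
        n = 4000
        x0 = rng.standard_normal(n)
        cols = [x0] + [rng.standard_normal(n) for _ in range(49)]
        for _ in range(5):
            cols.append(np.sqrt(0.3) * x0 + np.sqrt(0.7) * rng.standard_normal(n))
        x = np.column_stack(cols)
        kept = qc.ld_prune(_dosage_from_matrix(x))
        assert len(kept) == 55

    def test_no_surviving_pair_exceeds_threshold_within_window(self, rng):
        x = rng.binomial(2, 0.3, size=(300, 80)).astype(float)
        # plant heavy LD blocks
        for j in range(0, 60, 3):
            x[:, j + 1] = np.where(rng.random(300) < 0.9, x[:, j], x[:, j + 1])
        dosages = _dosage_from_matrix(x)
        kept = set(qc.ld_prune(dosages))
        idx = [j for j in range(80) if f"s{j}" in kept]
        r2 = np.corrcoef(x[:, idx], rowvar=False) ** 2
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if idx[b] - idx[a] < 50:  # co-windowed at some schedule step
                    assert r2[a, b] <= 0.2 + 1e-9

    def test_zero_variance_snp_kept(self, rng):
        x = np.column_stack([np.full(100, 1.0), rng.binomial(2, 0.4, 100)]).astype(float)
        assert qc.ld_prune(_dosage_from_matrix(x)) == ["s0", "s1"]


class TestIbsMds:
    def test_identical_samples_zero_distance(self, rng):
        g = rng.integers(0, 3, size=(5, 50)).astype(float)
        g[1] = g[0]
        d = qc.ibs_distance_matrix(g)
        assert d[0, 1] == 0.0
        assert d[0, 2] > 0

    def test_component_variances_ordered(self, small_cohort):
        dosages, _ = small_cohort
        res = qc.ibs_mds(dosages)
        assert res.components[:, 0].var() >= res.components[:, 1].var()

    def test_planted_frequency_outliers_flagged(self):
        spec = CohortSpec(100, 1000, maf_range=(0.1, 0.4), seed=9,
                          n_outlier_samples=2, outlier_freq_shift=0.3)
        dosages, info = simulate_genotypes(spec)
        res = qc.ibs_mds(dosages)
        planted = set(info.loc[info["is_outlier"], "sample_id"])
        flagged = {s for s, o in zip(res.sample_ids, res.outlier) if o}
        assert planted <= flagged

    def test_two_population_mixture_separates_on_c1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(17)
        p = rng.uniform(0.2, 0.5, 1000)
        g1 = rng.binomial(2, p, size=(50, 1000)).astype(float)
        g2 = rng.binomial(2, np.clip(p + 0.2, 0, 1), size=(50, 1000)).astype(float)
        dosages = _dosage_from_matrix(np.vstack([g1, g2]))
        res = qc.ibs_mds(dosages)
        labels = [0] * 50 + [1] * 50
        assert silhouette_score(res.components[:, :1], labels) > 0.5

    def test_degenerate_cohort_zero_components(self):
        x = np.full((6, 40), 1.0)
        res = qc.ibs_mds(_dosage_from_matrix(x))
        assert np.allclose(res.components, 0.0, atol=1e-8)
        assert not res.outlier.any()


class TestRelatedness:
    def test_duplicate_pair_pihat_one_and_later_excluded(self):
        spec = CohortSpec(60, 800, maf_range=(0.2, 0.5), seed=21, n_duplicate_pairs=1)
        dosages, _ = simulate_genotypes(spec)
        excluded, results = qc.relatedness_exclude(dosages)
        dup = [r for r in results if {r.sample_a, r.sample_b} == {"s0000", "s0001"}]
        assert dup and dup[0].pihat == pytest.approx(1.0, abs=1e-9)
        assert "s0001" in excluded and "s0000" not in excluded

    def test_unrelated_pairs_near_zero_at_many_snps(self):
        spec = CohortSpec(20, 10_000, maf_range=(0.1, 0.5), seed=22)
        dosages, _ = simulate_genotypes(spec)
        _, results = qc.relatedness_exclude(dosages, threshold=0.05)
        assert all(r.pihat < 0.05 for r in results)  # none should even be flagged
        excluded, _ = qc.relatedness_exclude(dosages)
        assert excluded == []

    def test_threshold_is_strict(self):
        # duplicates give pihat exactly 1.0; threshold 1.0 must retain them
        spec = CohortSpec(40, 500, maf_range=(0.2, 0.5), seed=23, n_duplicate_pairs=1)
        dosages, _ = simulate_genotypes(spec)
        excluded, _ = qc.relatedness_exclude(dosages, threshold=1.0)
        assert excluded == []

    def test_lower_call_rate_member_dropped(self):
        spec = CohortSpec(40, 500, maf_range=(0.2, 0.5), seed=24, n_duplicate_pairs=1)
        dosages, _ = simulate_genotypes(spec)
        excluded, _ = qc.relatedness_exclude(
            dosages, call_rates={"s0000": 0.90, "s0001": 0.99}
        )
        assert "s0000" in excluded

    def test_tiny_panel_skipped_with_warning(self, small_cohort):
        dosages, _ = small_cohort
        sub = DosageMatrix(dosages.dosages[:, :30], dosages.sample_ids,
                           dosages.snps.iloc[:30].reset_index(drop=True))
        with pytest.warns(UserWarning, match="pi-hat"):
            excluded, results = qc.relatedness_exclude(sub)
        assert excluded == [] and results == []


class TestSnpQcStats:
    def test_empirical_stats_sane(self, small_cohort):
        dosages, _ = small_cohort
        out = qc.snp_qc_stats(dosages)
        assert (out["call_rate"] == 1.0).all()
        assert ((out["maf"] >= 0) & (out["maf"] <= 0.5)).all()
        assert ((out["hwe_p"] > 0) & (out["hwe_p"] <= 1)).all()
        # simulated under HWE: very few SNPs should fail a nominal 0.001 test
        assert (out["hwe_p"] < 0.001).mean() < 0.02
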