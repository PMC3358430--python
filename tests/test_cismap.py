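"""cis pairing, dosage regression, BH-FDR, conditional and consensus logic."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from crossqtl import cismap
from crossqtl.simcohort import simulate_covariates, simulate_genotypes
from crossqtl.types import CohortSpec, DosageMatrix


class TestPairCis:
    def snps(self):
        return pd.DataFrame([{"snp_id": "rs1", "chrom": "chr1", "pos": 1_000_000}])

    def probes(self, chrom="1", start=1_499_974):
        # probe midpoint = start + 25.5 (always half-integer for a 50-mer)
        return pd.DataFrame(
            [{"probe_id": "p1", "chrom": chrom, "start": start, "end": start + 50}]
        )

    def test_window_boundary_inclusive(self):
        # midpoint 1,499,999.5 -> distance 499,999.5 <= 500 kb: paired
        paired = cismap.pair_cis(self.snps(), self.probes(start=1_499_974))
        assert len(paired) == 1
        assert paired["distance"].iloc[0] == pytest.approx(499_999.5)

    def test_outside_window_not_paired(self):
        # midpoint 1,500,000.5 -> distance 500,000.5 > 500 kb: not paired
        assert len(cismap.pair_cis(self.snps(), self.probes(start=1_499_975))) == 0

    def test_chromosome_gate_and_dialect_normalization(self):
        # "chr1" vs "1" must match; chrom 2 at numeric distance ~0 must not
        assert len(cismap.pair_cis(self.snps(), self.probes(chrom="1"))) == 1
        assert len(cismap.pair_cis(self.snps(), self.probes(chrom="2", start=999_975))) == 0


class TestMinHomozygoteFilter:
    def dosage_with_homs(self, k):
        d = np.zeros((50, 1))
        d[:k, 0] = 2.0
        d[k : k + 10, 0] = 1.0
        snps = pd.DataFrame(
            {"snp_id": ["s0"], "chrom": "1", "pos": [100], "ref": "A", "alt": "B",
             "maf": [0.2]}
        )
        return DosageMatrix(d, [f"i{j}" for j in range(50)], snps)

    def test_boundary_at_three(self):
        assert not cismap.min_homozygote_filter(self.dosage_with_homs(2), "s0")
        assert cismap.min_homozygote_filter(self.dosage_with_homs(3), "s0")

    def test_common_snp_passes_at_cohort_scale(self):
        spec = CohortSpec(500, 5, maf_range=(0.2, 0.2), seed=3)
        dosages, _ = simulate_genotypes(spec)
        for sid in dosages.snps["snp_id"]:
            assert cismap.min_homozygote_filter(dosages, sid)


class TestFitEqtl:
    def test_hand_computed_slope(self):
        res = cismap.fit_eqtl([1.0, 2.0, 2.0], [0.0, 1.0, 2.0])
        assert res.beta == pytest.approx(0.5)
        assert res.status == "tested"

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        n = 60
        dose = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * dose + rng.standard_normal(n)
        z = rng.standard_normal(n)
        z -= z.mean()
        dose_c = dose - dose.mean()
        z -= (z @ dose_c) / (dose_c @ dose_c) * dose_c  # orthogonalize to dose
        plain = cismap.fit_eqtl(y, dose)
        adjusted = cismap.fit_eqtl(y, dose, pd.DataFrame({"z": z}))
        assert adjusted.beta == pytest.approx(plain.beta, abs=1e-10)

    def test_collinear_design_flagged_not_raised(self, rng):
        n = 30
        dose = np.full(n, 1.0)  # constant dosage
        y = rng.standard_normal(n)
        res = cismap.fit_eqtl(y, dose)
        assert res.status == "collinear"
        assert np.isnan(res.p)

    def test_missing_values_dropped_pairwise(self, rng):
        n = 40
        dose = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * dose + rng.standard_normal(n)
        y[3] = np.nan
        dose[7] = np.nan
        res = cismap.fit_eqtl(y, dose)
        assert res.n_used == n - 2

    def test_matches_statsmodels_on_random_designs(self, rng):
        """Independent cross-check against statsmodels OLS (50 random designs)."""
        for _ in range(50):
            n = int(rng.integers(12, 25))
            k = int(rng.integers(0, 4))
            dose = rng.binomial(2, 0.3, n).astype(float)
            if dose.std() == 0:
                continue
            cov = pd.DataFrame(rng.standard_normal((n, k)),
                               columns=[f"c{j}" for j in range(k)])
            y = rng.standard_normal(n)
            mine = cismap.fit_eqtl(y, dose, cov if k else None)
            X = sm.add_constant(np.column_stack([dose] + ([cov.to_numpy()] if k else [])))
            ref = sm.OLS(y, X).fit()
            assert mine.beta == pytest.approx(ref.params[1], abs=1e-10)
            assert mine.se == pytest.approx(ref.bse[1], abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        n, reps = 50, 2000
        hits = 0
        dose = rng.binomial(2, 0.3, size=(reps, n)).astype(float)
        ys = rng.standard_normal((reps, n))
        for i in range(reps):
            res = cismap.fit_eqtl(ys[i], dose[i])
            hits += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * se

    def test_invariant_to_sample_order(self, rng):
        n = 80
        dose = rng.binomial(2, 0.25, n).astype(float)
        y = 0.3 * dose + rng.standard_normal(n)
        cov = pd.DataFrame({"age": rng.normal(70, 8, n)})
        a = cismap.fit_eqtl(y, dose, cov)
        perm = rng.permutation(n)
        b = cismap.fit_eqtl(y[perm], dose[perm], cov.iloc[perm].reset_index(drop=True))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        out = cismap.bh_fdr([0.01, 0.03, 0.04])
        assert list(out["q"]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert cismap.bh_fdr([0.2])["q"].iloc[0] == pytest.approx(0.2)
        assert (cismap.bh_fdr([1.0, 1.0, 1.0])["q"] == 1.0).all()
        assert len(cismap.bh_fdr([])) == 0

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=200)
        out = cismap.bh_fdr(p)
        assert (out["q"] >= out["p"] - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(out["q"].to_numpy()[order]) >= -1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            cismap.bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=30)
    )
    def test_step_up_properties_hold_for_any_pvector(self, pvals):
        out = cismap.bh_fdr(pvals)
        assert ((out["q"] >= out["p"] - 1e-15) & (out["q"] <= 1.0)).all()
        order = np.argsort(out["p"].to_numpy(), kind="stable")
        assert (np.diff(out["q"].to_numpy()[order]) >= -1e-15).all()


class TestConditionalFit:
    def test_identical_proxy_collinear(self, rng):
        dose = rng.binomial(2, 0.3, 40).astype(float)
        y = rng.standard_normal(40)
        res = cismap.conditional_fit(y, dose, dose)
        assert res.conditional.status == "collinear"
        assert res.marginal.status == "tested"

    def test_independent_proxy_leaves_beta(self, rng):
        n = 300
        dose = rng.binomial(2, 0.3, n).astype(float)
        proxy = rng.binomial(2, 0.3, n).astype(float)
        y = 0.5 * dose + rng.standard_normal(n)
        res = cismap.conditional_fit(y, dose, proxy)
        assert abs(res.conditional.beta - res.marginal.beta) < 2 * res.marginal.se

    def test_haplotype_tagged_signal_attenuates_under_conditioning(self):
        """Effect through a proxy in LD (r^2 ~ 0.8): conditional p rises."""
        n, reps = 400, 50
        weaker = 0
        for rep in range(reps):
            rng = np.random.default_rng(900 + rep)
            proxy = rng.binomial(2, 0.5, n).astype(float)
            # dose = proxy with 10% of entries resampled -> r^2 about 0.8
            dose = proxy.copy()
            flip = rng.random(n) < 0.10
            dose[flip] = rng.binomial(2, 0.5, int(flip.sum()))
            y = 0.5 * proxy + rng.standard_normal(n)
            res = cismap.conditional_fit(y, dose, proxy)
            weaker += res.conditional.p > res.marginal.p
        assert weaker >= 0.95 * reps


class TestConsensus:
    def results(self, tissue, pairs_status):
        rows = []
        for (s, pr), status in pairs_status.items():
            rows.append(
                {"snp_id": s, "probe_id": pr, "tissue": tissue, "n_used": 100,
                 "beta": 0.1, "se": 0.1, "t_stat": 1.0, "p": 0.3, "q": 0.5,
                 "status": status}
            )
        return pd.DataFrame(rows)

    def test_pair_tested_everywhere_in_consensus(self):
        by_tissue = {
            t: self.results(t, {("s1", "p1"): "tested", ("s2", "p2"): "tested"})
            for t in ("blood", "frontal_cortex", "cerebellum")
        }
        consensus, complement = cismap.consensus_set(by_tissue)
        assert len(consensus) == 2 and len(complement) == 0

    def test_undetected_in_blood_goes_to_complement(self):
        by_tissue = {
            "blood": self.results(
                "blood", {("s1", "p1"): "excluded_undetected", ("s2", "p2"): "tested"}
            ),
            "cerebellum": self.results(
                "cerebellum", {("s1", "p1"): "tested", ("s2", "p2"): "tested"}
            ),
        }
        consensus, complement = cismap.consensus_set(by_tissue)
        assert list(consensus["snp_id"]) == ["s2"]
        assert list(complement["tested_in"]) == ["cerebellum"]

    def test_empty_overlap(self):
        by_tissue = {
            "blood": self.results("blood", {("s1", "p1"): "tested"}),
            "cerebellum": self.results("cerebellum", {("s2", "p2"): "tested"}),
        }
        consensus, complement = cismap.consensus_set(by_tissue)
        assert len(consensus) == 0 and len(complement) == 2

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            cismap.consensus_set({"blood": self.results("blood", {})})


class TestScanTissue:
    def test_scan_orders_and_adjusts_within_tested_family(self, small_cohort, covariates200):
        dosages, _ = small_cohort
        rng = np.random.default_rng(77)
        probes = [f"pr{j}" for j in range(20)]
        vals = pd.DataFrame(rng.normal(8, 1, size=(20, 200)),
                            index=probes, columns=dosages.sample_ids)
        pairs = pd.DataFrame(
            {"snp_id": dosages.snps["snp_id"].iloc[:20].to_numpy(),
             "probe_id": probes, "distance": 0}
        )
        out = cismap.scan_tissue(dosages, vals, pairs, covariates200, "blood")
        tested = out[out["status"] == "tested"]
        assert len(tested) > 0
        assert (tested["q"] >= tested["p"] - 1e-12).all()
        # shuffled pair order produces identical sorted output
        out2 = cismap.scan_tissue(
            dosages, vals, pairs.sample(frac=1, random_state=0), covariates200, "blood"
        )
        pd.testing.assert_frame_equal(out, out2)
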