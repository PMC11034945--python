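import numpy as np
import pandas as pd
import pytest

from epipair import peaks_counts as pc
from epipair.io_cli.formats import GenomicInterval, Peak


def peak(chrom, start, end, summit=None, score=1.0):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit=(start + end) // 2 if summit is None else summit,
        score=score,
    )


class TestCallPeaksPoisson:
    def test_flat_coverage_empty(self):
        assert pc.call_peaks_poisson({"chr1": np.full(5000, 2.0)}) == []

    def test_all_zero_empty_not_error(self):
        assert pc.call_peaks_poisson({"chr1": np.zeros(1000)}) == []

    def test_single_spike(self):
        cov = np.ones(10_000)
        cov[3000:3300] = 10.0
        cov[3100] = 15.0
        peaks = pc.call_peaks_poisson({"chr1": cov}, bin_width=1)
        assert len(peaks) == 1
        (pk,) = peaks
        assert pk.interval.start <= 3000 and pk.interval.end >= 3300
        assert pk.summit == 3100

    def test_two_close_spikes_merged(self):
        cov = np.ones(10_000)
        cov[2000:2100] = 12.0
        cov[2150:2250] = 12.0  # 50 bp gap < 100 bp merge rule
        peaks = pc.call_peaks_poisson({"chr1": cov}, bin_width=1)
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 2000 and peaks[0].interval.end >= 2250

    def test_distant_spikes_not_merged(self):
        cov = np.ones(20_000)
        cov[2000:2100] = 15.0
        cov[12_000:12_100] = 15.0
        peaks = pc.call_peaks_poisson({"chr1": cov}, bin_width=1)
        assert len(peaks) == 2


class TestHighConfidence:
    def test_union_merge(self):
        out = pc.high_confidence_peaks(
            [peak("chr1", 100, 200, score=2)], [peak("chr1", 150, 250, score=1)]
        )
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 250)
        assert out[0].summit == 150  # from the higher-score rep1 peak

    def test_disjoint_replicates_empty(self):
        assert pc.high_confidence_peaks(
            [peak("chr1", 0, 100)], [peak("chr1", 500, 600)]
        ) == []

    def test_partial_overlap_counts(self):
        rep1 = [peak("chr1", 0, 100), peak("chr1", 1000, 1100), peak("chr1", 5000, 5100)]
        rep2 = [peak("chr1", 50, 150), peak("chr1", 1050, 1150)]
        assert len(pc.high_confidence_peaks(rep1, rep2)) == 2


class TestConsensusMaster:
    def test_identical_sets(self):
        s = [peak("chr1", 0, 100), peak("chr1", 500, 700)]
        master = pc.consensus_master([s, s, s])
        assert [(p.interval.start, p.interval.end) for p in master.peaks] == [
            (0, 100), (500, 700)
        ]
        assert master.support == [3, 3]

    def test_transitive_chain(self):
        sets = [
            [peak("chr1", 0, 100)],
            [peak("chr1", 50, 150)],
            [peak("chr1", 140, 200)],
        ]
        master = pc.consensus_master(sets)
        assert len(master) == 1
        assert (master.peaks[0].interval.start, master.peaks[0].interval.end) == (0, 200)

    def test_single_sample_identity(self):
        s = [peak("chr1", 10, 90)]
        master = pc.consensus_master([s])
        assert [(p.interval.start, p.interval.end) for p in master.peaks] == [(10, 90)]

    def test_invariant_to_sample_order(self):
        sets = [
            [peak("chr1", 0, 100), peak("chr2", 0, 50)],
            [peak("chr1", 80, 300)],
            [peak("chr2", 40, 90)],
        ]
        a = pc.consensus_master(sets)
        b = pc.consensus_master(sets[::-1])
        assert [(p.interval.chrom, p.interval.start, p.interval.end) for p in a.peaks] == [
            (p.interval.chrom, p.interval.start, p.interval.end) for p in b.peaks
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pc.consensus_master([])


class TestCountMatrixBuild:
    def master(self):
        return pc.MasterPeakSet([peak("chr1", 0, 100), peak("chr1", 200, 300)], [1, 1])

    def test_input_subtraction(self):
        mat = pc.count_matrix(
            {"s1": np.array([10, 8])},
            self.master(),
            {"s1": 100},
            input_controls={"s1": np.array([3, 2])},
        )
        np.testing.assert_array_equal(mat.counts[:, 0], [7, 6])

    def test_min_count_floor(self):
        mat = pc.count_matrix(
            {"s1": np.array([2, 10])},
            self.master(),
            {"s1": 100},
            input_controls={"s1": np.array([5, 1])},
            min_count=1,
        )
        assert mat.counts[0, 0] == 1

    def test_no_input_raw(self):
        mat = pc.count_matrix({"s1": np.array([4, 9])}, self.master(), {"s1": 100})
        np.testing.assert_array_equal(mat.counts[:, 0], [4, 9])

    def test_missing_input_control(self):
        with pytest.raises(ValueError):
            pc.count_matrix(
                {"s1": np.array([1, 2])}, self.master(), {"s1": 10}, input_controls={}
            )

    def test_library_size_invariant(self):
        with pytest.raises(ValueError):
            pc.CountMatrix(["f1"], ["s1"], np.array([[10]]), {"s1": 5})


def tmm_oracle(counts, libs, ref_idx, trim_m=0.30, trim_a=0.05):
    """Independent direct implementation over explicit M/A lists."""
    factors = []
    for j in range(counts.shape[1]):
        obs, ref = counts[:, j].astype(float), counts[:, ref_idx].astype(float)
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / libs[j]) / (r / libs[ref_idx]))
        a = 0.5 * np.log2((o / libs[j]) * (r / libs[ref_idx]))
        w = 1.0 / ((libs[j] - o) / (libs[j] * o) + (libs[ref_idx] - r) / (libs[ref_idx] * r))
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        from scipy.stats import rankdata

        rm, ra = rankdata(m), rankdata(a)
        k = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(np.sum(w[k] * m[k]) / np.sum(w[k]) if k.any() else 0.0)
    factors = np.array(factors)
    return 2.0 ** (factors - factors.mean())


class TestTMM:
    def make(self, counts, libs=None):
        counts = np.asarray(counts)
        if libs is None:
            libs = counts.sum(axis=0) * 10
        return pc.CountMatrix(
            [f"f{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
            {f"s{j}": int(libs[j]) for j in range(counts.shape[1])},
        )

    def test_identical_columns(self):
        mat = self.make(np.array([[10, 10], [20, 20], [35, 35], [5, 5]]))
        factors = pc.tmm_factors(mat)
        assert factors["s0"] == pytest.approx(1.0, abs=1e-9)
        assert factors["s1"] == pytest.approx(1.0, abs=1e-9)

    def test_doubled_column_absorbed_by_library_size(self):
        base = np.array([[10], [20], [35], [5], [50], [8]])
        counts = np.hstack([base, base * 2])
        mat = self.make(counts, libs=[counts[:, 0].sum() * 10, counts[:, 1].sum() * 10])
        factors = pc.tmm_factors(mat)
        assert factors["s0"] == pytest.approx(1.0, abs=1e-6)
        assert factors["s1"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(50, size=(40, 3)) + 1
        libs = counts.sum(axis=0) * 20
        mat = self.make(counts, libs)
        got = pc.tmm_factors(mat)
        # locate the reference column the implementation picks
        q75 = np.array([np.quantile(counts[:, j] / libs[j], 0.75) for j in range(3)])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
        expected = tmm_oracle(counts, libs, ref_idx)
        for j in range(3):
            assert got[f"s{j}"] == pytest.approx(expected[j], abs=1e-8)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, size=(60, 5)) + 1
        mat = self.make(counts)
        factors = np.array(list(pc.tmm_factors(mat).values()))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_column_rejected(self):
        mat = self.make(np.array([[0, 5], [0, 3]]), libs=[10, 100])
        with pytest.raises(ValueError):
            pc.tmm_factors(mat)


class TestFilterLow:
    def make(self, rows):
        counts = np.asarray(rows)
        return pc.CountMatrix(
            [f"f{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
            {f"s{j}": int(counts[:, j].sum() * 10 + 1) for j in range(counts.shape[1])},
        )

    def test_three_of_four_low_removed(self):
        out = pc.filter_low(self.make([[19, 19, 19, 25]]))
        assert out.feature_ids == []

    def test_half_low_kept_strict_inequality(self):
        out = pc.filter_low(self.make([[19, 19, 25, 25]]))
        assert out.feature_ids == ["f0"]

    def test_all_high_identity(self):
        mat = self.make([[20, 30], [50, 21]])
        out = pc.filter_low(mat)
        np.testing.assert_array_equal(out.counts, mat.counts)

    def test_idempotent(self):
        mat = self.make([[19, 19, 19, 25], [25, 25, 25, 25], [19, 19, 25, 25]])
        once = pc.filter_low(mat)
        twice = pc.filter_low(once)
        assert once.feature_ids == twice.feature_ids
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestPCCovariates:
    def test_covariate_equal_to_pc1_selected(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 30))
        vals[0] += np.linspace(-5, 5, 30)  # strong PC1 direction
        scores = pc.pc_scores(vals, 1)
        cov = pd.DataFrame({"c": scores[:, 0]})
        assert pc.pc_covariate_select(vals, cov, n_pcs=3) == ["c"]

    def test_independent_noise_not_selected(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(100, 50))
        cov = pd.DataFrame({"noise": rng.normal(size=50)})
        assert pc.pc_covariate_select(vals, cov, n_pcs=3) == []

    def test_constant_covariate_warned_not_error(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(20, 10))
        cov = pd.DataFrame({"const": np.ones(10)})
        with pytest.warns(UserWarning):
            assert pc.pc_covariate_select(vals, cov, n_pcs=2) == []


class TestRegressOut:
    def test_orthogonal_covariate_identity(self):
        rng = np.random.default_rng(4)
        n = 20
        cov_vec = rng.normal(size=n)
        cov_vec -= cov_vec.mean()
        vals = rng.normal(size=(5, n))
        # project features orthogonal to the covariate
        vals -= (vals @ cov_vec)[:, None] * cov_vec[None, :] / (cov_vec @ cov_vec)
        out = pc.regress_out(vals, pd.DataFrame({"c": cov_vec}))
        np.testing.assert_allclose(out, vals, atol=1e-10)

    def test_feature_proportional_to_covariate(self):
        cov_vec = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = (2 * cov_vec)[None, :]
        out = pc.regress_out(vals, pd.DataFrame({"c": cov_vec}))
        np.testing.assert_allclose(out, np.full((1, 5), vals.mean()), atol=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        n = 5
        cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        vals = rng.normal(size=(3, n))
        X = np.column_stack([np.ones(n), cov["a"], cov["b"]])
        beta = np.linalg.inv(X.T @ X) @ X.T @ vals.T
        expected = (vals.T - X @ beta).T + vals.mean(axis=1, keepdims=True)
        out = pc.regress_out(vals, cov)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(6)
        n = 30
        cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        vals = rng.normal(size=(10, n))
        out = pc.regress_out(vals, cov)
        resid = out - out.mean(axis=1, keepdims=True)
        for c in cov.columns:
            v = cov[c].to_numpy() - cov[c].mean()
            dots = np.abs(resid @ v)
            assert (dots < 1e-8 * np.linalg.norm(v) * np.linalg.norm(resid, axis=1) + 1e-12).all()

    def test_rank_deficient_design_rejected(self):
        cov = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="rank"):
            pc.regress_out(np.random.default_rng(0).normal(size=(2, 4)), cov)

    def test_null_pcs_uncorrelated_after_regression(self):
        rng = np.random.default_rng(7)
        n = 60
        cov = pd.DataFrame({"a": rng.normal(size=n)})
        vals = rng.normal(size=(200, n)) + 2.0 * cov["a"].to_numpy()[None, :]
        out = pc.regress_out(vals, cov)
        scores = pc.pc_scores(out, 3)
        for k in range(scores.shape[1]):
            r = np.corrcoef(scores[:, k], cov["a"])[0, 1]
            assert abs(r) < 0.05
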