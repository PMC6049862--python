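"""Normalization and differential-expression behaviour."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncscape.config import DEThresholds
from lncscape.de import (bh_adjust, differential_expression, flag_filter,
                         quantile_normalize, size_factors)

from conftest import make_matrix


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = make_matrix(np.tile([[1.0], [5.0], [3.0]], (1, 4)), n_tumor=2)
        out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_single_column_identity(self):
        m = make_matrix([[4.0], [1.0], [2.0]], n_tumor=1)
        assert np.allclose(quantile_normalize(m).values, m.values)

    def test_two_column_hand_example(self):
        # columns (1,3) and (4,2): sorted row means (1.5, 3.5)
        m = make_matrix([[1.0, 4.0], [3.0, 2.0]], n_tumor=1)
        out = quantile_normalize(m).values.to_numpy()
        assert np.allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_ties_get_mean_of_target_values(self):
        # column 0 all-tied: each entry takes the mean of the whole target
        m = make_matrix([[2.0, 1.0], [2.0, 5.0], [2.0, 9.0]], n_tumor=1)
        out = quantile_normalize(m).values.to_numpy()
        target = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        assert np.allclose(out[:, 0], target.mean())
        assert np.allclose(np.sort(out[:, 1]), target)

    def test_empty_matrix_is_error(self):
        m = make_matrix(np.empty((0, 0)), n_tumor=0)
        with pytest.raises(ValueError):
            quantile_normalize(m)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_share_sorted_multiset(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(17, 5)), n_tumor=3)
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = make_matrix(np.tile([[10.0], [20.0]], (1, 3)), n_tumor=2,
                        scale="linear_count")
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_closed_form(self):
        # B = 2A over 2 features: factors (1/sqrt(2), sqrt(2))
        m = make_matrix([[10.0, 20.0], [30.0, 60.0]], n_tumor=1,
                        scale="linear_count")
        assert np.allclose(size_factors(m), [2 ** -0.5, 2 ** 0.5])

    def test_invariant_under_feature_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 1000, size=(20, 5)).astype(float)
        m = make_matrix(X, n_tumor=3, scale="linear_count")
        perm = rng.permutation(20)
        mp = make_matrix(X[perm], n_tumor=3, scale="linear_count")
        assert np.allclose(size_factors(m), size_factors(mp))

    def test_no_all_positive_feature_is_error(self):
        m = make_matrix([[0.0, 5.0], [5.0, 0.0]], n_tumor=1,
                        scale="linear_count")
        with pytest.raises(ValueError, match="geometric-mean"):
            size_factors(m)

    def test_matches_deseq2_reference(self, tmp_path):
        """Median-of-ratios agrees with DESeq2's estimator on a small matrix."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(5)
        X = rng.integers(1, 500, size=(30, 4)).astype(float)
        np.savetxt(tmp_path / "m.tsv", X, delimiter="\t")
        script = tmp_path / "sf.R"
        script.write_text(
            'suppressMessages(library(DESeq2));'
            f'm <- as.matrix(read.table("{tmp_path}/m.tsv"));'
            'cat(estimateSizeFactorsForMatrix(m), sep="\\n")\n')
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = np.array([float(x) for x in res.stdout.split()])
        ours = size_factors(make_matrix(X, n_tumor=2, scale="linear_count"))
        assert np.allclose(ours, ref, rtol=1e-6)


class TestFlagFilter:
    def test_all_absent_feature_removed(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0]], n_tumor=1,
                        flags=[["Absent", "Absent"], ["Present", "Present"]])
        out = flag_filter(m, min_present=1)
        assert out.feature_ids == ["F1"]

    def test_boundary_is_inclusive(self):
        flags = [["Present", "Marginal", "Absent"]]
        m = make_matrix([[1.0, 2.0, 3.0]], n_tumor=2, flags=flags)
        assert flag_filter(m, min_present=2).feature_ids == ["F0"]
        assert flag_filter(m, min_present=3).feature_ids == []

    def test_no_flags_is_warned_noop(self):
        m = make_matrix([[1.0, 2.0]], n_tumor=1)
        with pytest.warns(UserWarning, match="flag filter skipped"):
            out = flag_filter(m, 7)
        assert out.feature_ids == m.feature_ids

    def test_random_fixture_matches_count_oracle(self):
        rng = np.random.default_rng(9)
        labels = np.array(["Present", "Marginal", "Absent"])
        flags = labels[rng.integers(0, 3, size=(20, 28))]
        m = make_matrix(rng.normal(size=(20, 28)), n_tumor=19, flags=flags)
        kept = set(flag_filter(m, min_present=7).feature_ids)
        oracle = {f"F{i}" for i in range(20)
                  if sum(1 for v in flags[i] if v in ("Present", "Marginal"))
                  >= 7}
        assert kept == oracle


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=60)
        # independent oracle: sort, scale by m/rank, enforce monotonicity
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj, 1.0)
        assert np.allclose(bh_adjust(p), oracle)


class TestDifferentialExpression:
    def test_identical_group_means_unchanged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        X = np.tile(base, (8, 1)).T + rng.normal(scale=1e-6, size=(6, 8))
        m = make_matrix(X, n_tumor=4)
        res = differential_expression(m, DEThresholds(fc=1.5, p=0.05))
        assert all(abs(r.log2_fc) < 1e-4 for r in res)
        assert all(r.direction == "unchanged" for r in res)

    def test_zero_variance_gives_p_one_with_warning(self):
        X = np.vstack([[5.0] * 8, np.arange(8.0)])
        m = make_matrix(X, n_tumor=4)
        with pytest.warns(UserWarning, match="zero variance"):
            res = differential_expression(m, DEThresholds())
        assert res[0].p_value == 1.0

    def test_label_symmetry(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 12))
        m = make_matrix(X, n_tumor=5)
        swapped = make_matrix(np.hstack([X[:, 5:], X[:, :5]]), n_tumor=7)
        a = differential_expression(m, DEThresholds())
        b = differential_expression(swapped, DEThresholds())
        assert np.allclose([r.log2_fc for r in a],
                           [-r.log2_fc for r in b])
        assert np.allclose([r.p_value for r in a], [r.p_value for r in b])

    def test_null_type_one_rate_near_nominal(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(2000, 20)), n_tumor=10)
        res = differential_expression(m, DEThresholds())
        frac = np.mean([r.p_value < 0.05 for r in res])
        # binomial sd at n=2000 is ~0.005; allow 4 sd
        assert abs(frac - 0.05) < 0.02

    def test_planted_fourfold_features_recovered(self):
        # within-group log2 sd of 0.5, the typical microarray noise level
        rng = np.random.default_rng(8)
        X = rng.normal(8.0, 0.5, size=(1000, 20))
        X[:50, :10] += 2.0  # 4-fold up in the 10 tumor samples
        m = make_matrix(X, n_tumor=10)
        res = differential_expression(m, DEThresholds(fc=2.0, p=0.05,
                                                      use_fdr=True))
        called = {r.feature_id for r in res if r.direction == "up"}
        planted = {f"F{i}" for i in range(50)}
        assert len(called & planted) / 50 >= 0.90
        false_calls = {r.feature_id for r in res if r.direction != "unchanged"
                       } - planted
        n_called = len(called & planted) + len(false_calls)
        assert len(false_calls) / max(n_called, 1) <= 0.10  # 2x nominal FDR
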