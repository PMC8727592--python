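"""Validation metrics: rescaling, MSE, Bland-Altman, invariant probes,
pooling regression, MDS."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from baldeconv import (
    BetaMatrix,
    ProportionTable,
    ValidationError,
    bland_altman,
    classical_mds,
    generate_mixtures,
    invariant_probe_check,
    mse,
    pooling_variance_regression,
    scale_flow_proportions,
)

CELL_TYPES = ["AlveolarMacrophage", "Lymphocyte", "Granulocyte", "AEC"]


def _table(rows, index, scale="percent", columns=None):
    return ProportionTable(
        pd.DataFrame(rows, index=index, columns=columns or CELL_TYPES),
        scale=scale,
    )


class TestScaleFlowProportions:
    def test_macrophage_dominant_sample(self):
        # unscaled cytometry with a large DNA-free fraction
        scaled = scale_flow_proportions(np.array([50.2, 5.0, 13.6, 0.4]))
        np.testing.assert_allclose(
            np.round(scaled, 1), [72.5, 7.2, 19.7, 0.6]
        )

    def test_granulocyte_rich_sample(self):
        scaled = scale_flow_proportions(np.array([46.1, 7.4, 26.9, 2.4]))
        np.testing.assert_allclose(
            np.round(scaled, 1), [55.7, 8.9, 32.5, 2.9]
        )

    def test_already_normalized_is_fixed_point(self):
        out = scale_flow_proportions(np.array([25.0, 25.0, 25.0, 25.0]))
        np.testing.assert_allclose(out, [25.0, 25.0, 25.0, 25.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            scale_flow_proportions(np.zeros(4))

    def test_frame_input_scales_each_row(self):
        df = pd.DataFrame([[10.0, 10.0], [30.0, 10.0]], columns=["A", "B"],
                          index=["s1", "s2"])
        out = scale_flow_proportions(df)
        np.testing.assert_allclose(out.loc["s1"], [50.0, 50.0])
        np.testing.assert_allclose(out.loc["s2"], [75.0, 25.0])

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=6)
    )
    def test_output_always_sums_to_100(self, values):
        out = scale_flow_proportions(np.asarray(values))
        assert abs(out.sum() - 100.0) < 1e-9


class TestMSE:
    def test_identical_tables_give_zero(self):
        t = _table([[50, 10, 35, 5]], ["s1"])
        assert mse(t, t, by="cell_type").max() == 0.0

    def test_granulocyte_rich_subject_mse_near_006(self):
        # flow truth over all cells vs a methylation estimate that sees only
        # the DNA-bearing types: the discrepancy lands near 0.06
        truth = _table([[2.4, 2.5, 39.7, 1.5]], ["CF1"])
        est = _table([[0.7, 1.6, 88.8, 9.2]], ["CF1"])
        value = mse(truth, est, by="subject")["CF1"]
        assert round(value, 2) == 0.06

    def test_matches_hand_summed_oracle(self):
        rng = np.random.default_rng(71)
        t = rng.random((6, 4))
        e = rng.random((6, 4))
        idx = [f"s{i}" for i in range(6)]
        truth = _table(t * 100, idx)
        est = _table(e * 100, idx)
        by_ct = mse(truth, est, by="cell_type")
        by_subj = mse(truth, est, by="subject")
        np.testing.assert_allclose(
            by_ct.to_numpy(), ((e - t) ** 2).mean(axis=0), atol=1e-12
        )
        np.testing.assert_allclose(
            by_subj.to_numpy(), ((e - t) ** 2).mean(axis=1), atol=1e-12
        )
        # with equal counts the two groupings share the same grand mean
        assert by_ct.mean() == pytest.approx(by_subj.mean())

    def test_misaligned_tables_rejected(self):
        t = _table([[50, 10, 35, 5]], ["s1"])
        e = _table([[50, 10, 35, 5]], ["other"])
        with pytest.raises(Exception, match="share"):
            mse(t, e)


class TestBlandAltman:
    def test_identical_inputs_zero_bias_zero_limits(self):
        t = _table([[50, 10, 35, 5], [40, 20, 30, 10]], ["s1", "s2"])
        ba = bland_altman(t, t)
        assert ba.summary.loc["overall", "bias"] == 0.0
        assert ba.summary.loc["overall", "lo"] == 0.0
        assert ba.summary.loc["overall", "hi"] == 0.0

    def test_constant_offset(self):
        t = _table([[50, 10, 30, 10], [40, 20, 30, 10]], ["s1", "s2"])
        shifted = ProportionTable(t.data + 10.0, scale="percent")
        ba = bland_altman(t, shifted)
        assert ba.summary.loc["overall", "bias"] == pytest.approx(0.1)
        assert ba.summary.loc["overall", "sd"] == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(72)
        t = rng.random((5, 4))
        e = rng.random((5, 4))
        idx = [f"s{i}" for i in range(5)]
        ba = bland_altman(_table(t * 100, idx), _table(e * 100, idx))
        diffs = (e - t).ravel()
        bias = diffs.mean()
        sd = diffs.std(ddof=1)
        assert ba.summary.loc["overall", "bias"] == pytest.approx(bias)
        assert ba.summary.loc["overall", "lo"] == pytest.approx(bias - 1.96 * sd)
        assert ba.summary.loc["overall", "hi"] == pytest.approx(bias + 1.96 * sd)
        # limits symmetric about bias
        mid = (ba.summary["lo"] + ba.summary["hi"]) / 2
        np.testing.assert_allclose(mid, ba.summary["bias"], atol=1e-12)


class TestInvariantProbeCheck:
    def _reference(self, sheet_factory):
        probes = ["cg_high", "cg_partial", "cg_low", "cg_mid"]
        data = pd.DataFrame(
            {
                "a1": [0.99, 0.99, 0.01, 0.5],
                "a2": [0.99, 0.99, 0.02, 0.5],
                "b1": [0.98, 0.50, 0.01, 0.5],
                "b2": [0.97, 0.50, 0.03, 0.5],
            },
            index=probes,
        )
        sheet = sheet_factory({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        return BetaMatrix(data), sheet

    def test_selects_stable_probes_only(self, sheet_factory):
        beta, sheet = self._reference(sheet_factory)
        mix = BetaMatrix(
            pd.DataFrame({"m1": [0.97, 0.6, 0.02, 0.5]}, index=beta.probe_ids)
        )
        check = invariant_probe_check(beta, sheet, mix)
        assert set(check.probe_ids) == {"cg_high", "cg_low"}
        assert check.side["cg_high"] == "high"
        assert check.consistency["m1"] == 1.0

    def test_relaxing_thresholds_never_shrinks_set(self, sheet_factory):
        beta, sheet = self._reference(sheet_factory)
        mix = BetaMatrix(
            pd.DataFrame({"m1": [0.97, 0.6, 0.02, 0.5]}, index=beta.probe_ids)
        )
        strict = invariant_probe_check(beta, sheet, mix, hi=0.99, lo=0.01)
        relaxed = invariant_probe_check(beta, sheet, mix, hi=0.9, lo=0.1)
        assert set(strict.probe_ids) <= set(relaxed.probe_ids)

    def test_consistency_high_on_pure_four_type_mixtures(
        self, profiles, exact_reference
    ):
        beta, sheet = exact_reference
        mixtures, _ = generate_mixtures(profiles, 6, noise_precision=200, seed=73)
        check = invariant_probe_check(beta, sheet, mixtures)
        assert len(check.probe_ids) > 0
        assert (check.consistency > 0.99).all()


class TestPoolingVarianceRegression:
    def _beta_with_sizes(self, variances, sizes, sheet_factory, seed=0):
        rng = np.random.default_rng(seed)
        n = 2000
        cols, assign, rows = {}, {}, []
        frames = []
        for i, (v, s) in enumerate(zip(variances, sizes)):
            sid = f"p{i}"
            vals = np.clip(rng.normal(0.5, np.sqrt(v), n), 0, 1)
            cols[sid] = vals
            rows.append({"sample_id": sid, "role": "reference",
                         "cell_type": "AM", "pool_size": s, "batch": ""})
        beta = BetaMatrix(
            pd.DataFrame(cols, index=[f"cg{i}" for i in range(n)])
        )
        from baldeconv import SampleSheet

        return beta, SampleSheet(pd.DataFrame(rows))

    def test_constant_variance_is_null(self, sheet_factory):
        # identical variance across pools: no association
        cols = {f"p{i}": np.tile([0.3, 0.7], 500) for i in range(4)}
        beta = BetaMatrix(pd.DataFrame(cols, index=[f"cg{i}" for i in range(1000)]))
        from baldeconv import SampleSheet

        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": f"p{i}", "role": "reference", "cell_type": "AM",
              "pool_size": s, "batch": ""} for i, s in enumerate([1, 2, 3, 6])]
        ))
        reg = pooling_variance_regression(beta, sheet)
        assert reg.slope == 0.0
        assert reg.p_value > 0.9

    def test_exactly_linear_variance_has_adj_r2_one(self, sheet_factory):
        sizes = [1, 2, 3, 6, 12]
        variances = [0.01 + 0.002 * s for s in sizes]
        beta, sheet = self._beta_with_sizes(variances, sizes, sheet_factory, seed=74)
        # overwrite observed variances with the exact linear values by
        # rescaling each column around its mean
        for sid, v in zip(beta.sample_ids, variances):
            col = beta.data[sid]
            observed = col.var(ddof=1)
            beta.data[sid] = 0.5 + (col - col.mean()) * np.sqrt(v / observed)
        reg = pooling_variance_regression(beta, sheet)
        assert reg.adj_r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_simple_regression(self, sheet_factory):
        sizes = [1, 2, 3, 5, 6, 12]
        rng = np.random.default_rng(75)
        variances = list(0.005 + 0.01 * rng.random(6))
        beta, sheet = self._beta_with_sizes(variances, sizes, sheet_factory, seed=76)
        reg = pooling_variance_regression(beta, sheet)
        x = np.asarray(sizes, dtype=float)
        y = beta.data.var(axis=0, ddof=1).to_numpy()
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        df = len(x) - 2
        s2 = np.sum(resid**2) / df
        t = slope / np.sqrt(s2 / sxx)
        from scipy import stats as sps

        p = 2 * sps.t.sf(abs(t), df)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        adj = 1 - (1 - r2) * (len(x) - 1) / df
        assert reg.slope == pytest.approx(slope, abs=1e-9)
        assert reg.p_value == pytest.approx(p, abs=1e-9)
        assert reg.adj_r_squared == pytest.approx(adj, abs=1e-9)

    def test_requires_varying_pool_sizes(self, sheet_factory):
        cols = {f"p{i}": np.linspace(0, 1, 10) for i in range(3)}
        beta = BetaMatrix(pd.DataFrame(cols, index=[f"cg{i}" for i in range(10)]))
        from baldeconv import SampleSheet

        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": f"p{i}", "role": "reference", "cell_type": "AM",
              "pool_size": 3, "batch": ""} for i in range(3)]
        ))
        with pytest.raises(ValidationError, match="vary"):
            pooling_variance_regression(beta, sheet)


class TestClassicalMDS:
    def test_three_equidistant_samples_form_equilateral_triangle(self):
        # three samples at equal pairwise distance d
        data = pd.DataFrame(
            {
                "s1": [1.0, 0.0, 0.0],
                "s2": [0.0, 1.0, 0.0],
                "s3": [0.0, 0.0, 1.0],
            },
            index=["cg1", "cg2", "cg3"],
        )
        res = classical_mds(BetaMatrix(data), top_n_variable=3, n_dims=2)
        coords = res.coordinates.to_numpy()
        d = np.sqrt(2.0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(d, abs=1e-9)

    def test_duplicated_sample_coincides(self):
        rng = np.random.default_rng(77)
        vals = rng.random((20, 3))
        vals[:, 2] = vals[:, 0]
        data = pd.DataFrame(vals, index=[f"cg{i}" for i in range(20)],
                            columns=["s1", "s2", "s1b"])
        res = classical_mds(BetaMatrix(data), top_n_variable=20, n_dims=2)
        assert np.allclose(res.coordinates.loc["s1"], res.coordinates.loc["s1b"],
                           atol=1e-6)

    def test_full_dimension_coordinates_reconstruct_distances(self):
        rng = np.random.default_rng(78)
        n = 6
        vals = rng.random((50, n))
        beta = BetaMatrix(pd.DataFrame(
            vals, index=[f"cg{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(n)],
        ))
        res = classical_mds(beta, top_n_variable=50, n_dims=n)
        coords = res.coordinates.to_numpy()
        from scipy.spatial.distance import pdist, squareform

        original = squareform(pdist(vals.T))
        reconstructed = squareform(pdist(coords))
        np.testing.assert_allclose(reconstructed, original, atol=1e-6)

    def test_cell_types_cluster_in_leading_dimensions(self, exact_reference):
        beta, sheet = exact_reference
        res = classical_mds(beta, top_n_variable=500, n_dims=3)
        # samples of the same cell type coincide at infinite precision,
        # different cell types separate
        for ct in sheet.cell_types:
            ids = sheet.samples_of(ct)
            pair = res.coordinates.loc[ids].to_numpy()
            assert np.linalg.norm(pair[0] - pair[1]) < 1e-6
        assert res.variance_fractions.sum() > 0.9

    def test_agrees_with_independent_pcoa(self):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(79)
        vals = rng.random((40, 5))
        ids = [f"s{j}" for j in range(5)]
        beta = BetaMatrix(pd.DataFrame(
            vals, index=[f"cg{i}" for i in range(40)], columns=ids
        ))
        res = classical_mds(beta, top_n_variable=40, n_dims=2)
        dm = skbio.DistanceMatrix(squareform(pdist(vals.T)), ids=ids)
        ref = skbio.stats.ordination.pcoa(dm, number_of_dimensions=2)
        for k in range(2):
            ours = res.coordinates.iloc[:, k].to_numpy()
            theirs = ref.samples.iloc[:, k].to_numpy()
            sign = np.sign(np.dot(ours, theirs)) or 1.0
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)
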