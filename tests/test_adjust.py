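"""Channel statistics, scale factors, quantile maps, and sample adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import batchanchor as ba
from batchanchor.adjust import SCALE_METHODS

nonneg_vectors = hnp.arrays(
    dtype=np.float64,
    shape=st.integers(2, 200),
    elements=st.floats(0, 1e5, allow_nan=False),
)


def _config(**kw):
    base = dict(method="percentile", percentile_p=95.0,
                reference_batch="batch1", channels_to_adjust=["Ch1"])
    base.update(kw)
    return ba.AdjustmentConfig(**base)


class TestChannelStatistic:
    @pytest.mark.parametrize(
        "values,method,p,expected",
        [
            # >50% zero-valued events force a zero median
            ([0, 0, 0, 10], "median", None, 0.0),
            # rank 1 + 99*0.95 = 95.05 -> linear interpolation
            (list(range(1, 101)), "percentile", 95.0, 95.05),
            ([5, 5, 5], "mean", None, 5.0),
            ([5, 5, 5], "sd", None, 0.0),
            ([0, 2, 4], "mean", None, 2.0),
            # sample SD, divisor n-1
            ([1, 3], "sd", None, np.sqrt(2.0)),
        ],
    )
    def test_examples(self, values, method, p, expected):
        result = ba.channel_statistic(np.asarray(values, float), method,
                                      percentile_p=p or 95.0)
        assert result == pytest.approx(expected, abs=1e-12)

    def test_percentile_matches_brute_force_interpolation(self, rng):
        """Percentile equals explicit interpolation between order statistics
        at rank 1 + (n-1)p/100, computed independently."""
        values = rng.lognormal(3, 1, size=137)
        ordered = np.sort(values)
        for p in (5.0, 50.0, 80.0, 95.0, 99.0):
            h = 1 + (len(values) - 1) * p / 100.0
            lo = int(np.floor(h)) - 1
            frac = h - np.floor(h)
            expected = ordered[lo] + frac * (ordered[min(lo + 1, len(values) - 1)] - ordered[lo])
            assert ba.channel_statistic(values, "percentile", p) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ba.channel_statistic(np.array([]), "mean")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            ba.channel_statistic(np.array([1.0]), "mode")


class TestScaleFactor:
    def test_ratio(self):
        ref = np.full(10, 10.0)
        batch = np.full(10, 5.0)
        assert ba.compute_scale_factor(ref, batch, _config(method="mean")) == 2.0

    def test_identity_on_same_anchor(self, rng):
        values = rng.lognormal(3, 1, 1000)
        for method in SCALE_METHODS:
            factor = ba.compute_scale_factor(values, values, _config(method=method))
            assert factor == pytest.approx(1.0, abs=0.0)

    def test_majority_zero_median_yields_skip(self):
        """>50% zero-valued events give a zero median, hence an undefined
        scaling factor: the channel is skipped with a recorded reason."""
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        batch = np.array([0.0, 0.0, 0.0, 10.0])
        result = ba.compute_scale_factor(ref, batch, _config(method="median"))
        assert isinstance(result, ba.SkipChannel)
        assert "zero" in result.reason

    def test_zero_stat_raises_when_skip_disabled(self):
        ref = np.array([1.0, 2.0])
        batch = np.array([0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            ba.compute_scale_factor(ref, batch,
                                    _config(method="mean", skip_on_zero_stat=False))

    def test_arcsinh_space_uses_transformed_statistics(self):
        ref = np.array([5.0, 10.0, 20.0])
        batch = np.array([2.0, 4.0, 8.0])
        config = _config(method="mean", space="arcsinh", cofactor=5.0)
        expected = np.mean(np.arcsinh(ref / 5)) / np.mean(np.arcsinh(batch / 5))
        assert ba.compute_scale_factor(ref, batch, config) == pytest.approx(expected)


class TestApplyScale:
    def test_identity_factor(self):
        values = np.array([0.0, 2.0, 4.0])
        for space in ("raw", "arcsinh"):
            np.testing.assert_allclose(ba.apply_scale(values, 1.0, space), values,
                                       atol=1e-12)

    def test_raw_is_linear(self):
        np.testing.assert_array_equal(
            ba.apply_scale(np.array([0.0, 2.0, 4.0]), 2.0, "raw"), [0.0, 4.0, 8.0]
        )

    def test_arcsinh_closed_form(self):
        # 5*sinh(2*asinh(1)) = 10*sinh(asinh(1))*cosh(asinh(1)) = 10*sqrt(2),
        # by the double-angle identity — an independent closed-form derivation
        result = ba.apply_scale(np.array([5.0]), 2.0, "arcsinh", cofactor=5.0)
        assert result[0] == pytest.approx(10 * np.sqrt(2.0))
        assert result[0] == pytest.approx(14.1421, abs=2e-4)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            ba.apply_scale(np.array([1.0]), 0.0, "raw")
        with pytest.raises(ValueError):
            ba.apply_scale(np.array([1.0]), np.inf, "raw")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=nonneg_vectors, factor=st.floats(0.01, 10.0),
           space=st.sampled_from(["raw", "arcsinh"]))
    def test_monotone_nonnegative_zero_preserving(self, values, factor, space):
        """Scaling in either space preserves rank order and nonnegativity,
        and maps zeros exactly to zeros."""
        out = ba.apply_scale(values, factor, space, cofactor=5.0)
        assert np.all(out >= 0)
        np.testing.assert_array_equal(out[values == 0], 0.0)
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-9 * np.abs(out[order][:-1]))


class TestQuantileMap:
    def test_identity_when_anchors_equal(self, rng):
        values = rng.lognormal(3, 1, 500)
        values[:50] = 0.0  # zero-inflated, so 0 lies inside the knot range
        qmap = ba.build_quantile_map(values, values, n_knots=101)
        assert qmap.is_identity
        np.testing.assert_allclose(
            ba.apply_quantile_map(np.array([0.0, 7.0, 13.0]), qmap),
            [0.0, 7.0, 13.0], rtol=1e-9,
        )

    def test_halving_map_from_doubled_batch(self, rng):
        """If the batch anchor is exactly 2x the reference, the map halves
        interior knots."""
        ref = rng.lognormal(3, 0.5, 2000)
        qmap = ba.build_quantile_map(ref, 2.0 * ref, n_knots=51)
        interior = slice(1, -1)
        np.testing.assert_allclose(
            qmap.target_knots[interior], qmap.source_knots[interior] / 2.0, rtol=1e-9
        )

    def test_simple_linear_interpolation(self):
        qmap = ba.QuantileMap(np.array([0.0, 10.0]), np.array([0.0, 20.0]))
        assert ba.apply_quantile_map(np.array([5.0]), qmap)[0] == 10.0

    def test_clamps_outside_knot_range(self):
        qmap = ba.QuantileMap(np.array([1.0, 10.0]), np.array([2.0, 20.0]))
        out = ba.apply_quantile_map(np.array([0.5, 50.0]), qmap)
        np.testing.assert_array_equal(out, [2.0, 20.0])

    def test_mapped_batch_matches_reference_distribution(self, rng):
        from scipy.stats import ks_2samp

        ref = rng.lognormal(3.0, 0.8, 20_000)
        batch = rng.lognormal(3.6, 0.5, 20_000)
        qmap = ba.build_quantile_map(ref, batch, n_knots=10_001)
        mapped = ba.apply_quantile_map(batch, qmap)
        assert ks_2samp(mapped, ref).statistic <= 2 / 10_001 + 0.02

    def test_zero_mass_artifact_pooled(self, rng):
        """With more zeros in the batch than the reference, the pooled map
        inflates zeros to positive values; with fewer zeros it squashes the
        lowest positive events toward zero."""
        positive = rng.lognormal(3, 0.5, 10_000)
        ref = positive.copy()
        ref[:1000] = 0.0          # 10% zeros
        batch = positive.copy()
        batch[:4000] = 0.0        # 40% zeros
        qmap = ba.build_quantile_map(ref, batch, n_knots=1001)
        mapped = ba.apply_quantile_map(batch, qmap)
        assert np.mean(mapped == 0) < np.mean(batch == 0)  # zeros inflated
        # swap roles: batch has fewer zeros than reference
        qmap2 = ba.build_quantile_map(batch, ref, n_knots=1001)
        mapped2 = ba.apply_quantile_map(ref, qmap2)
        assert np.mean(mapped2 == 0) > np.mean(ref == 0)   # positives squashed

    def test_conditional_mode_preserves_zeros(self, rng):
        positive = rng.lognormal(3, 0.5, 5000)
        ref = positive.copy(); ref[:500] = 0.0
        batch = positive * 1.7; batch[:2000] = 0.0
        qmap = ba.build_quantile_map(ref, batch, n_knots=501,
                                     zero_handling="conditional")
        mapped = ba.apply_quantile_map(batch, qmap)
        np.testing.assert_array_equal(mapped[batch == 0], 0.0)
        assert np.all(mapped[batch > 0] > 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ref=nonneg_vectors, batch=nonneg_vectors, values=nonneg_vectors)
    def test_rank_preservation_property(self, ref, batch, values):
        """Any valid map applied to any values preserves rank order (ties
        allowed), checked against an independent sort."""
        qmap = ba.build_quantile_map(ref, batch, n_knots=21)
        out = ba.apply_quantile_map(values, qmap)
        assert np.all(out >= 0)
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_invalid_knots_rejected(self):
        with pytest.raises(ValueError):
            ba.QuantileMap(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            ba.build_quantile_map(np.array([1.0]), np.array([1.0]), n_knots=1)


class TestAdjustSample:
    @pytest.fixture
    def batch2_table(self, rng):
        data = rng.lognormal(3, 0.7, size=(800, 3))
        data[rng.random(data.shape) < 0.15] = 0.0
        return ba.EventTable(
            sample_id="b2s1", batch_id="batch2", role="study",
            channels=[("Ch1", ""), ("Ch2", ""), ("Ch3", "")], data=data,
        )

    def test_reference_batch_is_noop(self, batch2_table):
        table = batch2_table
        table.batch_id = "batch1"
        record = ba.ScaleFactorRecord("batch1", "percentile", "raw",
                                      {"Ch1": 1.0, "Ch2": 1.0, "Ch3": 1.0})
        config = _config(channels_to_adjust=["Ch1", "Ch2", "Ch3"])
        out = ba.adjust_sample(table, record, config)
        np.testing.assert_array_equal(out.data, table.data)

    def test_unit_factors_are_noop(self, batch2_table):
        record = ba.ScaleFactorRecord("batch2", "percentile", "raw",
                                      {"Ch1": 1.0, "Ch2": 1.0, "Ch3": 1.0})
        config = _config(channels_to_adjust=["Ch1", "Ch2", "Ch3"])
        out = ba.adjust_sample(batch2_table, record, config)
        np.testing.assert_allclose(out.data, batch2_table.data, atol=1e-12)

    def test_unselected_channels_untouched(self, batch2_table):
        record = ba.ScaleFactorRecord("batch2", "percentile", "raw", {"Ch1": 2.0})
        out = ba.adjust_sample(batch2_table, record, _config())
        np.testing.assert_array_equal(out.channel_values("Ch2"),
                                      batch2_table.channel_values("Ch2"))
        np.testing.assert_allclose(out.channel_values("Ch1"),
                                   2 * batch2_table.channel_values("Ch1"))

    def test_skipped_channel_unchanged_and_flagged(self, batch2_table):
        record = ba.ScaleFactorRecord(
            "batch2", "median", "raw",
            {"Ch1": 2.0, "Ch2": ba.SkipChannel("zero median"), "Ch3": 1.5},
        )
        config = _config(method="median", channels_to_adjust=["Ch1", "Ch2", "Ch3"])
        out = ba.adjust_sample(batch2_table, record, config)
        np.testing.assert_array_equal(out.channel_values("Ch2"),
                                      batch2_table.channel_values("Ch2"))
        assert "Ch2" in out.keywords["BATCHADJ_SKIPPED"]

    def test_missing_channel_error_names_channel_and_sample(self, batch2_table):
        config = _config(channels_to_adjust=["Ch1", "Ch9"])
        record = ba.ScaleFactorRecord("batch2", "percentile", "raw", {"Ch1": 1.0})
        with pytest.raises(ValueError, match="Ch9"):
            ba.adjust_sample(batch2_table, record, config)

    def test_batch_mismatch_rejected(self, batch2_table):
        record = ba.ScaleFactorRecord("batch3", "percentile", "raw", {"Ch1": 1.0})
        with pytest.raises(ValueError, match="batch3"):
            ba.adjust_sample(batch2_table, record, _config())

    @pytest.mark.parametrize("method,space", [
        ("percentile", "raw"), ("mean", "raw"), ("median", "raw"), ("sd", "raw"),
        ("percentile", "arcsinh"), ("mean", "arcsinh"),
    ])
    def test_homogeneity_closure(self, rng, method, space):
        """After adjustment, the batch anchor's per-channel statistic equals
        the reference anchor's to 1e-6 relative tolerance (computed in the
        adjustment space)."""
        ref = rng.lognormal(3.2, 0.8, 5000)
        batch = 1.7 * rng.lognormal(3.2, 0.8, 5000)
        config = _config(method=method, space=space)
        factor = ba.compute_scale_factor(ref, batch, config)
        adjusted = ba.apply_scale(batch, factor, space, config.cofactor)

        def stat(v):
            if space == "arcsinh":
                v = np.arcsinh(v / config.cofactor)
            return ba.channel_statistic(v, method, config.percentile_p)

        assert stat(adjusted) == pytest.approx(stat(ref), rel=1e-6)
        # idempotence: recomputing the factor on adjusted data gives ~1
        refactor = ba.compute_scale_factor(ref, adjusted, config)
        assert refactor == pytest.approx(1.0, rel=1e-6)


class TestRecordSerialization:
    def test_roundtrip_csv_and_knots(self, tmp_path, rng):
        values = rng.lognormal(3, 0.6, 400)
        qmap = ba.build_quantile_map(values, 2 * values, n_knots=51)
        records = [
            ba.ScaleFactorRecord("batch1", "percentile", "raw",
                                 {"Ch1": 1.0, "Ch2": 1.0}),
            ba.ScaleFactorRecord(
                "batch2", "percentile", "raw",
                {"Ch1": 1.8, "Ch2": ba.SkipChannel("zero stat")},
            ),
            ba.ScaleFactorRecord("batch3", "quantile_norm", "raw", {"Ch1": qmap}),
        ]
        csv_path = str(tmp_path / "factors.csv")
        knots_path = str(tmp_path / "knots.json")
        ba.save_records(records, csv_path, knots_path)
        loaded = {r.batch_id: r for r in ba.load_records(csv_path, knots_path)}
        assert loaded["batch1"].entries["Ch1"] == 1.0
        assert loaded["batch2"].entries["Ch1"] == 1.8
        assert isinstance(loaded["batch2"].entries["Ch2"], ba.SkipChannel)
        reloaded = loaded["batch3"].entries["Ch1"]
        np.testing.assert_allclose(reloaded.source_knots, qmap.source_knots)
        np.testing.assert_allclose(reloaded.target_knots, qmap.target_knots)

    def test_nonpositive_factor_rejected(self):
        record = ba.ScaleFactorRecord("b", "mean", "raw", {"Ch1": -2.0})
        with pytest.raises(ValueError, match="positive"):
            record.validate()


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"method": "zscore"},
        {"percentile_p": 0.0},
        {"percentile_p": 100.0},
        {"space": "log"},
        {"cofactor": 0.0},
        {"qn_n_knots": 1},
        {"qn_zero_handling": "drop"},
    ])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            _config(**kw)
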