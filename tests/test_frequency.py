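"""Correction factors, the four estimators, normalisation, pooled tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolgwas.errors import ValidationError
from poolgwas.frequency import (
    estimate_correction_factors,
    estimate_hoogendoorn,
    estimate_meaburn,
    estimate_pool_frequencies,
    estimate_unadjusted,
    fit_normalization,
    read_frequency_table,
    write_frequency_table,
)

signals = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)
pos_signals = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)
ks = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def het_frame(pairs, marker="rs1"):
    return pd.DataFrame(
        [(marker, f"s{i}", a, b, "AB") for i, (a, b) in enumerate(pairs)],
        columns=["marker_id", "sample_id", "signal_a", "signal_b", "call"],
    )


class TestCorrectionFactors:
    def test_constant_ratio_heterozygotes(self):
        fac = estimate_correction_factors(het_frame([(2, 1), (4, 2), (6, 3)]))
        row = fac.loc["rs1"]
        assert row["k_h"] == pytest.approx(2.0)
        assert row["ras_het_mean"] == pytest.approx(2 / 3)
        assert row["n_het"] == 3
        assert row["usable"]

    def test_symmetric_signals(self):
        fac = estimate_correction_factors(het_frame([(1, 1), (1, 1)]))
        assert fac.loc["rs1", "k_h"] == pytest.approx(1.0)
        assert fac.loc["rs1", "ras_het_mean"] == pytest.approx(0.5)

    def test_mixed_ratios_hand_arithmetic(self):
        # mean of ratios (3/1, 1/1) = 2; mean of RAS (0.75, 0.5) = 0.625
        fac = estimate_correction_factors(het_frame([(3, 1), (1, 1)]))
        assert fac.loc["rs1", "k_h"] == pytest.approx(2.0)
        assert fac.loc["rs1", "ras_het_mean"] == pytest.approx(0.625)

    def test_zero_b_excluded_from_ratio_mean(self):
        fac = estimate_correction_factors(het_frame([(2, 1), (5, 0), (4, 2)]))
        row = fac.loc["rs1"]
        assert row["k_h"] == pytest.approx(2.0)  # the b == 0 row is excluded
        assert row["n_het"] == 2
        assert row["n_excluded"] == 1
        # but the (5, 0) row still contributes RAS = 1.0
        assert row["ras_het_mean"] == pytest.approx((2 / 3 + 1.0 + 2 / 3) / 3)

    def test_min_het_flags_unusable(self):
        fac = estimate_correction_factors(het_frame([(2, 1)]), min_het=2)
        assert not fac.loc["rs1", "usable"]
        assert fac.loc["rs1", "n_het"] == 1

    def test_non_het_input_rejected(self):
        df = het_frame([(1, 1)])
        df.loc[0, "call"] = "AA"
        with pytest.raises(ValidationError, match="AB"):
            estimate_correction_factors(df)


class TestEstimators:
    @pytest.mark.parametrize(
        "a,b,expected", [(100, 100, 0.5), (150, 50, 0.75), (0, 10, 0.0)]
    )
    def test_unadjusted(self, a, b, expected):
        assert estimate_unadjusted(a, b) == pytest.approx(expected)

    def test_unadjusted_degenerate_is_nan(self):
        assert np.isnan(estimate_unadjusted(0.0, 0.0))

    @pytest.mark.parametrize(
        "a,b,k,expected",
        [(100, 100, 1.0, 0.5), (200, 100, 2.0, 0.5), (90, 10, 3.0, 0.75)],
    )
    def test_hoogendoorn(self, a, b, k, expected):
        assert estimate_hoogendoorn(a, b, k) == pytest.approx(expected)

    def test_meaburn_heterozygote_calibrated_pool_reads_half(self):
        # pool RAS 2/3 with mean het RAS 2/3 -> corrected 0.5
        assert estimate_meaburn(2.0, 1.0, 2 / 3) == pytest.approx(0.5)

    def test_meaburn_hand_value(self):
        assert estimate_meaburn(90.0, 10.0, 0.75) == pytest.approx(0.75)

    def test_invalid_parameters_give_nan(self):
        assert np.isnan(estimate_hoogendoorn(10.0, 5.0, 0.0))
        assert np.isnan(estimate_hoogendoorn(10.0, 5.0, np.nan))
        assert np.isnan(estimate_meaburn(10.0, 5.0, 1.0))
        assert np.isnan(estimate_meaburn(0.0, 0.0, 0.5))

    @given(a=signals, b=pos_signals)
    @settings(max_examples=200, derandomize=True)
    def test_k1_reduction_is_bitwise(self, a, b):
        assert estimate_hoogendoorn(a, b, 1.0) == estimate_unadjusted(a, b)

    @given(a=signals, b=pos_signals)
    @settings(max_examples=200, derandomize=True)
    def test_meaburn_half_reduces_to_unadjusted(self, a, b):
        assert estimate_meaburn(a, b, 0.5) == pytest.approx(
            estimate_unadjusted(a, b), abs=1e-12
        )

    @given(a=signals, b=pos_signals, kappa=ks)
    @settings(max_examples=300, derandomize=True)
    def test_meaburn_equals_hoogendoorn_at_same_kappa(self, a, b, kappa):
        ras = kappa / (1.0 + kappa)  # het RAS whose odds are kappa
        m = estimate_meaburn(a, b, ras)
        h = estimate_hoogendoorn(a, b, kappa)
        assert m == pytest.approx(h, abs=1e-9)

    @given(a=signals, b=pos_signals, k=ks)
    @settings(max_examples=300, derandomize=True)
    def test_range_and_scale_invariance(self, a, b, k):
        for scale in (1.0, 7.5):
            u = estimate_unadjusted(a * scale, b * scale)
            h = estimate_hoogendoorn(a * scale, b * scale, k)
            assert 0.0 <= u <= 1.0 and 0.0 <= h <= 1.0
        assert estimate_unadjusted(a, b) == pytest.approx(
            estimate_unadjusted(a * 7.5, b * 7.5), rel=1e-12
        )
        assert estimate_hoogendoorn(a, b, k) == pytest.approx(
            estimate_hoogendoorn(a * 7.5, b * 7.5, k), rel=1e-12
        )

    def test_monotonicity(self):
        b, k = 50.0, 1.3
        freqs = [estimate_hoogendoorn(a, b, k) for a in (10, 20, 40, 80)]
        assert freqs == sorted(freqs) and len(set(freqs)) == 4
        a = 60.0
        by_k = [estimate_hoogendoorn(a, b, kk) for kk in (0.5, 1.0, 2.0, 4.0)]
        assert by_k == sorted(by_k, reverse=True) and len(set(by_k)) == 4


class TestNormalisation:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["marker_id", "sample_id", "signal_a", "signal_b"]
        )

    def test_identical_replicates_give_unit_scales(self):
        df = self.frame(
            [("m1", "r1", 10, 20), ("m2", "r1", 30, 40),
             ("m1", "r2", 10, 20), ("m2", "r2", 30, 40)]
        )
        scales = fit_normalization(df)
        assert np.allclose(scales[["c_a", "c_b"]].to_numpy(), 1.0)

    def test_doubled_replicate_gets_half_scale(self):
        df = self.frame(
            [("m1", "r1", 10, 20), ("m2", "r1", 30, 40),
             ("m1", "r2", 20, 40), ("m2", "r2", 60, 80)]
        )
        scales = fit_normalization(df)
        assert scales.loc["r2", "c_a"] / scales.loc["r1", "c_a"] == pytest.approx(0.5)
        assert scales.loc["r2", "c_b"] / scales.loc["r1", "c_b"] == pytest.approx(0.5)
        # post-normalisation channel means are equalised across replicates
        for ch, c in (("signal_a", "c_a"), ("signal_b", "c_b")):
            means = (
                df.assign(x=df[ch] * scales.loc[df["sample_id"], c].to_numpy())
                .groupby("sample_id")["x"]
                .mean()
            )
            assert means.nunique() == 1 or np.allclose(means, means.iloc[0])

    def test_channel_specific_scaling_changes_ras(self):
        # replicate 2 has only its A channel doubled: c_a must halve relative
        # to c_b, so normalisation changes its RAS (a total-intensity scaling
        # could not do that)
        df = self.frame(
            [("m1", "r1", 10, 20), ("m1", "r2", 20, 20)]
        )
        scales = fit_normalization(df)
        ratio_r2 = scales.loc["r2", "c_a"] / scales.loc["r2", "c_b"]
        ratio_r1 = scales.loc["r1", "c_a"] / scales.loc["r1", "c_b"]
        assert ratio_r2 == pytest.approx(ratio_r1 / 2)
        raw_ras = 20 / (20 + 20)
        norm_ras = (20 * scales.loc["r2", "c_a"]) / (
            20 * scales.loc["r2", "c_a"] + 20 * scales.loc["r2", "c_b"]
        )
        assert norm_ras != pytest.approx(raw_ras)

    def test_zero_channel_replicate_is_an_error(self):
        df = self.frame([("m1", "r1", 0, 0), ("m1", "r2", 1, 2)])
        with pytest.raises(ValidationError, match="r1"):
            fit_normalization(df)


class TestPooledTable:
    def pool_frame(self, design, a, b):
        rows = [(("rs1"), rep, a, b) for rep in design.replicate_ids]
        return pd.DataFrame(rows, columns=["marker_id", "sample_id", "signal_a", "signal_b"])

    def factors(self, k=1.0, ras=0.5):
        return pd.DataFrame(
            {"k_h": [k], "ras_het_mean": [ras], "n_het": [10], "n_excluded": [0],
             "usable": [True]},
            index=pd.Index(["rs1"], name="marker_id"),
        )

    def test_all_methods_agree_on_balanced_signals(self, design_2x2x2):
        pool = self.pool_frame(design_2x2x2, 50.0, 50.0)
        scales = fit_normalization(pool)
        for method in ("H", "M", "N", "U"):
            out = estimate_pool_frequencies(
                pool, design_2x2x2, method, factors=self.factors(), scales=scales
            )
            assert np.allclose(out["freq"], 0.5)
            assert out["valid"].all()
            assert set(out["method"]) == {method}

    def test_unadjusted_scale_invariance(self, design_2x2x2):
        pool = self.pool_frame(design_2x2x2, 60.0, 40.0)
        pool.loc[pool["sample_id"] == "cp1_r2", ["signal_a", "signal_b"]] = (66.0, 44.0)
        out = estimate_pool_frequencies(pool, design_2x2x2, "U")
        assert np.allclose(out["freq"], 0.6)

    def test_unusable_factor_marks_invalid_not_unadjusted(self, design_2x2x2):
        pool = self.pool_frame(design_2x2x2, 60.0, 40.0)
        fac = self.factors()
        fac["usable"] = False
        out = estimate_pool_frequencies(pool, design_2x2x2, "H", factors=fac)
        assert not out["valid"].any()
        assert out["freq"].isna().all()

    def test_method_n_without_scales_is_error(self, design_2x2x2):
        pool = self.pool_frame(design_2x2x2, 60.0, 40.0)
        with pytest.raises(ValidationError, match="scale"):
            estimate_pool_frequencies(pool, design_2x2x2, "N", factors=self.factors())

    def test_unknown_replicate_is_error(self, design_2x2x2):
        pool = self.pool_frame(design_2x2x2, 60.0, 40.0)
        pool.loc[0, "sample_id"] = "mystery"
        with pytest.raises(ValidationError, match="mystery"):
            estimate_pool_frequencies(pool, design_2x2x2, "U")

    def test_round_trip(self, design_2x2x2, tmp_path):
        pool = self.pool_frame(design_2x2x2, 60.0, 40.0)
        out = estimate_pool_frequencies(pool, design_2x2x2, "U")
        path = tmp_path / "f.tsv"
        write_frequency_table(out, path)
        pd.testing.assert_frame_equal(out, read_frequency_table(path))


class TestParameterRecovery:
    """Synthetic heterozygotes: does the k estimate recover the truth?"""

    @pytest.mark.parametrize("k_true", [0.5, 1.0, 2.0])
    def test_k_recovery_with_multiplicative_noise(self, k_true, rng):
        n_markers, n_het, cv = 400, 25, 0.10
        sigma = np.sqrt(np.log1p(cv * cv))
        base = 1000.0
        a = base * k_true / 2 * rng.lognormal(-sigma**2 / 2, sigma, (n_markers, n_het))
        b = base / 2 * rng.lognormal(-sigma**2 / 2, sigma, (n_markers, n_het))
        df = pd.DataFrame(
            {
                "marker_id": np.repeat([f"m{i:04d}" for i in range(n_markers)], n_het),
                "sample_id": np.tile([f"s{j}" for j in range(n_het)], n_markers),
                "signal_a": a.ravel(),
                "signal_b": b.ravel(),
            }
        )
        fac = estimate_correction_factors(df)
        assert fac["usable"].all()
        assert fac["k_h"].mean() == pytest.approx(k_true, rel=0.03)
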