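"""Count-profile computations: normalization, ranking, ratios, rank statistics."""

import numpy as np
import pandas as pd
import pytest

from utakit import (
    CountMatrix,
    compartment_ratio,
    kruskal_dunn,
    log2_quartile_rank,
    median_of_ratios_size_factors,
    normalize_median_of_ratios,
    rpkm_normalize,
    rpm_normalize,
)
from oracles import brute_force_dunn_z, brute_force_kruskal


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = pd.DataFrame({"a": [10, 30, 5], "b": [10, 30, 5]})
        assert np.allclose(median_of_ratios_size_factors(m), [1.0, 1.0])

    def test_hand_computed_two_by_two(self):
        m = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]})
        factors = median_of_ratios_size_factors(m)
        assert factors["s1"] == pytest.approx(1 / np.sqrt(2), abs=5e-6)
        assert factors["s2"] == pytest.approx(np.sqrt(2), abs=5e-6)

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(30, 3)), columns=["a", "b", "c"]
        ) + 1
        base = median_of_ratios_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 4
        factors = median_of_ratios_size_factors(scaled)
        # scaling one sample rescales the geometric-mean reference too, so
        # equivariance holds for factor *ratios*, not single factors
        assert factors["b"] / factors["a"] == pytest.approx(4 * base["b"] / base["a"], rel=1e-9)
        assert factors["c"] / factors["a"] == pytest.approx(base["c"] / base["a"], rel=1e-9)

    def test_exact_scalar_multiple_columns(self, rng):
        col = rng.poisson(100, size=20) + 1
        scalars = np.array([0.5, 1.0, 2.0])
        m = pd.DataFrame({f"s{i}": np.round(col * c).astype(int) + 1 for i, c in enumerate(scalars)})
        factors = median_of_ratios_size_factors(m).to_numpy()
        # equal to the scalars up to a common constant of geometric mean ~1
        ratio = factors / scalars
        assert np.allclose(ratio, ratio[0], rtol=0.06)

    def test_all_zero_feature_rows_rejected(self):
        m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="positive"):
            median_of_ratios_size_factors(m)

    def test_normalized_matrix_uses_factors(self):
        m = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]})
        norm = normalize_median_of_ratios(m)
        assert np.allclose(norm["s1"] * (1 / np.sqrt(2)), m["s1"], rtol=1e-6)


class TestQuartilesAndRPM:
    def test_log2_with_pseudocount(self):
        out = log2_quartile_rank(pd.Series([0.0, 1023.0]))
        assert out["log2"].iloc[0] == 0.0
        assert out["log2"].iloc[1] == pytest.approx(10.0)

    def test_eight_distinct_values_two_per_quartile(self):
        out = log2_quartile_rank(pd.Series([1, 2, 4, 8, 16, 32, 64, 128]))
        assert out["quartile"].value_counts().eq(2).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            log2_quartile_rank(pd.Series([], dtype=float))

    def test_rpm_direct_arithmetic(self):
        m = pd.DataFrame({"s": [5, 15]})
        assert np.allclose(rpm_normalize(m)["s"], [250_000.0, 750_000.0])

    def test_rpm_columns_sum_to_million_and_duplication_invariant(self, rng):
        m = pd.DataFrame(rng.poisson(20, size=(50, 4)))
        rpm = rpm_normalize(m)
        assert np.allclose(rpm.sum(axis=0), 1e6)
        assert np.allclose(rpm_normalize(2 * m), rpm)

    def test_rpm_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            rpm_normalize(pd.DataFrame({"s": [0, 0]}))

    def test_rpkm_scales_by_kilobase(self):
        m = pd.DataFrame({"s": [5, 15]})
        lengths = pd.Series([500.0, 2000.0])
        rpkm = rpkm_normalize(m, lengths)
        assert rpkm["s"].iloc[0] == pytest.approx(250_000.0 / 0.5)
        assert rpkm["s"].iloc[1] == pytest.approx(750_000.0 / 2.0)


class TestCompartmentRatio:
    def make_matrix(self, cyto, nuc):
        counts = pd.DataFrame(
            {"c1": cyto, "n1": nuc}, index=[f"mir{i}" for i in range(len(cyto))]
        )
        comp = pd.Series({"c1": "cytoplasm", "n1": "nucleus"})
        return CountMatrix(counts, compartments=comp)

    def test_equal_profiles_give_unit_ratio(self):
        m = self.make_matrix([10, 90], [10, 90])
        assert np.allclose(compartment_ratio(m), 1.0)

    def test_pseudocount_arithmetic(self):
        # one miRNA owns the whole cytoplasmic library: RPM 1e6 vs 0
        m = self.make_matrix([10, 0], [0, 10])
        ratio = compartment_ratio(m, pseudocount=1.0)
        assert ratio.iloc[0] == pytest.approx((1e6 + 1) / 1.0)

    def test_swapping_compartments_inverts_ratio(self):
        m = self.make_matrix([30, 70], [60, 40])
        forward = compartment_ratio(m)
        backward = compartment_ratio(m, num="nucleus", den="cytoplasm")
        assert np.allclose(forward * backward, 1.0) or (forward * backward - 1).abs().max() < 0.05

    def test_missing_compartment_rejected(self):
        m = self.make_matrix([1, 2], [3, 4])
        with pytest.raises(ValueError, match="nucleolus"):
            compartment_ratio(m, num="nucleolus")


class TestKruskalDunn:
    FIXTURE = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}

    def test_hand_derived_h_and_extreme_dunn_z(self):
        res = kruskal_dunn(self.FIXTURE)
        assert res.h_statistic == pytest.approx(7.2)
        row = res.pairwise.set_index(["group_a", "group_b"]).loc[("g1", "g3")]
        assert abs(row["z"]) == pytest.approx(6 / np.sqrt(5))

    def test_identical_groups_h_zero_p_one(self):
        res = kruskal_dunn({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert res.h_statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        for _ in range(50):
            k = rng.integers(2, 5)
            groups = {
                f"g{i}": rng.integers(0, 8, size=rng.integers(3, 10)).astype(float)
                for i in range(k)
            }
            if min(np.ptp(np.concatenate(list(groups.values()))), 1) == 0:
                continue
            res = kruskal_dunn(groups)
            h_bf, p_bf = brute_force_kruskal(groups)
            assert res.h_statistic == pytest.approx(h_bf, abs=1e-9)
            assert res.pvalue == pytest.approx(p_bf, abs=1e-6)
            names = list(groups)
            row = res.pairwise.iloc[0]
            z_bf = brute_force_dunn_z(groups, names[0], names[1])
            assert row["z"] == pytest.approx(z_bf, abs=1e-9)

    def test_bonferroni_adjustment(self):
        res = kruskal_dunn(self.FIXTURE, adjust="bonferroni")
        res_none = kruskal_dunn(self.FIXTURE, adjust="none")
        assert np.allclose(
            res.pairwise["pvalue_adj"], np.minimum(1.0, res_none.pairwise["pvalue"] * 3)
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1, 2]})
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1, 2], "b": []})
        with pytest.raises(ValueError):
            kruskal_dunn(self.FIXTURE, adjust="holm")

    def test_extreme_pair_power_pattern(self, rng):
        """Only the extreme groups differ (2 pooled SD shift): the extreme-pair
        Dunn comparison is usually significant, adjacent pairs mostly not."""
        extreme_sig = adjacent_sig = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = {
                "low": rng.normal(0.0, 1.0, 10),
                "mid": rng.normal(1.0, 1.0, 10),
                "high": rng.normal(2.0, 1.0, 10),
            }
            res = kruskal_dunn(groups)
            table = res.pairwise.set_index(["group_a", "group_b"])
            if table.loc[("low", "high"), "pvalue_adj"] < 0.05:
                extreme_sig += 1
            if (
                table.loc[("low", "mid"), "pvalue_adj"] < 0.05
                or table.loc[("mid", "high"), "pvalue_adj"] < 0.05
            ):
                adjacent_sig += 1
        assert extreme_sig / n_rep > 0.80
        assert adjacent_sig / n_rep < 0.20 * 2  # either adjacent pair


class TestCountMatrix:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "mirna\tlength\ts1\ts2\nmir-a\t22\t10\t20\nmir-b\t21\t30\t60\n"
        )
        sheet = tmp_path / "sheet.tsv"
        sheet.write_text("s1\tcytoplasm\ns2\tnucleus\n")
        cm = CountMatrix.read_tsv(path, sample_sheet=sheet)
        assert list(cm.counts.columns) == ["s1", "s2"]
        assert cm.feature_length.tolist() == [22, 21]
        assert cm.compartments["s2"] == "nucleus"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(pd.DataFrame({"s": [-1, 2]}))

    def test_duplicate_samples_rejected(self):
        frame = pd.DataFrame([[1, 2]], columns=["s", "s"])
        with pytest.raises(ValueError):
            CountMatrix(frame)
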