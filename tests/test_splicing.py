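import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bscomp import splicing
from bscomp.simulate import sim_counts
from conftest import make_count_matrix


class TestSizeFactors:
    def test_two_sample_oracle(self):
        # geometric means (sqrt(200), sqrt(1800)); each sample's ratios are
        # constant, so the factors are sqrt(1/2) and sqrt(2)
        factors = splicing.median_ratio_size_factors(np.array([[10, 20], [30, 60]]))
        assert factors == pytest.approx([math.sqrt(0.5), math.sqrt(2)], rel=1e-12)

    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[7], [13], [21]], (1, 4))
        assert splicing.median_ratio_size_factors(counts) == pytest.approx([1, 1, 1, 1])

    def test_single_sample_degenerate(self):
        assert splicing.median_ratio_size_factors(np.array([[5], [50]])) == pytest.approx([1.0])

    def test_all_zero_rows_error(self):
        with pytest.raises(ValueError, match="nonzero"):
            splicing.median_ratio_size_factors(np.array([[0, 1], [2, 0]]))

    def test_scaling_one_sample_scales_relative_factors(self):
        # the geometric-mean reference rescales too, so only factor RATIOS
        # pick up the library scaling: f1/f0 gains exactly the factor c
        counts = np.array([[10.0, 20.0, 15.0], [30.0, 60.0, 45.0], [5.0, 9.0, 7.0]])
        base = splicing.median_ratio_size_factors(counts)
        scaled = counts.copy()
        scaled[:, 1] *= 3
        new = splicing.median_ratio_size_factors(scaled)
        assert new[1] / new[0] == pytest.approx(3 * base[1] / base[0], rel=1e-9)
        assert new[2] / new[0] == pytest.approx(base[2] / base[0], rel=1e-9)


class TestPercentUnspliced:
    @pytest.mark.parametrize("u,s,expected", [(25, 75, 25.0), (0, 50, 0.0), (50, 0, 100.0)])
    def test_formula(self, u, s, expected):
        assert splicing.percent_unspliced(u, s) == expected

    def test_zero_total_is_missing(self):
        assert math.isnan(splicing.percent_unspliced(0, 0))

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            splicing.percent_unspliced(-1, 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        u=st.integers(0, 1000), s=st.integers(0, 1000),
        k=st.floats(0.01, 100, allow_nan=False),
    )
    def test_scale_invariance(self, u, s, k):
        if u + s == 0:
            return
        assert splicing.percent_unspliced(k * u, k * s) == pytest.approx(
            splicing.percent_unspliced(u, s), rel=1e-9
        )


class TestPuTable:
    def test_pooled_t_oracle(self):
        # control pu (10,12,14)%, treatment (20,22,24)%: delta 10 points,
        # pooled t = 6.124, df = 4, two-sided p ~ 0.00357
        cm = make_count_matrix(
            u_ctrl=[10, 12, 14], u_trt=[20, 22, 24],
            s_ctrl=[90, 88, 86], s_trt=[80, 78, 76],
        )
        from scipy import stats

        row = splicing.pu_table(cm, expression_min=0).iloc[0]
        assert row["delta_pu"] == pytest.approx(10.0)
        t_expected = 10.0 / (2.0 * math.sqrt(2.0 / 3.0))  # pooled sd = 2
        assert t_expected == pytest.approx(6.124, abs=1e-3)
        assert row["p_value"] == pytest.approx(2 * stats.t.sf(t_expected, 4), rel=1e-9)
        assert row["significant"]

    def test_zero_variance_gene_excluded_from_significant(self):
        cm = make_count_matrix(
            u_ctrl=[10, 10, 10], u_trt=[20, 20, 20],
            s_ctrl=[90, 90, 90], s_trt=[80, 80, 80],
        )
        row = splicing.pu_table(cm, expression_min=0).iloc[0]
        assert math.isnan(row["p_value"]) and not row["significant"]

    def test_expression_filter_blocks_significance(self):
        cm = make_count_matrix(
            u_ctrl=[1, 2, 1], u_trt=[5, 6, 5],
            s_ctrl=[9, 8, 9], s_trt=[5, 4, 5],
        )
        row = splicing.pu_table(cm, expression_min=100).iloc[0]
        assert row["base_mean"] < 100 and not row["significant"]

    def test_library_scaling_leaves_pu_and_base_mean_unchanged(self):
        cm = make_count_matrix(
            u_ctrl=[10, 12, 14], u_trt=[20, 22, 24],
            s_ctrl=[90, 88, 86], s_trt=[80, 78, 76],
        )
        scaled_counts = cm.counts.copy()
        scaled_counts["t0"] *= 4  # quadruple one library
        cm_scaled = make_count_matrix(
            u_ctrl=scaled_counts.loc["g1_pre", ["c0", "c1", "c2"]],
            u_trt=scaled_counts.loc["g1_pre", ["t0", "t1", "t2"]],
            s_ctrl=scaled_counts.loc["g1_m", ["c0", "c1", "c2"]],
            s_trt=scaled_counts.loc["g1_m", ["t0", "t1", "t2"]],
        )
        base = splicing.pu_table(cm, expression_min=0).iloc[0]
        scaled = splicing.pu_table(cm_scaled, expression_min=0).iloc[0]
        # pu is a within-library ratio: delta and the test are untouched
        assert scaled["delta_pu"] == pytest.approx(base["delta_pu"])
        assert scaled["p_value"] == pytest.approx(base["p_value"], rel=1e-9)
        # the normalized matrix rescales globally by c^(1/m) with m samples
        assert scaled["base_mean"] == pytest.approx(
            base["base_mean"] * 4 ** (1 / 6), rel=1e-9
        )

    def test_planted_shift_recovery(self):
        cm, truth = sim_counts(n_genes=60, n_planted=12, n_intronless=0, seed=11)
        table = splicing.pu_table(cm).set_index("gene_id")
        planted = truth["planted_genes"]
        recall = np.mean([bool(table.loc[g, "significant"]) for g in planted])
        assert recall >= 0.8
        deltas = table.loc[list(planted), "delta_pu"]
        assert deltas.mean() == pytest.approx(truth["delta_pu"], abs=5)


class TestClassAbundanceShift:
    def test_separated_classes_ordered_and_significant(self):
        rng = np.random.default_rng(5)
        # one gene pair per class is not enough: build 10 genes + 10 intronless
        counts, meta = {}, {}
        samples = ["c0", "c1", "c2", "t0", "t1", "t2"]
        rows, classes, genes = [], [], []
        ids = []
        for i in range(10):
            base = 1000 + 50 * i
            # unspliced doubles, spliced flat
            rows.append([base * 0.1] * 3 + [base * 0.2] * 3)
            ids.append(f"g{i}_pre"); classes.append("unspliced"); genes.append(f"g{i}")
            rows.append([base * 0.9] * 3 + [base * 0.9] * 3)
            ids.append(f"g{i}_m"); classes.append("spliced"); genes.append(f"g{i}")
            # intronless halves
            rows.append([base] * 3 + [base * 0.5] * 3)
            ids.append(f"nl{i}"); classes.append("intronless"); genes.append(f"nl{i}")
        counts = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
        meta = pd.DataFrame({"tx_class": classes, "gene_id": genes}, index=ids)
        cm = splicing.CountMatrix(
            counts=counts, meta=meta,
            sample_groups={s: ("control" if s.startswith("c") else "treatment") for s in samples},
        )
        res = splicing.class_abundance_shift(cm)
        assert res.medians["unspliced"] > res.medians["spliced"] > res.medians["intronless"]
        assert res.pairwise_p[("unspliced", "spliced")] < 0.01
        assert res.pairwise_p[("spliced", "intronless")] < 0.01

    def test_exact_rank_sum_small_case(self):
        from scipy import stats

        # A = {1,2,3}, B = {4,5,6}: U = 0 and the exact two-sided p is
        # 2 * (1/C(6,3)) = 0.1 by enumeration of all 20 arrangements
        u, p = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided")
        assert u == 0 and p == pytest.approx(0.1, rel=1e-12)

    def test_identical_distributions_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        from scipy import stats

        _, p = stats.mannwhitneyu(vals, vals, alternative="two-sided")
        assert p == pytest.approx(1.0, abs=0.05)
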