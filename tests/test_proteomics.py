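import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bscomp import proteomics
from bscomp.simulate import sim_proteomics


class TestBgCorrectedEnrichment:
    def test_score_arithmetic(self, nsc_table):
        enr = proteomics.bg_corrected_enrichment(nsc_table).set_index("protein_id")
        assert enr.loc["p1", "WT"] == pytest.approx((10 - 2) / 4)  # 2.0
        assert enr.loc["p1", "upDEL"] == pytest.approx(0.0)
        assert enr.loc["p2", "dnDEL"] == pytest.approx((1 - 5) / 3)

    def test_zero_ne_and_missing_propagate(self, nsc_table):
        enr = proteomics.bg_corrected_enrichment(nsc_table).set_index("protein_id")
        assert enr.loc["p3", proteomics.SUBSTRATES].isna().all()  # NE = 0
        assert np.isnan(enr.loc["p4", "WT"])  # missing NSC

    def test_inclusion_rule(self, nsc_table):
        enr = proteomics.bg_corrected_enrichment(nsc_table).set_index("protein_id")
        assert enr.loc["p1", "included"]  # E/U2 with a positive score
        assert not enr.loc["p2", "included"]  # E/U2 but all scores <= 0
        assert not enr.loc["p4", "included"]  # positive scores but not E/U2

    def test_score_sign_equals_numerator_sign(self, nsc_table):
        enr = proteomics.bg_corrected_enrichment(nsc_table).set_index("protein_id")
        for sub in proteomics.SUBSTRATES:
            for pid in ("p1", "p2"):
                raw = nsc_table.set_index("protein_id")
                expected = np.sign(raw.loc[pid, sub] - raw.loc[pid, "APT"])
                assert np.sign(enr.loc[pid, sub]) == expected

    def test_scaling_all_channels_leaves_scores_invariant(self, nsc_table):
        scaled = nsc_table.copy()
        cols = ["NE", "APT"] + proteomics.SUBSTRATES
        scaled.loc[0, cols] = scaled.loc[0, cols] * 7.0
        base = proteomics.bg_corrected_enrichment(nsc_table).set_index("protein_id")
        after = proteomics.bg_corrected_enrichment(scaled).set_index("protein_id")
        for sub in proteomics.SUBSTRATES:
            assert after.loc["p1", sub] == pytest.approx(base.loc["p1", sub], rel=1e-12)


class TestSignCounts:
    def test_zeros_and_missing_counted_in_neither(self):
        rows = pd.DataFrame(
            {
                "protein_id": ["a", "b", "c", "d"],
                "WT": [0.5, -0.1, 0.0, np.nan],
                "upDEL": [1.0, 1.0, 1.0, 1.0],
                "dnDEL": [1.0, 1.0, 1.0, 1.0],
                "2xDEL": [1.0, 1.0, 1.0, 1.0],
                "included": [True, True, True, True],
            }
        )
        counts = proteomics.eu2_sign_counts(rows).set_index("substrate")
        assert counts.loc["WT", "n_pos"] == 1 and counts.loc["WT", "n_neg"] == 1

    def test_bounded_by_included(self):
        nsc, _, _, truth = sim_proteomics(seed=3)
        enr = proteomics.bg_corrected_enrichment(nsc)
        counts = proteomics.eu2_sign_counts(enr)
        n_included = int(enr["included"].sum())
        assert ((counts["n_pos"] + counts["n_neg"]) <= n_included).all()

    def test_matches_generator_truth(self):
        nsc, _, _, truth = sim_proteomics(seed=9)
        enr = proteomics.bg_corrected_enrichment(nsc)
        counts = proteomics.eu2_sign_counts(enr).set_index("substrate")
        for sub in proteomics.SUBSTRATES:
            assert counts.loc[sub, "n_pos"] == truth["sign_counts"][sub]["n_pos"]
            assert counts.loc[sub, "n_neg"] == truth["sign_counts"][sub]["n_neg"]


class TestRowZscores:
    def test_three_point_row(self):
        z = proteomics.row_zscores(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert z.iloc[0].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        z = proteomics.row_zscores(pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        assert len(z) == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        rows=st.lists(
            st.lists(st.floats(-50, 50, allow_nan=False), min_size=4, max_size=4),
            min_size=1, max_size=6,
        )
    )
    def test_output_rows_standardized(self, rows):
        z = proteomics.row_zscores(pd.DataFrame(rows))
        for _, row in z.iterrows():
            assert row.mean() == pytest.approx(0.0, abs=1e-9)
            assert row.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestClusterRows:
    def test_identical_pair_merges_first(self):
        mat = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]], index=["a", "b", "far"]
        )
        order, linkage = proteomics.cluster_rows(mat)
        assert set(linkage[0, :2].astype(int)) == {0, 1}
        assert order.index("far") in (0, 2)

    def test_single_row_identity(self):
        order, linkage = proteomics.cluster_rows(pd.DataFrame([[1.0, 2.0]], index=["x"]))
        assert order == ["x"] and linkage is None

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(8, 4)), index=[f"p{i}" for i in range(8)])
        _, link1 = proteomics.cluster_rows(mat)
        perm = mat.sample(frac=1, random_state=7)
        _, link2 = proteomics.cluster_rows(perm)
        # identical merge heights regardless of row order
        assert np.allclose(np.sort(link1[:, 2]), np.sort(link2[:, 2]))
        # cophenetic distances agree after relabeling
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        c1 = pd.DataFrame(squareform(cophenet(link1)), index=mat.index, columns=mat.index)
        c2 = pd.DataFrame(squareform(cophenet(link2)), index=perm.index, columns=perm.index)
        c2 = c2.loc[mat.index, mat.index]
        assert np.allclose(c1.values, c2.values)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        adj = proteomics.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(1e-8, 1.0, allow_nan=False), min_size=2, max_size=40)
    )
    def test_monotone_and_bounded(self, p):
        adj = proteomics.benjamini_hochberg(p)
        assert (adj <= 1.0).all() and (adj >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDiaDifferential:
    def _frame(self, a_vals, b_vals):
        cols = [f"a{i}" for i in range(len(a_vals))] + [f"b{i}" for i in range(len(b_vals))]
        groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
        df = pd.DataFrame([list(a_vals) + list(b_vals)], index=["prot"], columns=cols)
        return df, groups

    def test_welch_oracle(self):
        # equal variances, delta = -1.0: |t| = 6.124, p ~ 0.0037 at Welch df 4
        df, groups = self._frame([1.0, 1.2, 0.8], [2.0, 2.2, 1.8])
        res = proteomics.dia_differential(df, groups, "A", "B", method="welch")
        assert res.loc[0, "l2fc"] == pytest.approx(-1.0)
        t_expected = 1.0 / (0.2 * np.sqrt(2.0 / 3.0))
        p_expected = 2 * stats.t.sf(t_expected, 4)
        assert res.loc[0, "p_value"] == pytest.approx(p_expected, rel=1e-9)

    def test_identical_groups_not_passing(self):
        df, groups = self._frame([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        res = proteomics.dia_differential(df, groups, "A", "B", method="welch")
        assert res.loc[0, "l2fc"] == 0.0 and not res.loc[0, "pass_loose"]

    def test_strict_implies_loose(self):
        _, dia, groups, _ = sim_proteomics(seed=4)
        res = proteomics.dia_differential(dia, groups, "WT", "dnDEL")
        assert (res["pass_strict"] <= res["pass_loose"]).all()

    def test_missing_group_dropped(self):
        df, groups = self._frame([1.0, 1.2, 0.8], [np.nan, np.nan, np.nan])
        res = proteomics.dia_differential(df, groups, "A", "B", method="welch")
        assert len(res) == 0

    def test_moderated_shrinks_toward_common_variance(self):
        rng = np.random.default_rng(12)
        n = 60
        cols = ["a0", "a1", "a2", "b0", "b1", "b2"]
        groups = {c: c[0].upper() for c in cols}
        mat = pd.DataFrame(
            rng.normal(0, 0.3, size=(n, 6)), columns=cols,
            index=[f"p{i}" for i in range(n)],
        )
        mat.iloc[0, :3] += 1.5  # one true shift
        res = proteomics.dia_differential(mat, groups, "A", "B").set_index("protein_id")
        assert res.loc["p0", "pass_strict"]
        assert res.drop("p0")["pass_strict"].mean() < 0.1

    def test_moderated_matches_limma_on_fixture(self, tmp_path):
        """Cross-check the moderated t against the reference R implementation."""
        import shutil
        import subprocess

        rng = np.random.default_rng(7)
        n = 25
        mat = rng.normal(20, 0.5, size=(n, 6))
        mat[:5, :3] += 1.0
        csv = tmp_path / "m.csv"
        pd.DataFrame(mat).to_csv(csv, index=False)
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.csv(commandArgs(TRUE)[1]))
            design <- cbind(Intercept=1, A=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(m, design))
            cat(fit$p.value[, "A"], sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        )
        limma_p = np.array([float(x) for x in out.stdout.split()])
        cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        groups = {c: c[0].upper() for c in cols}
        df = pd.DataFrame(mat, columns=cols, index=[f"p{i}" for i in range(n)])
        res = proteomics.dia_differential(df, groups, "A", "B").set_index("protein_id")
        ours = res["p_value"].to_numpy()
        assert np.allclose(np.log10(ours), np.log10(limma_p), atol=0.2)
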