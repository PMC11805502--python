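"""Differential-expression pipeline against closed forms, brute force and limma."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tendonquant as tq
from tendonquant import array_stats
from tendonquant.array_stats import (
    ModeratedFitParams,
    ModeratedTTest,
    average_replicate_probes,
    classify_degs,
    ebayes_moderate,
    filter_low_expression,
    fit_two_group,
    read_series_matrix,
)


def _toy_matrix(values, samples=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)


class TestFilter:
    def test_keeps_gene_above_cutoff_in_three_samples_removes_two(self):
        # cutoff is the overall median; rows engineered around it
        m = _toy_matrix(
            [
                [9, 9, 9, 1],  # above cutoff in 3 samples -> kept
                [9, 9, 1, 1],  # above in exactly 2 -> removed
                [1, 1, 1, 1],  # never above -> removed
                [9, 9, 9, 1],  # above in 3 -> kept
            ]
        )
        # eight 9s and eight 1s: the overall median (cutoff) is 5
        kept = filter_low_expression(m)
        assert list(kept.index) == ["g0", "g3"]

    def test_all_equal_values_remove_everything(self):
        m = _toy_matrix(np.full((5, 4), 3.0))
        assert len(filter_low_expression(m)) == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_low_expression(pd.DataFrame())

    def test_planted_low_expression_fraction_recovered(self):
        config = tq.SynthExprConfig(n_genes=3000, low_expression_fraction=0.3, seed=4)
        synth = tq.generate_expression_matrix(config)
        kept = filter_low_expression(synth.matrix)
        kept_genes = set(
            synth.probe_map.set_index("probe_id").loc[kept.index, "gene_id"]
        )
        removed_frac = 1 - len(set(synth.truth.gene_id) & kept_genes) / len(synth.truth)
        assert abs(removed_frac - 0.3) < 0.03


class TestProbeAveraging:
    def test_replicates_average_and_unique_pass_through(self):
        m = pd.DataFrame(
            {"s1": [1.0, 3.0, 7.0], "s2": [2.0, 4.0, 8.0]},
            index=["pA1", "pA2", "pB"],
        )
        pmap = pd.Series({"pA1": "A", "pA2": "A"})
        out = average_replicate_probes(m, pmap)
        assert out.loc["A", "s1"] == 2.0
        assert out.loc["pB", "s1"] == 7.0  # unmapped probe kept under probe id


class TestTwoGroupFit:
    def test_identical_groups_zero_effect(self):
        m = _toy_matrix(np.tile([[5.0, 6.0]], (3, 2)).reshape(3, 4))
        groups = pd.Series(["control", "control", "case", "case"], index=m.columns)
        # columns: control (5,6), case (5,6)
        m.iloc[:, 2:] = m.iloc[:, :2].to_numpy()
        fit = fit_two_group(m, groups)
        assert np.allclose(fit.effect, 0.0)

    def test_degenerate_variance_and_unit_effect(self):
        m = _toy_matrix([[0.0, 0.0, 1.0, 1.0]])
        groups = pd.Series(["control", "control", "case", "case"], index=m.columns)
        fit = fit_two_group(m, groups)
        assert fit.effect.iloc[0] == 1.0
        assert fit.sigma2.iloc[0] == 0.0
        assert fit.df_residual == 2

    def test_matches_per_gene_least_squares(self):
        rng = np.random.default_rng(7)
        m = _toy_matrix(rng.normal(8, 1, (20, 10)))
        groups = pd.Series(["control"] * 5 + ["case"] * 5, index=m.columns)
        fit = fit_two_group(m, groups)
        design = np.column_stack([np.ones(10), (groups == "case").astype(float)])
        for i in range(20):
            beta, res, *_ = np.linalg.lstsq(design, m.iloc[i].to_numpy(), rcond=None)
            assert fit.effect.iloc[i] == pytest.approx(beta[1])
            assert fit.sigma2.iloc[i] == pytest.approx(res[0] / 8)

    def test_small_group_rejected(self):
        m = _toy_matrix(np.ones((3, 3)))
        groups = pd.Series(["control", "case", "case"], index=m.columns)
        with pytest.raises(ValueError):
            fit_two_group(m, groups)


class TestModeration:
    def _fit(self, sigma2, effect=None, dg=2, n1=2, n2=2):
        sigma2 = pd.Series(np.asarray(sigma2, float))
        effect = pd.Series(
            np.ones(len(sigma2)) if effect is None else np.asarray(effect, float)
        )
        return ModeratedFitParams(effect=effect, sigma2=sigma2, df_residual=dg, n1=n1, n2=n2)

    def _posterior_var(self, de, fit):
        # back the posterior variance out of the reported t-statistic
        se = fit.effect.to_numpy() / de["t"].to_numpy()
        return se**2 / (1.0 / fit.n1 + 1.0 / fit.n2)

    def test_posterior_variance_formula(self):
        fit = self._fit([4.0] * 10, dg=2)
        de = ebayes_moderate(fit, prior_df=4.0, prior_scale=1.0)
        np.testing.assert_allclose(self._posterior_var(de, fit), 2.0)  # (4*1+2*4)/6

    def test_infinite_prior_df_limit(self):
        fit = self._fit([0.5, 4.0, 9.0], dg=2)
        de = ebayes_moderate(fit, prior_df=np.inf, prior_scale=1.0)
        np.testing.assert_allclose(self._posterior_var(de, fit), 1.0)

    def test_zero_prior_df_reduces_to_ordinary_pooled_t(self):
        rng = np.random.default_rng(8)
        m = _toy_matrix(rng.normal(0, 1, (50, 8)))
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=m.columns)
        de = ebayes_moderate(fit_two_group(m, groups), prior_df=0.0)
        for i in range(0, 50, 7):
            t, p = stats.ttest_ind(
                m.iloc[i, 4:], m.iloc[i, :4], equal_var=True
            )
            assert de["t"].iloc[i] == pytest.approx(t)
            assert de["pvalue"].iloc[i] == pytest.approx(p)

    def test_all_zero_variances_not_estimable(self):
        with pytest.raises(ValueError, match="not estimable"):
            ebayes_moderate(self._fit([0.0] * 200))

    def test_group_label_swap_flips_effect_keeps_p(self):
        rng = np.random.default_rng(9)
        m = _toy_matrix(rng.normal(0, 1, (100, 8)))
        g1 = pd.Series(["control"] * 4 + ["case"] * 4, index=m.columns)
        g2 = pd.Series(["case"] * 4 + ["control"] * 4, index=m.columns)
        de1 = ebayes_moderate(fit_two_group(m, g1))
        de2 = ebayes_moderate(fit_two_group(m, g2))
        np.testing.assert_allclose(de1["log2fc"], -de2["log2fc"])
        np.testing.assert_allclose(de1["pvalue"], de2["pvalue"])

    def test_prior_recovery_on_synthetic_genes(self):
        config = tq.SynthExprConfig(
            n_genes=5000, prior_df=4.0, prior_scale=0.25,
            de_fraction=0.0, low_expression_fraction=0.0, replicate_probe_fraction=0.0,
            seed=10,
        )
        synth = tq.generate_expression_matrix(config)
        de = ebayes_moderate(fit_two_group(synth.matrix, synth.groups))
        assert de.attrs["prior_df"] == pytest.approx(4.0, rel=0.10)
        assert de.attrs["prior_scale"] == pytest.approx(0.25, rel=0.10)

    def test_matches_limma_reference(self, tmp_path):
        """Independent cross-check: moderated t and p agree with the
        Bioconductor limma implementation on the same matrix."""
        rng = np.random.default_rng(11)
        m = _toy_matrix(rng.normal(8, 1, (300, 8)))
        m.iloc[:30, 4:] += 1.5
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=m.columns)
        de = ebayes_moderate(fit_two_group(m, groups))
        mat_path = tmp_path / "mat.tsv"
        m.to_csv(mat_path, sep="\t")
        script = tmp_path / "limma_check.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(limma))
                m <- as.matrix(read.delim("{mat_path}", row.names=1))
                design <- cbind(Intercept=1, case=c(rep(0,4), rep(1,4)))
                fit <- eBayes(lmFit(m, design))
                out <- data.frame(t=fit$t[,"case"], pvalue=fit$p.value[,"case"])
                write.csv(out, "{tmp_path / 'r_de.csv'}")
                cat(fit$df.prior, fit$s2.prior)
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        d0_r, s0_r = map(float, proc.stdout.split()[-2:])
        ref = pd.read_csv(tmp_path / "r_de.csv", index_col=0)
        np.testing.assert_allclose(de["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(de["pvalue"], ref["pvalue"], rtol=1e-6)
        assert de.attrs["prior_df"] == pytest.approx(d0_r, rel=1e-4)
        assert de.attrs["prior_scale"] == pytest.approx(s0_r, rel=1e-4)


class TestClassification:
    def _de(self, effects, pvalues):
        return pd.DataFrame(
            {"log2fc": effects, "t": np.zeros(len(effects)), "pvalue": pvalues,
             "padj": pvalues},
            index=[f"g{i}" for i in range(len(effects))],
        )

    def test_volcano_thresholds(self):
        de, counts = classify_degs(
            self._de([1.5, 0.8, -1.5], [0.01, 0.01, 0.01]), 0.05, 1.0
        )
        assert list(de["class"]) == ["up", "ns", "down"]
        assert counts == {"up": 1, "down": 1, "ns": 1}

    def test_p_exactly_at_threshold_is_not_significant(self):
        de, counts = classify_degs(self._de([1.5], [0.05]), 0.05, 1.0)
        assert counts["ns"] == 1

    def test_sign_only_classification_without_lfc_threshold(self):
        de, counts = classify_degs(self._de([0.399, -0.1], [0.035, 0.2]), 0.05, None)
        assert list(de["class"]) == ["up", "ns"]

    def test_counts_partition_total(self):
        rng = np.random.default_rng(12)
        de, counts = classify_degs(
            self._de(rng.normal(0, 1, 500), rng.random(500)), 0.05, 1.0
        )
        assert counts["up"] + counts["down"] + counts["ns"] == 500


class TestEstimatorInterface:
    def test_sklearn_style_fit_exposes_trailing_underscore_attributes(self):
        config = tq.SynthExprConfig(n_genes=400, low_expression_fraction=0.0, seed=13)
        synth = tq.generate_expression_matrix(config)
        est = ModeratedTTest().fit(synth.matrix.T, synth.groups.to_numpy())
        assert est.pvalue_.shape[0] == len(synth.matrix)
        assert est.prior_df_ > 0
        assert set(est.counts_) == {"up", "down", "ns"}
        assert est.get_params()["p_threshold"] == 0.05


class TestSeriesMatrix:
    def test_round_trip_parse(self, tmp_path):
        text = "\n".join(
            [
                "!Series_title\t\"synthetic fixture\"",
                '!Sample_geo_accession\t"GSM1"\t"GSM2"\t"GSM3"\t"GSM4"',
                '!Sample_characteristics_ch1\t"state: normal"\t"state: normal"\t"state: lesion"\t"state: lesion"',
                "!series_matrix_table_begin",
                '"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\t"GSM4"',
                '"p1"\t7.1\t7.2\t8.1\t8.3',
                '"p2"\t5.0\t5.1\t5.2\t4.9',
                "!series_matrix_table_end",
            ]
        )
        path = tmp_path / "series_matrix.txt"
        path.write_text(text)
        matrix, samples = read_series_matrix(path)
        assert matrix.shape == (2, 4)
        assert matrix.loc["p1", "GSM3"] == 8.1
        assert samples.loc["GSM4", "Sample_characteristics_ch1"] == "state: lesion"

    def test_missing_table_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("!Series_title\tnothing here\n")
        with pytest.raises(ValueError, match="table"):
            read_series_matrix(path)

    def test_sheathed_exclusion_list_is_ten_unique_gsm_ids(self):
        ids = array_stats.GSE26051_SHEATHED_SAMPLES
        assert len(ids) == 10 and len(set(ids)) == 10
        assert all(i.startswith("GSM") for i in ids)


def test_full_pipeline_recovers_planted_de_genes():
    """End-to-end: filter, probe-average, fit, moderate, classify; the planted
    DE genes dominate the significant calls."""
    config = tq.SynthExprConfig(n_genes=2000, de_fraction=0.05, seed=14)
    synth = tq.generate_expression_matrix(config)
    de, counts = array_stats.differential_expression(
        synth.matrix, synth.groups, probe_map=synth.probe_map
    )
    de_genes = set(synth.truth.loc[synth.truth.is_de, "gene_id"])
    called = set(de.index[de["class"] != "ns"])
    recovered = len(de_genes & called) / len(de_genes)
    assert recovered > 0.9
    # false positive rate among null genes near the nominal alpha
    null_called = called - de_genes
    n_null = len(de) - len(de_genes & set(de.index))
    assert len(null_called) / n_null < 0.1


def test_log2_transform_requires_positive_values():
    with pytest.raises(ValueError):
        array_stats.log2_transform(_toy_matrix([[1.0, -2.0]]))
    out = array_stats.log2_transform(_toy_matrix([[2.0, 8.0]]))
    assert out.iloc[0, 0] == 1.0 and out.iloc[0, 1] == 3.0
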