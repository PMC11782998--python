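"""Roll-up, filtering, imputation, TMM, batch removal, moderated tests."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tandemquant import de_pipeline as dp
from tandemquant import synthetic_data as sd


def small_matrix(values, genotype=None, run_order=None):
    values = pd.DataFrame(values)
    values.index = [f"P{i}" for i in range(len(values))]
    n = values.shape[1]
    values.columns = [f"S{i}" for i in range(n)]
    if genotype is None:
        genotype = ["KO"] * (n // 2) + ["WT"] * (n - n // 2)
    samples = pd.DataFrame(
        {
            "genotype": genotype,
            "age": np.full(n, 10.0),
            "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "run_order": run_order if run_order is not None else np.arange(1, n + 1),
        },
        index=values.columns,
    )
    return dp.AbundanceMatrix(values, samples)


class TestContainer:
    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            small_matrix([[-1.0, 2.0, 3.0, 4.0]])

    def test_metadata_required_for_every_sample(self):
        values = pd.DataFrame(
            [[1.0, 2.0]], index=["P0"], columns=["S0", "S1"]
        )
        samples = pd.DataFrame(
            {"genotype": ["KO"], "age": [10], "sex": ["M"], "run_order": [1]},
            index=["S0"],
        )
        with pytest.raises(ValueError, match="without metadata"):
            dp.AbundanceMatrix(values, samples)

    def test_duplicate_protein_ids_rejected(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["P0", "P0"], columns=["S0", "S1"]
        )
        samples = pd.DataFrame(
            {
                "genotype": ["KO", "WT"],
                "age": [10, 10],
                "sex": ["M", "F"],
                "run_order": [1, 2],
            },
            index=["S0", "S1"],
        )
        with pytest.raises(ValueError, match="unique"):
            dp.AbundanceMatrix(values, samples)


class TestTopN:
    def test_top3_sums_same_peptides_in_every_sample(self):
        peps = pd.DataFrame(
            {
                "s1": [10.0, 8.0, 6.0, 4.0],
                "s2": [1.0, 80.0, 6.0, 400.0],
            },
            index=["p1", "p2", "p3", "p4"],
        )
        mapping = pd.Series("prot", index=peps.index)
        # means: p4 (202) > p2 (44) > p1 (5.5) > p3 (6)? -> p4, p2, p3
        out = dp.topn_protein_quant(peps, mapping, n=3)
        means = peps.mean(axis=1)
        top = means.nlargest(3).index
        assert out.loc["prot", "s1"] == peps.loc[top, "s1"].sum()
        assert out.loc["prot", "s2"] == peps.loc[top, "s2"].sum()

    def test_single_peptide_protein_passthrough(self):
        peps = pd.DataFrame({"s1": [5.0], "s2": [7.0]}, index=["pep"])
        out = dp.topn_protein_quant(peps, {"pep": "prot"}, n=3)
        assert out.loc["prot"].tolist() == [5.0, 7.0]

    def test_n_equals_total_sums_everything(self):
        peps = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]
        )
        out = dp.topn_protein_quant(peps, dict.fromkeys(peps.index, "prot"), n=3)
        assert out.loc["prot", "s1"] == 6.0

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            dp.topn_protein_quant(pd.DataFrame({"s1": [1.0]}, index=["p"]), {})


class TestFilter:
    def test_all_zero_removed_by_condition_mean_rule(self):
        m = small_matrix(
            [[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0]],
        )
        out = dp.filter_uninformative(m)
        assert list(out.proteins) == ["P1"]

    def test_constant_protein_removed_by_variance_rule(self):
        m = small_matrix(
            [[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]],
        )
        out = dp.filter_uninformative(m)
        assert list(out.proteins) == ["P1"]

    def test_zero_in_one_condition_retained(self):
        m = small_matrix(
            [[0.0, 0.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]],
            genotype=["KO", "KO", "WT", "WT"],
        )
        out = dp.filter_uninformative(m)
        assert "P0" in out.proteins

    def test_all_removed_signalled(self):
        m = small_matrix([[0.0, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="all features"):
            dp.filter_uninformative(m)


class TestImputation:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.0, 4.0, 8.0, 5.0], [2.0, 4.0, 8.0, 5.0]),
            ([0.0, 0.0, 6.0, 6.0], [3.0, 3.0, 6.0, 6.0]),
            ([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]),
        ],
    )
    def test_midpoint_of_row_minimum(self, row, expected):
        m = small_matrix([row])
        out = dp.impute_zeros_midpoint(m)
        assert out.values.iloc[0].tolist() == expected

    def test_all_zero_row_rejected_with_filter_hint(self):
        m = small_matrix([[0.0, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="filter"):
            dp.impute_zeros_midpoint(m)

    def test_result_independent_of_sample_order(self):
        m = small_matrix([[0.0, 4.0, 2.0, 8.0]])
        shuffled = dp.AbundanceMatrix(
            m.values[["S3", "S0", "S2", "S1"]], m.samples
        )
        a = dp.impute_zeros_midpoint(m).values
        b = dp.impute_zeros_midpoint(shuffled).values
        assert a.loc["P0", "S0"] == b.loc["P0", "S0"] == 1.0


class TestTMM:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(3, 1, 200)
        m = small_matrix(np.column_stack([col] * 4))
        factors, _ = dp.tmm_factors(m)
        assert np.allclose(factors["tmm"], 1.0, atol=1e-9)
        assert np.allclose(factors["scaling"], 1.0, atol=1e-9)

    def test_doubled_sample_effective_factor_ratio_two(self):
        rng = np.random.default_rng(1)
        col = rng.lognormal(5, 1, 500)
        m = small_matrix(np.column_stack([col, 2 * col, col, col]))
        factors, norm = dp.tmm_factors(m)
        ratio = factors["scaling"]["S1"] / factors["scaling"]["S0"]
        assert ratio == pytest.approx(2.0, abs=1e-6)
        # normalised columns coincide again
        assert np.allclose(norm.values["S1"], norm.values["S0"], rtol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(4, 1, size=(300, 4))
        f1, _ = dp.tmm_factors(small_matrix(X))
        f2, _ = dp.tmm_factors(small_matrix(X * 7.3))
        assert np.allclose(f1["tmm"], f2["tmm"], rtol=1e-9)
        assert np.allclose(f1["scaling"], f2["scaling"], rtol=1e-9)

    def test_factor_product_is_one(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(4, 1, size=(400, 6)) * rng.lognormal(0, 0.3, 6)
        factors, _ = dp.tmm_factors(small_matrix(X, genotype=["KO"] * 3 + ["WT"] * 3))
        assert np.prod(factors["tmm"]) == pytest.approx(1.0, rel=1e-9)
        assert np.prod(factors["scaling"]) == pytest.approx(1.0, rel=1e-9)

    def test_nonpositive_entries_rejected(self):
        m = small_matrix([[0.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="positive"):
            dp.tmm_factors(m)

    def test_matches_edger_reference(self, tmp_path):
        """Independent oracle: edgeR's calcNormFactors on integer counts."""
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(20, 0.05, size=(500, 6)).astype(float) + 1
        counts *= rng.lognormal(0, 0.4, 6)
        counts = np.round(counts)
        m = small_matrix(counts, genotype=["KO"] * 3 + ["WT"] * 3)
        factors, _ = dp.tmm_factors(m)
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}"))
            f <- calcNormFactors(x, method="TMM")
            cat(f, sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(factors["tmm"].to_numpy(), ref, rtol=0.02, atol=0.01)


class TestBatchRemoval:
    def _planted(self, delta=1.0, seed=0, n_prot=400):
        rng = np.random.default_rng(seed)
        n = 18
        genotype = np.array(["KO"] * 9 + ["WT"] * 9)
        batch = np.tile([0, 1, 2], 6)  # balanced across genotype
        log2 = rng.normal(20, 1.5, size=(n_prot, 1)) + rng.normal(
            0, 0.3, size=(n_prot, n)
        )
        lfc = np.zeros(n_prot)
        lfc[:40] = 1.5
        log2 += lfc[:, None] * (genotype == "KO")
        log2 += delta * (batch == 1)
        values = pd.DataFrame(
            2.0**log2,
            index=[f"P{i}" for i in range(n_prot)],
            columns=[f"S{i}" for i in range(n)],
        )
        samples = pd.DataFrame(
            {
                "genotype": genotype,
                "age": 10.0,
                "sex": "M",
                "run_order": np.arange(1, n + 1),
            },
            index=values.columns,
        )
        return dp.AbundanceMatrix(values, samples), batch, lfc

    def test_no_batch_effect_is_near_identity(self):
        m, batch, _ = self._planted(delta=0.0)
        out = dp.remove_batch_arsyn(m, batch=batch)
        logdiff = np.log2(out.values.to_numpy()) - np.log2(m.values.to_numpy())
        # only batch-mean noise (O(1/sqrt(n)) of residual sd) is touched
        assert np.abs(logdiff).max() < 0.5
        assert np.abs(logdiff).mean() < 0.1

    def test_planted_offset_removed_genotype_preserved(self):
        delta = 1.0
        m, batch, lfc = self._planted(delta=delta, seed=3)
        out = dp.remove_batch_arsyn(m, batch=batch)

        def block_gap(mat):
            log2 = np.log2(mat.values.to_numpy())
            return log2[:, batch == 1].mean() - log2[:, batch != 1].mean()

        assert abs(block_gap(m)) > 0.9 * delta
        assert abs(block_gap(out)) < 0.05 * delta

        def est_lfc(mat):
            log2 = np.log2(mat.values.to_numpy())
            ko = mat.genotype.to_numpy() == "KO"
            return log2[:, ko].mean(axis=1) - log2[:, ~ko].mean(axis=1)

        change = est_lfc(out)[:40] - est_lfc(m)[:40]
        assert np.abs(change).max() < 0.05 * 1.5

    def test_single_batch_rejected(self):
        m, _, _ = self._planted()
        with pytest.raises(ValueError, match="2 batches"):
            dp.remove_batch_arsyn(m, batch=np.zeros(18, dtype=int))

    def test_confounded_design_rejected(self):
        m, _, _ = self._planted()
        confounded = (m.genotype.to_numpy() == "KO").astype(int)
        with pytest.raises(ValueError, match="confounded"):
            dp.remove_batch_arsyn(m, batch=confounded)

    def test_assign_batches_consecutive_blocks(self):
        batches = dp.assign_batches([5, 1, 3, 2, 6, 4], 3)
        assert list(batches) == [2, 0, 1, 0, 2, 1]


class TestVoomWeights:
    def test_homoskedastic_weights_flat(self):
        rng = np.random.default_rng(0)
        log2 = rng.uniform(14, 22, size=(800, 1)) + rng.normal(
            0, 0.3, size=(800, 12)
        )
        counts = 2.0**log2
        design = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        _y, w = dp.voom_weights(counts, design)
        mid = np.median(w)
        assert np.quantile(w, 0.9) / np.quantile(w, 0.1) < 3.0

    def test_planted_mean_variance_trend_gives_monotone_weights(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(12, 24, size=1000))
        sds = np.interp(base, [12, 24], [1.0, 0.1])  # variance falls with mean
        log2 = base[:, None] + rng.normal(0, 1, size=(1000, 12)) * sds[:, None]
        counts = 2.0**log2
        design = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        y, w = dp.voom_weights(counts, design)
        rho = spearmanr(y.mean(axis=1), w.mean(axis=1)).statistic
        assert rho > 0.9

    def test_weights_positive_finite(self):
        rng = np.random.default_rng(2)
        counts = rng.lognormal(10, 2, size=(200, 8))
        design = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        _y, w = dp.voom_weights(counts, design)
        assert np.isfinite(w).all() and (w > 0).all()

    def test_design_wider_than_samples_rejected(self):
        counts = np.full((10, 3), 100.0)
        with pytest.raises(ValueError):
            dp.voom_weights(counts, np.eye(3))


class TestModeratedT:
    def _fit(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        D = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
        Y = rng.normal(0, 1, size=(n, 12)) * rng.uniform(0.5, 2.0, size=(n, 1))
        return Y, D

    def test_zero_prior_df_is_ordinary_t(self):
        Y, D = self._fit()
        beta, se_u, sigma, df = dp._fit_ols(Y, D)
        params = dp.ModerationParams(prior_var=1.0, prior_df=0.0)
        mod = dp.moderated_t(beta[:, 1], se_u[:, 1], sigma, df, params)
        ordinary = beta[:, 1] / (se_u[:, 1] * sigma)
        assert np.allclose(mod["t"], ordinary, rtol=1e-12)

    def test_infinite_prior_df_pools_completely(self):
        Y, D = self._fit()
        beta, se_u, sigma, df = dp._fit_ols(Y, D)
        params = dp.ModerationParams(prior_var=1.3, prior_df=np.inf)
        mod = dp.moderated_t(beta[:, 1], se_u[:, 1], sigma, df, params)
        assert np.allclose(mod["posterior_var"], 1.3)

    def test_hyperparameter_recovery_from_scaled_chisq(self):
        """Variances drawn from the model's own prior are recovered."""
        rng = np.random.default_rng(5)
        d, d0, s0 = 10, 8.0, 0.7
        prior = s0 * d0 / rng.chisquare(d0, size=20000)
        s2 = prior * rng.chisquare(d, size=20000) / d
        est = dp.estimate_moderation_params(s2, d)
        assert est.prior_df == pytest.approx(d0, rel=0.15)
        assert est.prior_var == pytest.approx(s0, rel=0.1)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, g = 18, 2000
        D = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], [8, 10])])
        Y = rng.normal(size=(g, n)) * rng.uniform(0.5, 1.5, size=(g, 1))
        beta, se_u, sigma, df = dp._fit_ols(Y, D)
        mod = dp.moderated_t(beta[:, 1], se_u[:, 1], sigma, df)
        rate = (mod["p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: limma voom + lmFit + eBayes on the same data."""
        rng = np.random.default_rng(21)
        n, g = 12, 300
        cond = np.repeat([0.0, 1.0], 6)
        age = rng.uniform(8, 14, n)
        log2 = rng.normal(18, 2, size=(g, 1)) + rng.normal(0, 0.4, size=(g, n))
        log2[:20] += 1.0 * cond
        counts = np.round(2.0 ** (log2 - 8))  # keep counts moderate
        counts = np.clip(counts, 1, None)
        pd.DataFrame(counts).to_csv(tmp_path / "c.csv", index=False)
        pd.DataFrame({"cond": cond, "age": age}).to_csv(
            tmp_path / "d.csv", index=False
        )
        script = tmp_path / "limma.R"
        script.write_text(
            f"""
            suppressMessages(library(limma))
            counts <- as.matrix(read.csv("{tmp_path / 'c.csv'}"))
            meta <- read.csv("{tmp_path / 'd.csv'}")
            design <- model.matrix(~ cond + age, data=meta)
            v <- voom(counts, design)
            fit <- eBayes(lmFit(v, design))
            tab <- topTable(fit, coef=2, number=Inf, sort.by="none")
            write.csv(tab, "{tmp_path / 'out.csv'}")
            cat(fit$df.prior, sqrt(fit$s2.prior), sep="\\n")
            """
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        est = dp.ModeratedDE(contrast=("KO", "WT"))
        X = pd.DataFrame(counts).T
        y = np.where(cond == 1, "KO", "WT")
        est.fit(X, y, covariates=pd.DataFrame({"age": age}))
        r = est.results_
        assert np.allclose(r["log2fc"], ref["logFC"], atol=0.02)
        corr = np.corrcoef(r["t"], ref["t"])[0, 1]
        assert corr > 0.99
        assert np.allclose(r["t"], ref["t"], rtol=0.1, atol=0.2)


class TestBH:
    def bh_oracle(self, p):
        """Brute-force step-up: adj_i = min over j>=i of p_(j)·m/j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_textbook_example(self):
        assert np.allclose(
            dp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert dp.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.bh_adjust([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(dp.bh_adjust(p), self.bh_oracle(p), atol=1e-12)

    def test_monotone_in_sorted_inputs(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=30))
        adj = dp.bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestCallDE:
    def _frame(self, log2fc, adj_p):
        return pd.DataFrame({"log2fc": log2fc, "adj_p": adj_p})

    def test_threshold_arithmetic(self):
        out = dp.call_de(self._frame([0.6], [0.04]))
        assert out["significant"].iloc[0] and out["direction"].iloc[0] == "up"

    def test_fc_below_cut_not_significant(self):
        out = dp.call_de(self._frame([np.log2(1.4)], [1e-6]))
        assert not out["significant"].iloc[0]

    def test_boundary_p_strict(self):
        out = dp.call_de(self._frame([2.0], [0.05]))
        assert not out["significant"].iloc[0]

    def test_down_direction(self):
        out = dp.call_de(self._frame([-1.0], [0.001]))
        assert out["direction"].iloc[0] == "down"


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(10, 1, 100)
        m = small_matrix(np.column_stack([col, col, col * 2, col * 3]))
        scores, _ = dp.pca_scores(m, k=2)
        assert np.allclose(scores.loc["S0"], scores.loc["S1"], atol=1e-8)

    def test_separated_groups_on_top_components(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        base = rng.normal(18, 2, size=(300, 1))
        log2 = base + rng.normal(0, 0.2, size=(300, 12))
        log2[:100, :6] += 2.0
        m = small_matrix(2.0**log2, genotype=["KO"] * 6 + ["WT"] * 6)
        scores, _ = dp.pca_scores(m, k=2)
        s = silhouette_score(scores, m.genotype)
        assert s > 0.5

    def test_variance_shares_bounded(self):
        rng = np.random.default_rng(2)
        m = small_matrix(rng.lognormal(8, 1, size=(50, 6)), genotype=["KO"] * 3 + ["WT"] * 3)
        _scores, share = dp.pca_scores(m, k=3)
        assert share.sum() <= 1.0 + 1e-9

    def test_k_beyond_rank_rejected(self):
        rng = np.random.default_rng(3)
        m = small_matrix(rng.lognormal(8, 1, size=(50, 4)))
        with pytest.raises(ValueError):
            dp.pca_scores(m, k=5)


class TestFullPipeline:
    def test_stage_order_and_dimension_log(self):
        cfg = sd.SimulationConfig(seed=8, n_proteins=400)
        m, _ = sd.simulate_abundance_matrix(cfg)
        res = dp.run_de_pipeline(m)
        names = [s["stage"] for s in res.stages]
        assert names == ["input", "filter", "impute", "tmm", "batch"]
        sizes = [s["proteins"] for s in res.stages]
        assert sizes[0] >= sizes[1] and len(res.results) == sizes[-1]

    def test_recovers_planted_de(self):
        cfg = sd.SimulationConfig(seed=9, n_proteins=800)
        m, truth = sd.simulate_abundance_matrix(cfg)
        res = dp.run_de_pipeline(m)
        sig = res.results["significant"]
        de = truth.is_de.loc[res.results.index]
        sens = (sig & de).sum() / de.sum()
        fdp = (sig & ~de).sum() / max(int(sig.sum()), 1)
        assert sens > 0.6
        assert fdp < 0.2
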