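import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from atrimir.data_io import CountMatrix
from atrimir.diffexpr import (
    Contrast,
    DispersionEstimate,
    chi2_upper_tail,
    estimate_common_dispersion,
    fit_nb_glm_lrt,
    run_two_set_de,
)

CONTRAST = Contrast("SR60_vs_SR40", "SR60", "SR40")


def four_samples():
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2"],
            "group": ["SR40", "SR40", "SR60", "SR60"],
            "age": [40, 40, 60, 60],
            "sex": ["F", "M", "F", "M"],
        }
    )


class TestChi2UpperTail:
    @pytest.mark.parametrize(
        "stat,expected",
        [(13.23, 2.8e-4), (6.34, 0.012), (6.49, 0.011), (5.82, 0.016)],
    )
    def test_reference_values(self, stat, expected):
        p = chi2_upper_tail(stat, 1)
        # agreement at the precision the reference values carry (2 s.f.)
        assert float(f"{p:.1e}") == pytest.approx(expected, rel=0.06)

    def test_zero_statistic(self):
        assert chi2_upper_tail(0.0, 1) == 1.0
        assert chi2_upper_tail(0.0, 4) == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi2_upper_tail(-1.0, 1)


class TestContrast:
    def test_identical_groups_rejected(self):
        with pytest.raises(ValueError):
            Contrast("x", "SR60", "SR60")


class TestFitNbGlmLrt:
    def test_identity_case(self, six_samples):
        cm = CountMatrix(
            pd.DataFrame(
                {s: [10] for s in six_samples["sample_id"]}, index=["f"]
            )
        )
        res = fit_nb_glm_lrt(cm, six_samples, CONTRAST, phi=0.1)
        row = res.iloc[0]
        assert row["logFC"] == pytest.approx(0.0, abs=1e-8)
        assert row["LR"] == pytest.approx(0.0, abs=1e-8)
        assert row["pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_poisson_closed_form(self):
        # equal library sizes via a filler feature; group means 5 vs 20
        counts = pd.DataFrame(
            {"a1": [4, 96], "a2": [6, 94], "b1": [14, 86], "b2": [26, 74]},
            index=["f", "filler"],
        )
        cm = CountMatrix(counts)
        res = fit_nb_glm_lrt(cm, four_samples(), CONTRAST, phi=0.0, prior_count=0.0)
        row = res.set_index("feature").loc["f"]
        expected_lr = 2 * (10 * np.log(5 / 12.5) + 40 * np.log(20 / 12.5))
        assert row["LR"] == pytest.approx(expected_lr, abs=1e-6)
        assert row["logFC"] == pytest.approx(2.0, abs=1e-8)

    def test_matches_brute_force_nb_mle(self):
        # 2-vs-2 toy counts at phi = 0.5: compare the LR against direct
        # maximisation of the NB likelihood over per-group rates
        phi = 0.5
        y = np.array([3.0, 9.0, 30.0, 18.0])
        lib = np.array([1000.0, 1200.0, 900.0, 1100.0])
        counts = pd.DataFrame(
            {
                "a1": [3, 997], "a2": [9, 1191], "b1": [30, 870], "b2": [18, 1082],
            },
            index=["f", "filler"],
        )
        cm = CountMatrix(counts)

        def nb_ll(y, mu):
            r = 1.0 / phi
            return np.sum(
                gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
            )

        def best_rate_ll(yv, libv):
            # fine grid then golden refinement, independent of IRLS
            grid = np.geomspace(1e-6, 1.0, 4000)
            lls = [nb_ll(yv, g * libv) for g in grid]
            i = int(np.argmax(lls))
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(
                lambda g: -nb_ll(yv, g * libv),
                bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
                method="bounded",
                options={"xatol": 1e-12},
            )
            return -res.fun

        ll_full = best_rate_ll(y[:2], lib[:2]) + best_rate_ll(y[2:], lib[2:])
        ll_null = best_rate_ll(y, lib)
        expected_lr = 2 * (ll_full - ll_null)

        res = fit_nb_glm_lrt(cm, four_samples(), CONTRAST, phi=phi)
        lr = res.set_index("feature").loc["f", "LR"]
        assert lr == pytest.approx(expected_lr, abs=1e-4)

    def test_poisson_limit_equivalence(self):
        # phi -> 0 must converge to the closed-form Poisson LRT
        rng = np.random.default_rng(11)
        Y = rng.poisson(20, size=(50, 4))
        Y[:, 2:] = rng.poisson(35, size=(50, 2))
        cm = CountMatrix(
            pd.DataFrame(Y + 1, index=[f"g{i}" for i in range(50)],
                         columns=["a1", "a2", "b1", "b2"])
        )
        lib = cm.values.sum(axis=0).astype(float)
        res = fit_nb_glm_lrt(cm, four_samples(), CONTRAST, phi=1e-8)
        y = cm.values.astype(float)
        rate_a = y[:, :2].sum(1) / lib[:2].sum()
        rate_b = y[:, 2:].sum(1) / lib[2:].sum()
        rate_0 = y.sum(1) / lib.sum()
        mu_full = np.concatenate(
            [np.outer(rate_a, lib[:2]), np.outer(rate_b, lib[2:])], axis=1
        )
        mu_null = np.outer(rate_0, lib)
        lr_closed = 2 * (np.sum(y * np.log(mu_full / mu_null), axis=1)
                         - mu_full.sum(1) + mu_null.sum(1))
        assert np.allclose(res["LR"].to_numpy(), np.maximum(lr_closed, 0), atol=1e-3)

    def test_library_size_scaling_leaves_lr_and_logfc_unchanged(self, six_samples):
        rng = np.random.default_rng(3)
        y = rng.poisson([10, 10, 10, 30, 30, 30])
        filler = rng.integers(500, 600, 6)
        base = pd.DataFrame(
            np.vstack([y, filler]), index=["f", "filler"],
            columns=six_samples["sample_id"],
        )
        # multiply every library size by exactly 10 via the filler row
        lib = base.sum(axis=0)
        scaled = base.copy()
        scaled.loc["filler"] += 9 * lib.to_numpy()
        r1 = fit_nb_glm_lrt(CountMatrix(base), six_samples, CONTRAST, phi=0.1)
        r2 = fit_nb_glm_lrt(CountMatrix(scaled), six_samples, CONTRAST, phi=0.1)
        a = r1.set_index("feature").loc["f"]
        b = r2.set_index("feature").loc["f"]
        assert a["LR"] == pytest.approx(b["LR"], abs=1e-6)
        assert a["logFC"] == pytest.approx(b["logFC"], abs=1e-6)

    def test_negative_phi_rejected(self, six_samples):
        cm = CountMatrix(
            pd.DataFrame({s: [1] for s in six_samples["sample_id"]}, index=["f"])
        )
        with pytest.raises(ValueError):
            fit_nb_glm_lrt(cm, six_samples, CONTRAST, phi=-0.1)

    def test_null_pvalues_uniform(self, six_samples, null_nb_counts):
        res = fit_nb_glm_lrt(null_nb_counts, six_samples, CONTRAST, phi=0.1)
        ks = stats.kstest(res["pvalue"].dropna(), "uniform")
        assert ks.pvalue > 0.01


class TestDispersionEstimation:
    def _simulate(self, phi, seed, F=2000):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.normal(np.log(60), 1.0, F))
        lib = rng.uniform(0.9e6, 1.1e6, 6)
        base = mu[:, None] * lib[None, :] / 1e6
        if phi == 0:
            Y = rng.poisson(base)
        else:
            r = 1 / phi
            Y = rng.negative_binomial(r, r / (r + base))
        return CountMatrix(
            pd.DataFrame(Y, index=[f"g{i}" for i in range(F)],
                         columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        )

    def test_poisson_data_gives_near_zero_phi(self, six_samples):
        cm = self._simulate(0.0, seed=21)
        est = estimate_common_dispersion(cm, six_samples, CONTRAST)
        assert est.common_phi <= 0.01

    def test_recovers_generating_dispersion(self, six_samples):
        cm = self._simulate(0.1, seed=22)
        est = estimate_common_dispersion(cm, six_samples, CONTRAST)
        assert 0.07 <= est.common_phi <= 0.14

    def test_fixed_method_passthrough(self, six_samples):
        cm = self._simulate(0.1, seed=23, F=10)
        est = estimate_common_dispersion(
            cm, six_samples, CONTRAST, method="fixed", fixed_phi=0.2
        )
        assert est == DispersionEstimate(common_phi=0.2, method="fixed")

    def test_negative_phi_invalid(self):
        with pytest.raises(ValueError):
            DispersionEstimate(common_phi=-0.1, method="fixed")


class TestAgainstReferenceImplementation:
    """Cross-check the NB GLM against edgeR (glmFit/glmLRT, common dispersion)
    on the committed fixture; the two implementations are fully independent."""

    R_SCRIPT = """
    suppressMessages(library(edgeR))
    args <- commandArgs(trailingOnly=TRUE)
    counts <- read.delim(args[1], row.names=1)
    samples <- read.delim(args[2])
    keep <- samples$group %in% c("SR40", "SR60")
    y <- DGEList(counts=counts[, keep])
    y$samples$norm.factors <- 1
    group <- factor(samples$group[keep], levels=c("SR40", "SR60"))
    design <- model.matrix(~group)
    y <- estimateGLMCommonDisp(y, design)
    fit <- glmFit(y, design, dispersion=y$common.dispersion, prior.count=0)
    lrt <- glmLRT(fit, coef=2)
    out <- data.frame(feature=rownames(lrt$table),
                      dispersion=y$common.dispersion,
                      logFC=lrt$table$logFC, LR=lrt$table$LR)
    write.table(out, args[3], sep="\\t", quote=FALSE, row.names=FALSE)
    """

    def test_dispersion_and_lrt_match_edger(self, tmp_path, tiny_dir, six_samples):
        import subprocess

        script = tmp_path / "edger.R"
        script.write_text(self.R_SCRIPT)
        out = tmp_path / "edger.tsv"
        subprocess.run(
            ["Rscript", str(script), str(tiny_dir / "mirna_counts.tsv"),
             str(tiny_dir / "samples.tsv"), str(out)],
            check=True, capture_output=True, text=True,
        )
        ref = pd.read_csv(out, sep="\t").set_index("feature")
        cm = CountMatrix(
            pd.read_csv(tiny_dir / "mirna_counts.tsv", sep="\t", index_col=0),
            feature_kind="miRNA",
        )
        samples = pd.read_csv(tiny_dir / "samples.tsv", sep="\t")
        est = estimate_common_dispersion(cm, samples, CONTRAST)
        phi_ref = float(ref["dispersion"].iloc[0])
        assert est.common_phi == pytest.approx(phi_ref, rel=0.02)
        mine = fit_nb_glm_lrt(
            cm, samples, CONTRAST, phi=phi_ref, prior_count=0.0
        ).set_index("feature")
        joined = mine.join(ref, lsuffix="_py", rsuffix="_r").dropna()
        assert len(joined) == len(ref)
        assert np.allclose(joined["logFC_py"], joined["logFC_r"], atol=1e-4)
        assert np.allclose(joined["LR_py"], joined["LR_r"], atol=1e-3)


class TestRunTwoSetDe:
    def test_overlapping_groups_rejected(self, tiny_bundle):
        contrasts = [
            Contrast("c1", "SR60", "SR40"),
            Contrast("c2", "SR60", "SR50"),
        ]
        with pytest.raises(ValueError, match="share a group"):
            run_two_set_de(tiny_bundle["mirna"], tiny_bundle["samples"], contrasts)

    def test_planted_features_rank_high_and_rerun_identical(self, tiny_bundle):
        contrasts = [
            Contrast("SR60_vs_SR40", "SR60", "SR40"),
            Contrast("SR70_vs_SR50", "SR70", "SR50"),
        ]
        de1 = run_two_set_de(tiny_bundle["mirna"], tiny_bundle["samples"], contrasts)
        de2 = run_two_set_de(tiny_bundle["mirna"], tiny_bundle["samples"], contrasts)
        pd.testing.assert_frame_equal(de1, de2)  # deterministic rerun

        truth = tiny_bundle["truth_features"]
        planted = set(truth.loc[truth["kind"] == "miRNA", "feature"])
        hits = de1[de1["feature"].isin(planted)]
        # planted features sit at the top of both p-value lists
        for pcol in ("pvalue1", "pvalue2"):
            assert (hits[pcol] < 0.05).mean() >= 0.8
            planted_rank = de1[pcol].rank()[de1["feature"].isin(planted)].mean()
            assert planted_rank < 0.25 * len(de1)
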