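"""Moderated t DE, BH adjustment, and signature derivation."""

import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sarcotype import (
    all_pairwise_de,
    bh_adjust,
    derive_signatures,
    expression_filter,
    fit_moderated_de,
    gen_cohort,
    normalize,
)
from sarcotype.preprocess import NormalizedMatrix
from sarcotype.signatures import SignatureError, estimate_prior, trigamma_inverse
from sarcotype.simulate import CohortConfig, null_config


def _unit_norm(x: np.ndarray, samples=None) -> NormalizedMatrix:
    genes = [f"g{i}" for i in range(x.shape[0])]
    samples = samples or [f"s{i}" for i in range(x.shape[1])]
    logexpr = pd.DataFrame(x, index=genes, columns=samples)
    return NormalizedMatrix(
        logexpr, logexpr * 0 + 1.0, pd.Series(1.0, index=samples)
    )


def _labels(groups):
    return pd.Series(groups, index=[f"s{i}" for i in range(len(groups))])


class TestModeratedT:
    def test_hand_evaluated_formula(self):
        # 1 gene, two groups of 3, unit weights, injected d0=4, s0^2=0.5
        vals = np.array([[1.0, 2.0, 3.0, 5.0, 6.0, 7.0]])
        norm = _unit_norm(vals)
        labels = _labels([1, 1, 1, 2, 2, 2])
        res = fit_moderated_de(norm, labels, (2, 1), d0=4.0, s0_sq=0.5)
        log_fc = 6.0 - 2.0
        sg2 = (2.0 + 2.0) / 4  # pooled residual SS / (n - k)
        s_mod = (4.0 * 0.5 + 4 * sg2) / (4.0 + 4)
        v = 1 / 3 + 1 / 3
        t_expected = log_fc / np.sqrt(s_mod * v)
        assert res.table["t_mod"].iloc[0] == pytest.approx(t_expected, abs=1e-10)
        assert res.table["logFC"].iloc[0] == pytest.approx(4.0)
        assert res.table["df"].iloc[0] == 4

    def test_infinite_prior_df_pins_variance_to_prior(self):
        rng = np.random.default_rng(0)
        norm = _unit_norm(rng.normal(size=(20, 8)))
        labels = _labels([1] * 4 + [2] * 4)
        res = fit_moderated_de(norm, labels, (1, 2), d0=np.inf, s0_sq=0.7)
        v = 1 / 4 + 1 / 4
        expected_t = res.table["logFC"] / np.sqrt(0.7 * v)
        assert np.allclose(res.table["t_mod"], expected_t)

    def test_d0_equal_dg_averages_variances(self):
        rng = np.random.default_rng(1)
        norm = _unit_norm(rng.normal(size=(10, 8)))
        labels = _labels([1] * 4 + [2] * 4)
        dg = 8 - 2
        res = fit_moderated_de(norm, labels, (1, 2), d0=float(dg), s0_sq=0.5)
        v = 1 / 4 + 1 / 4
        s_mod = (0.5 + res.table["sigma2"]) / 2
        assert np.allclose(res.table["t_mod"], res.table["logFC"] / np.sqrt(s_mod * v))

    def test_tiny_d0_approaches_ordinary_t(self):
        rng = np.random.default_rng(2)
        norm = _unit_norm(rng.normal(size=(15, 10)))
        labels = _labels([1] * 5 + [2] * 5)
        res = fit_moderated_de(norm, labels, (1, 2), d0=1e-6, s0_sq=123.0)
        v = 1 / 5 + 1 / 5
        t_ordinary = res.table["logFC"] / np.sqrt(res.table["sigma2"] * v)
        assert np.allclose(res.table["t_mod"], t_ordinary, atol=1e-4)

    def test_contrast_flip_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(3)
        norm = _unit_norm(rng.normal(size=(12, 9)))
        labels = _labels([1] * 3 + [2] * 3 + [3] * 3)
        ab = fit_moderated_de(norm, labels, (1, 2), d0=5.0, s0_sq=1.0)
        ba = fit_moderated_de(norm, labels, (2, 1), d0=5.0, s0_sq=1.0)
        assert np.allclose(ab.table["logFC"], -ba.table["logFC"])
        assert np.allclose(ab.table["t_mod"], -ba.table["t_mod"])
        assert np.allclose(ab.table["p"], ba.table["p"])
        assert np.allclose(ab.table["q"], ba.table["q"])

    def test_small_cluster_rejected(self):
        norm = _unit_norm(np.zeros((3, 4)) + np.arange(4))
        labels = _labels([1, 1, 1, 2])
        with pytest.raises(SignatureError, match="fewer than 2"):
            fit_moderated_de(norm, labels, (1, 2))

    def test_matches_bioconductor_limma(self):
        # independent oracle: limma lmFit + eBayes on the same matrix
        rng = np.random.default_rng(5)
        g, n = 200, 12
        sig2 = 8.0 / rng.chisquare(8.0, g)
        x = rng.normal(0, np.sqrt(sig2)[:, None], (g, n)) + 5
        x[:20, 6:] += 1.5
        norm = _unit_norm(x)
        labels = _labels([1] * 6 + [2] * 6)
        res = fit_moderated_de(norm, labels, (2, 1))
        with tempfile.TemporaryDirectory() as td:
            norm.logexpr.to_csv(f"{td}/x.csv")
            script = f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{td}/x.csv", row.names=1))
            design <- model.matrix(~0 + factor(c(rep(1,6), rep(2,6))))
            colnames(design) <- c("c1","c2")
            fit <- lmFit(x, design)
            fit2 <- contrasts.fit(fit, makeContrasts(c2-c1, levels=design))
            fit2 <- eBayes(fit2)
            out <- data.frame(t=fit2$t[,1], p=fit2$p.value[,1])
            write.csv(out, "{td}/limma.csv")
            """
            proc = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True
            )
            assert proc.returncode == 0, proc.stderr
            lim = pd.read_csv(f"{td}/limma.csv", index_col=0)
        assert np.allclose(lim["t"].values, res.table["t_mod"].values, atol=1e-6)
        assert np.allclose(lim["p"].values, res.table["p"].values, atol=1e-6)


class TestPriorEstimation:
    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-8)

    def test_recovers_known_prior(self):
        rng = np.random.default_rng(7)
        d0, s0 = 6.0, 2.0
        df = 10.0
        sigma2 = (
            d0 * s0 / rng.chisquare(d0, 20000)
        ) * rng.chisquare(df, 20000) / df
        d0_hat, s0_hat = estimate_prior(sigma2, df)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0_hat == pytest.approx(s0, rel=0.05)

    def test_underdispersed_falls_back(self, caplog):
        sigma2 = np.full(100, 1.0) + np.random.default_rng(0).normal(0, 1e-4, 100)
        d0, s0 = estimate_prior(sigma2, 10.0)
        assert d0 == 10.0
        assert s0 == pytest.approx(1.0, rel=0.01)


class TestBH:
    def test_brute_force_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm)

    def test_out_of_range_rejected(self):
        with pytest.raises(SignatureError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    def test_dominates_p_and_sorted_nondecreasing(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)


class TestDeriveSignatures:
    def _three_cluster_de(self, seed=0, planted=True):
        rng = np.random.default_rng(seed)
        g, per = 60, 5
        x = rng.normal(0, 0.3, (g, 3 * per))
        if planted:
            x[0, :per] += 4.0     # over in cluster 1
            x[1, :per] -= 4.0     # under in cluster 1
            x[2, :per] += 4.0     # up vs cluster 2/3? also up everywhere
            x[2, per : 2 * per] += 4.0  # up in 1 and 2 -> mixed, excluded
        norm = _unit_norm(x)
        labels = _labels([1] * per + [2] * per + [3] * per)
        return norm, labels

    def test_rule_and_exclusions(self):
        norm, labels = self._three_cluster_de()
        de = all_pairwise_de(norm, labels)
        sig = derive_signatures(de)
        assert "g0" in sig.sets["C1_over"]
        assert "g1" in sig.sets["C1_under"]
        # g2 is up in both clusters 1 and 2: significant up vs 3 but not vs
        # each other -> in neither cluster's set
        assert "g2" not in sig.sets["C1_over"]
        assert "g2" not in sig.sets["C2_over"]

    def test_monotone_in_q_threshold(self):
        norm, labels = self._three_cluster_de(seed=1)
        de = all_pairwise_de(norm, labels)
        strict = derive_signatures(de, q_threshold=0.01)
        loose = derive_signatures(de, q_threshold=0.05)
        for name in strict.sets:
            assert strict.sets[name] <= loose.sets[name]

    def test_matches_naive_intersection_oracle(self):
        norm, labels = self._three_cluster_de(seed=2)
        de = all_pairwise_de(norm, labels)
        sig = derive_signatures(de, q_threshold=0.05)
        clusters = [1, 2, 3]
        for c in clusters:
            for direction, cmp in (("over", 1), ("under", -1)):
                members = set()
                for gene in norm.kept_genes:
                    ok = True
                    for j in clusters:
                        if j == c:
                            continue
                        pair = (c, j) if (c, j) in de else (j, c)
                        row = de[pair].table.loc[gene]
                        lfc = row["logFC"] if pair == (c, j) else -row["logFC"]
                        if not (row["q"] < 0.05 and cmp * lfc > 0):
                            ok = False
                            break
                    if ok:
                        members.add(gene)
                assert members == set(sig.sets[f"C{c}_{direction}"]), (c, direction)

    def test_missing_contrast_rejected(self):
        norm, labels = self._three_cluster_de()
        de = all_pairwise_de(norm, labels)
        del de[(1, 2)]
        with pytest.raises(SignatureError, match="missing"):
            derive_signatures(de)

    def test_null_cohort_false_entry_rate_bounded(self):
        # no planted effects: expected fraction of genes entering any
        # signature stays below the FDR threshold (2x slack), averaged
        # over seeds
        rates = []
        for seed in range(20):
            cfg = null_config(
                CohortConfig(
                    n_samples=30,
                    n_subtypes=3,
                    n_genes=200,
                    markers_per_subtype_per_direction=5,
                    hazards_per_month=(0.01, 0.02, 0.03),
                ),
                seed=seed,
            )
            cohort = gen_cohort(cfg)
            norm = normalize(expression_filter(cohort.counts))
            de = all_pairwise_de(norm, cohort.truth)
            sig = derive_signatures(de, q_threshold=0.05)
            entered = set().union(*sig.sets.values())
            rates.append(len(entered) / len(norm.kept_genes))
        assert np.mean(rates) <= 0.05 * 2
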