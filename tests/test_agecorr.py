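"""Age-association statistics vs closed-form / exhaustive oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from atacage import agecorr


AGES5 = np.array([20, 30, 40, 50, 60.0])


class TestAgeCorrelations:
    def test_perfect_monotone(self):
        m = pd.DataFrame([AGES5, -AGES5], index=["up", "down"])
        tab = agecorr.age_correlations(m, AGES5, q_threshold=0.05)
        assert tab.set_index("feature_id").loc["up", "spearman_r"] == 1.0
        assert tab.set_index("feature_id").loc["up", "class"] == "opening"
        assert tab.set_index("feature_id").loc["down", "spearman_r"] == -1.0
        assert tab.set_index("feature_id").loc["down", "class"] == "closing"

    def test_toy_matches_rank_formula(self):
        vals = np.array([3, 1, 4, 1, 5.0])
        m = pd.DataFrame([vals], index=["f"])
        tab = agecorr.age_correlations(m, AGES5)
        expected = stats.spearmanr(vals, AGES5)
        assert np.isclose(tab["spearman_r"].iloc[0], expected.statistic)

    def test_constant_feature_flagged_stable(self):
        m = pd.DataFrame([np.ones(5), AGES5], index=["const", "up"])
        tab = agecorr.age_correlations(m, AGES5).set_index("feature_id")
        assert tab.loc["const", "spearman_r"] == 0
        assert tab.loc["const", "p_value"] == 1
        assert tab.loc["const", "class"] == "stable"
        assert bool(tab.loc["const", "constant"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 30)))
        ages = rng.uniform(20, 74, 30)
        t1 = agecorr.age_correlations(m, ages)["spearman_r"]
        t2 = agecorr.age_correlations(np.exp(m * 2), ages ** 3)["spearman_r"]
        assert np.allclose(t1, t2)

    def test_bh_matches_brute_force_stepup(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(300, 20)))
        m.iloc[:30] += np.linspace(0, 3, 20)  # some real signal
        ages = np.linspace(20, 74, 20)
        tab = agecorr.age_correlations(m, ages, q_threshold=0.05)
        p = tab["p_value"].to_numpy()
        # brute-force BH step-up at level alpha
        alpha = 0.05
        order = np.argsort(p)
        ps = p[order]
        n = len(p)
        below = np.flatnonzero(ps <= alpha * (np.arange(n) + 1) / n)
        rejected = np.zeros(n, dtype=bool)
        if len(below):
            rejected[order[: below.max() + 1]] = True
        assert ((tab["q_value"] < alpha).to_numpy() == rejected).all()
        # q monotone in p, q >= p
        qs = tab["q_value"].to_numpy()[order]
        assert (np.diff(qs) >= -1e-12).all()
        assert (tab["q_value"] >= tab["p_value"] - 1e-12).all()


class TestAnnotationEnrichment:
    def ocrs(self, anns):
        return pd.DataFrame({"ocr_id": [f"o{i}" for i in range(len(anns))], "annotation": anns})

    def table(self, classes):
        return pd.DataFrame({"feature_id": [f"o{i}" for i in range(len(classes))], "class": classes})

    def test_no_association(self):
        anns = ["enhancer"] * 10 + ["unannotated"] * 10 + ["enhancer"] * 10 + ["unannotated"] * 10
        cls = ["opening"] * 20 + ["stable"] * 20
        res = agecorr.annotation_enrichment(self.table(cls), self.ocrs(anns), "opening")
        assert res["odds_ratio"] == 1.0
        assert res["p_value"] == 1.0

    def test_strong_association_matches_hypergeometric(self):
        anns = (["enhancer"] * 9 + ["unannotated"]) + (["enhancer"] + ["unannotated"] * 9)
        cls = ["opening"] * 10 + ["stable"] * 10
        res = agecorr.annotation_enrichment(self.table(cls), self.ocrs(anns), "opening")
        assert res["odds_ratio"] == 81.0
        # exhaustive two-sided Fisher p by hypergeometric enumeration
        M, nn, N = 20, 10, 10
        probs = [hypergeom.pmf(k, M, nn, N) for k in range(11)]
        p_obs = probs[9]
        expected_p = sum(pk for pk in probs if pk <= p_obs + 1e-12)
        assert np.isclose(res["p_value"], expected_p, rtol=1e-8)

    def test_degenerate_infinite_or(self):
        anns = ["enhancer"] * 5 + ["unannotated"] * 5
        cls = ["opening"] * 5 + ["stable"] * 5
        res = agecorr.annotation_enrichment(self.table(cls), self.ocrs(anns), "opening")
        assert np.isinf(res["odds_ratio"])

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="closing"):
            agecorr.annotation_enrichment(
                self.table(["opening", "stable"]), self.ocrs(["enhancer", "enhancer"]), "closing"
            )


class TestKsShift:
    def test_identical_samples_zero(self):
        x = np.arange(10.0)
        res = agecorr.ks_shift(x, x, "greater")
        assert res["D"] == 0.0

    def test_complete_separation(self):
        res = agecorr.ks_shift(np.array([1.0, 2.0]), np.array([3.0, 4.0]), "less")
        assert res["D"] == 1.0

    def test_matches_ecdf_enumeration_and_scipy(self):
        rng = np.random.default_rng(2)
        t = rng.normal(0.5, 1, 300)
        b = rng.normal(0, 1, 400)
        res = agecorr.ks_shift(t, b, "greater")
        # brute-force ECDF max over the pooled grid
        grid = np.concatenate([t, b])
        d_brute = max((np.mean(b <= x) - np.mean(t <= x)) for x in grid)
        assert np.isclose(res["D"], d_brute)
        # scipy one-sided statistic agrees (scipy's "less" alternative means
        # F_target lies below F_background, i.e. target values are greater)
        d_scipy = stats.ks_2samp(t, b, alternative="less").statistic
        assert np.isclose(res["D"], d_scipy)
        # asymptotic p formula
        n_eff = len(t) * len(b) / (len(t) + len(b))
        assert np.isclose(res["p_value"], np.exp(-2 * n_eff * res["D"] ** 2))

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            agecorr.ks_shift(np.array([1.0]), np.array([1.0, 2.0]), "less")


class TestLinkCpgs:
    OCRS = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 200],
                         "end": [100, 300], "ocr_id": ["o1", "o2"]})

    def cpgs(self, positions, chrom="chr1"):
        return pd.DataFrame({"cpg_id": [f"c{i}" for i in range(len(positions))],
                             "chrom": chrom, "pos": positions})

    def test_inside_assigned(self):
        out = agecorr.link_cpgs_to_ocrs(self.cpgs([50]), self.OCRS)
        assert out.iloc[0].tolist() == ["c0", "o1"]

    def test_end_coordinate_excluded(self):
        out = agecorr.link_cpgs_to_ocrs(self.cpgs([100]), self.OCRS)
        assert len(out) == 0

    def test_randomized_membership_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, 400, 50)
        out = agecorr.link_cpgs_to_ocrs(self.cpgs(pos), self.OCRS)
        expected = {}
        for i, p in enumerate(pos):
            for row in self.OCRS.itertuples():
                if row.start <= p < row.end:
                    expected[f"c{i}"] = row.ocr_id
        assert dict(zip(out["cpg_id"], out["ocr_id"])) == expected


class TestCorrelationOfCorrelations:
    def tables(self, ra, rb):
        ta = pd.DataFrame({"feature_id": [f"a{i}" for i in range(len(ra))], "spearman_r": ra})
        tb = pd.DataFrame({"feature_id": [f"b{i}" for i in range(len(rb))], "spearman_r": rb})
        links = pd.DataFrame({"feature_a": ta["feature_id"], "feature_b": tb["feature_id"]})
        return ta, tb, links

    def test_identity_and_negation(self):
        r = np.linspace(-0.5, 0.5, 20)
        ta, tb, links = self.tables(r, r)
        assert np.isclose(agecorr.correlation_of_correlations(ta, tb, links)["pearson_r"], 1.0)
        ta, tb, links = self.tables(r, -r)
        assert np.isclose(agecorr.correlation_of_correlations(ta, tb, links)["pearson_r"], -1.0)

    def test_too_few_pairs_errors(self):
        ta, tb, links = self.tables([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError, match=">= 3"):
            agecorr.correlation_of_correlations(ta, tb, links)


class TestSyntheticRecovery:
    """Generator-truth recovery on the shared small cohort (fixed seed)."""

    def test_strong_tier_sign_recovery(self, default_cohort):
        c = default_cohort
        tab = agecorr.age_correlations(c["log_normalized"], c["samples"]["age"])
        tr = c["truth"]["ocr"].merge(tab, left_on="ocr_id", right_on="feature_id")
        strong = tr[tr["gene_tier"] == "strong"]
        agree = (np.sign(strong["spearman_r"]) == np.sign(strong["true_r"])).mean()
        assert agree >= 0.95

    def test_cross_modality_structure(self, default_cohort):
        c = default_cohort
        ages = c["samples"]["age"]
        acc = agecorr.age_correlations(c["log_normalized"], ages)
        rna = agecorr.age_correlations(c["expression"], ages, modality="rna")
        meth = agecorr.age_correlations(c["methylation"], ages, modality="methylation")
        links = c["truth"]["ocr"].dropna(subset=["linked_gene"]).rename(
            columns={"ocr_id": "feature_a", "linked_gene": "feature_b"})[["feature_a", "feature_b"]]
        ann = c["ocrs"].set_index("ocr_id")["annotation"]
        prom = agecorr.correlation_of_correlations(acc, rna, links, "promoter", ann)
        enh = agecorr.correlation_of_correlations(acc, rna, links, "enhancer", ann)
        # planted coupling recovered within +/-0.1
        assert abs(prom["pearson_r"] - 0.32) < 0.1
        assert abs(enh["pearson_r"] - 0.25) < 0.1
        # promoter coupling exceeds enhancer coupling
        assert prom["pearson_r"] > enh["pearson_r"]
        # methylation-expression coupling is near zero
        hostg = c["truth"]["ocr"].set_index("ocr_id")["linked_gene"]
        cl = c["truth"]["cpg"][c["truth"]["cpg"]["host_ocr"] != ""].copy()
        cl["feature_b"] = hostg.reindex(cl["host_ocr"]).to_numpy()
        me_links = cl.dropna(subset=["feature_b"]).rename(
            columns={"cpg_id": "feature_a"})[["feature_a", "feature_b"]]
        me = agecorr.correlation_of_correlations(meth, rna, me_links)
        assert abs(me["pearson_r"]) < 0.1
        assert enh["pearson_r"] > abs(me["pearson_r"])
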