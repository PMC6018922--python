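"""PGLS under Brownian covariance: covariance construction, the GLS fit,
its reductions and oracles, and family-scan error control."""

import shutil
import subprocess
import textwrap

import dendropy
import numpy as np
import pytest
from scipy import stats

import dosagescan as ds
from dosagescan.phylo import UntestableFamilyError
from dosagescan.simulate import simulate_tree_and_traits


class TestBrownianCovariance:
    def test_star_tree_is_diagonal(self):
        cov = ds.brownian_covariance("(A:2,B:2,C:2,D:2);")
        assert np.allclose(cov.matrix, 2 * np.eye(4))

    def test_three_tip_path_arithmetic(self):
        cov = ds.brownian_covariance("((A:1,B:1):1,C:2);")
        idx = {t: i for i, t in enumerate(cov.tip_labels)}
        c = cov.matrix
        assert c[idx["A"], idx["A"]] == pytest.approx(2.0)
        assert c[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert c[idx["A"], idx["C"]] == pytest.approx(0.0)

    def test_matches_bruteforce_mrca_depths_on_random_tree(self):
        nwk, _, _, _ = simulate_tree_and_traits(10, seed=17)
        cov = ds.brownian_covariance(nwk)
        # oracle: explicit double loop over tip pairs via dendropy's MRCA
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.is_rooted = True
        tree.encode_bipartitions()
        taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
        n = len(cov.tip_labels)
        oracle = np.zeros((n, n))
        for i, la in enumerate(cov.tip_labels):
            for j, lb in enumerate(cov.tip_labels):
                if i == j:
                    oracle[i, j] = tree.find_node_with_taxon_label(
                        la).distance_from_root()
                else:
                    oracle[i, j] = tree.mrca(
                        taxa=[taxa[la], taxa[lb]]).distance_from_root()
        assert np.allclose(cov.matrix, oracle)

    def test_explicitly_unrooted_tree_rejected(self):
        with pytest.raises(ValueError, match="unrooted"):
            ds.brownian_covariance("[&U]((A:1,B:1):1,(C:1,D:1):1);")


class TestLogTransform:
    def test_offset_anchors_zero(self):
        out = ds.log_transform_abundance([0.0, 999.0, 10.0])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(3.0)
        assert out[2] == pytest.approx(np.log10(11.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ds.log_transform_abundance([-1.0])


FIVE_TIP_TREE = "((A:1,(B:0.5,C:0.5):0.5):1,(D:1.5,E:1.5):0.5);"
FIVE_TIP_X = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.0, "E": 4.0}
FIVE_TIP_Y = {"A": 0.30, "B": 0.65, "C": 1.02, "D": 0.70, "E": 1.35}


def five_tip_instance():
    cov = ds.brownian_covariance(FIVE_TIP_TREE)
    x = np.array([FIVE_TIP_X[t] for t in cov.tip_labels])
    y = np.array([FIVE_TIP_Y[t] for t in cov.tip_labels])
    return cov, x, y


class TestPGLSFit:
    def test_identity_covariance_reduces_to_ols(self, rng):
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        res = ds.pgls_fit(x, y, np.eye(12))
        ols = stats.linregress(x, y)
        assert res.slope == pytest.approx(ols.slope, abs=1e-12)
        assert res.intercept == pytest.approx(ols.intercept, abs=1e-12)
        assert res.slope_se == pytest.approx(ols.stderr, abs=1e-12)
        assert res.p_value == pytest.approx(ols.pvalue, abs=1e-12)

    def test_perfect_linear_relation(self):
        cov = ds.brownian_covariance(FIVE_TIP_TREE)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = ds.pgls_fit(x, 2 * x + 1, cov)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-12

    def test_matches_hand_matrix_algebra_on_five_tips(self):
        cov, x, y = five_tip_instance()
        # oracle: hand-coded MRCA-depth covariance in the fitted tip order,
        # then the GLS normal equations evaluated with explicit inverses
        depth = {("A", "A"): 2.0, ("B", "B"): 2.0, ("C", "C"): 2.0,
                 ("D", "D"): 2.0, ("E", "E"): 2.0,
                 ("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 1.5,
                 ("D", "E"): 0.5}
        n = 5
        c_hand = np.zeros((n, n))
        for i, a in enumerate(cov.tip_labels):
            for j, b in enumerate(cov.tip_labels):
                key = (a, b) if (a, b) in depth else (b, a)
                c_hand[i, j] = depth.get(key, 0.0)
        assert np.allclose(cov.matrix, c_hand)

        design = np.column_stack([np.ones(n), x])
        ci = np.linalg.inv(c_hand)
        beta = np.linalg.inv(design.T @ ci @ design) @ design.T @ ci @ y
        resid = y - design @ beta
        sigma2 = resid @ ci @ resid / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(design.T @ ci @ design)[1, 1])
        t_stat = beta[1] / se
        p = 2 * stats.t.sf(abs(t_stat), n - 2)

        res = ds.pgls_fit(x, y, cov)
        assert res.slope == pytest.approx(beta[1], rel=1e-10)
        assert res.intercept == pytest.approx(beta[0], rel=1e-10)
        assert res.slope_se == pytest.approx(se, rel=1e-10)
        assert res.t_stat == pytest.approx(t_stat, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_slope_invariant_to_covariance_scale(self):
        cov, x, y = five_tip_instance()
        r1 = ds.pgls_fit(x, y, cov.matrix)
        r2 = ds.pgls_fit(x, y, 37.5 * cov.matrix)
        assert r1.slope == pytest.approx(r2.slope, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-10)

    def test_constant_predictor_untestable(self):
        cov, _, y = five_tip_instance()
        with pytest.raises(UntestableFamilyError):
            ds.pgls_fit(np.ones(5), y, cov)

    def test_slope_recovery_over_brownian_replicates(self):
        beta = 0.3
        slopes = []
        for s in range(200):
            nwk, _, k, y = simulate_tree_and_traits(
                30, beta=beta, sigma2=0.1, seed=1000 + s)
            if np.ptp(k) == 0:
                continue
            slopes.append(ds.pgls_fit(k, y, ds.brownian_covariance(nwk)).slope)
        slopes = np.array(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - beta) <= 3 * sem


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_agrees_with_independent_gls_implementation(tmp_path):
    """Cross-check slope/SE/p against nlme::gls with an ape corBrownian
    structure — a fully independent GLS implementation. The instance is
    ultrametric because nlme correlation structures assume equal tip
    variances."""
    cov, x, y = five_tip_instance()
    script = textwrap.dedent(f"""
        suppressMessages({{library(ape); library(nlme)}})
        tree <- read.tree(text="{FIVE_TIP_TREE}")
        dat <- data.frame(tip=c({','.join(repr(t) for t in cov.tip_labels)}),
                          x=c({','.join(str(v) for v in x)}),
                          y=c({','.join(str(v) for v in y)}))
        fit <- gls(y ~ x, data=dat,
                   correlation=corBrownian(1, phy=tree, form=~tip))
        tt <- summary(fit)$tTable
        cat(sprintf("%.12g %.12g %.12g\\n", tt["x","Value"],
                    tt["x","Std.Error"], tt["x","p-value"]))
    """)
    rfile = tmp_path / "pgls_check.R"
    rfile.write_text(script)
    out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                         text=True, check=True)
    slope_r, se_r, p_r = map(float, out.stdout.split())
    res = ds.pgls_fit(x, y, cov)
    assert res.slope == pytest.approx(slope_r, rel=1e-6)
    assert res.slope_se == pytest.approx(se_r, rel=1e-6)
    assert res.p_value == pytest.approx(p_r, rel=1e-4)


class TestFamilyScan:
    @staticmethod
    def scan_once(seed, n_families=10, beta_by_family=None, n_tips=20):
        families = {}
        for f in range(n_families):
            beta = (beta_by_family or {}).get(f, 0.0)
            nwk, _, k, y = simulate_tree_and_traits(
                n_tips, beta=beta, sigma2=0.2,
                seed=seed * n_families + f)
            families[f"fam{f}"] = (nwk, k, y)
        return ds.run_family_scan(families)

    def test_single_family_bonferroni_is_identity(self):
        nwk, _, k, y = simulate_tree_and_traits(15, beta=0.5, sigma2=0.05,
                                                seed=2)
        results, _, _ = ds.run_family_scan({"only": (nwk, k, y)})
        assert results[0].p_bonferroni == pytest.approx(results[0].p_value)

    def test_familywise_error_controlled_under_the_null(self):
        alpha = 0.05
        false_positive_scans = 0
        n_scans = 300
        for s in range(n_scans):
            results, _, _ = self.scan_once(s)
            if any(r.p_bonferroni <= alpha for r in results):
                false_positive_scans += 1
        rate = false_positive_scans / n_scans
        # one-sided binomial slack on top of the nominal level
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_scans)

    def test_true_effect_family_attains_smallest_p(self):
        hits = 0
        n_reps = 200
        for s in range(n_reps):
            results, _, _ = self.scan_once(
                10_000 + s, beta_by_family={0: 0.5})
            best = min(results, key=lambda r: r.p_value)
            hits += best.family_id == "fam0"
        assert hits / n_reps >= 0.90

    def test_untestable_families_reported_with_reason(self):
        nwk, _, k, y = simulate_tree_and_traits(10, beta=0.2, sigma2=0.1,
                                                seed=3)
        families = {"ok": (nwk, k, y),
                    "flat": (nwk, np.ones_like(k), y)}
        results, untestable, _ = ds.run_family_scan(families)
        assert [r.family_id for r in results] == ["ok"]
        assert "flat" in untestable
        # Bonferroni factor counts testable families only
        assert results[0].p_bonferroni == pytest.approx(results[0].p_value)

    def test_multi_tree_mode_reports_per_tree_pvalues(self):
        nwk1, _, k, y = simulate_tree_and_traits(12, beta=0.4, sigma2=0.1,
                                                 seed=4)
        nwk2, _, _, _ = simulate_tree_and_traits(12, seed=5)
        families = {"fam": (nwk1, k, y)}
        _, _, per_tree = ds.run_family_scan(
            families, extra_trees={"fam": [nwk1, nwk1]})
        assert len(per_tree["fam"]) == 2
        assert per_tree["fam"][0] == pytest.approx(per_tree["fam"][1])
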