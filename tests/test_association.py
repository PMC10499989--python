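import numpy as np
import pandas as pd
import pytest

from svcis.association import (ScanFilterPolicy, concordance,
                               concordance_percentage,
                               count_impacted_tumors, fit_association,
                               mask_mrna_to_protein, run_scan)
from svcis.breakpoints import RegionSpec, BreakpointMatrix
from svcis.io import Matrix
from svcis.stats import bh_fdr


def simple_groups(n, k=2):
    return np.array([f"ct{i % k}" for i in range(n)])


class TestFitAssociation:
    def test_exact_fit_recovers_coefficient(self):
        n = 50
        bp = np.zeros(n)
        bp[:5] = 1
        res = fit_association(bp.copy(), bp, np.zeros(n), ["ct0"] * n)
        np.testing.assert_allclose(res.coefficient, 1.0, atol=1e-10)
        assert res.p_two_sided < 1e-12
        assert res.direction == "positive"

    def test_matches_normal_equations_oracle(self, rng):
        """OLS path agrees with an explicit normal-equations solve."""
        for _ in range(50):
            n = int(rng.integers(25, 60))
            bp = (rng.random(n) < 0.2).astype(float)
            if bp.sum() == 0:
                bp[0] = 1
            cna = rng.integers(-2, 3, n).astype(float)
            grp = simple_groups(n, 3)
            y = 0.5 * bp + 0.2 * cna + rng.normal(0, 1, n)
            res = fit_association(y, bp, cna, grp)
            X = np.column_stack([np.ones(n), bp, cna,
                                 (grp == "ct1").astype(float),
                                 (grp == "ct2").astype(float)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.coefficient, beta[1], atol=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 200
        bp = (rng.random(n) < 0.1).astype(float)
        cna = rng.integers(-2, 3, n).astype(float)
        grp = simple_groups(n, 4)
        y = 0.8 * bp + rng.normal(0, 1, n)
        res = fit_association(y, bp, cna, grp)
        X = pd.get_dummies(pd.DataFrame({"bp": bp, "cna": cna,
                                         "grp": grp}),
                           columns=["grp"], drop_first=True, dtype=float)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(res.coefficient, fit.params["bp"],
                                   atol=1e-8)
        np.testing.assert_allclose(res.p_two_sided, fit.pvalues["bp"],
                                   atol=1e-8)

    def test_null_type_one_error_in_band(self):
        rng = np.random.default_rng(7)
        n = 300
        bp = (rng.random(n) < 0.1).astype(float)
        grp = simple_groups(n)
        hits = 0
        n_feat = 2000
        for _ in range(n_feat):
            y = rng.normal(0, 1, n)
            res = fit_association(y, bp, None, grp)
            hits += res.p_two_sided < 0.05
        assert 0.04 <= hits / n_feat <= 0.06

    def test_shift_and_scale_equivariance(self, rng):
        n = 120
        bp = (rng.random(n) < 0.15).astype(float)
        y = rng.normal(0, 1, n)
        grp = simple_groups(n)
        base = fit_association(y, bp, None, grp)
        shifted = fit_association(y + 5.0, bp, None, grp)
        scaled = fit_association(3.0 * y, bp, None, grp)
        np.testing.assert_allclose(shifted.coefficient, base.coefficient,
                                   atol=1e-10)
        np.testing.assert_allclose(scaled.coefficient,
                                   3.0 * base.coefficient, atol=1e-10)
        np.testing.assert_allclose(scaled.p_two_sided, base.p_two_sided,
                                   atol=1e-12)

    def test_constant_bp_untestable(self):
        res = fit_association(np.arange(10.0), np.zeros(10), None,
                              ["a"] * 10)
        assert res.untestable and np.isnan(res.p_two_sided)

    def test_reference_level_choice_does_not_change_p(self, rng):
        n = 90
        bp = (rng.random(n) < 0.2).astype(float)
        y = rng.normal(0, 1, n) + 0.4 * bp
        grp1 = simple_groups(n, 3)
        relabel = {"ct0": "zzz", "ct1": "aaa", "ct2": "mmm"}
        grp2 = np.array([relabel[g] for g in grp1])
        r1 = fit_association(y, bp, None, grp1)
        r2 = fit_association(y, bp, None, grp2)
        np.testing.assert_allclose(r1.p_two_sided, r2.p_two_sided,
                                   atol=1e-10)

    def test_missing_y_drops_empty_group_level(self):
        y = np.array([1.0, 2.0, np.nan, np.nan, 0.5, 1.5, 0.7, 1.1])
        bp = np.array([1, 0, 1, 0, 0, 1, 0, 0], dtype=float)
        grp = np.array(["a", "a", "b", "b", "a", "a", "a", "a"])
        res = fit_association(y, bp, None, grp)
        assert res.n_used == 6 and not res.untestable


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_brute_force_definition(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        m = len(p)
        brute = np.empty(m)
        for i in range(m):
            brute[i] = min(min(p[j] * m / (np.sum(p <= p[j]))
                               for j in range(m) if p[j] >= p[i]), 1.0)
        np.testing.assert_allclose(q, brute, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm, atol=1e-12)


class TestConcordance:
    def table(self, ids, ps, direction="positive"):
        return pd.DataFrame({"feature_id": ids, "p_two_sided": ps,
                             "direction": direction})

    def test_hypergeometric_oracle_case(self):
        bg = {f"g{i}" for i in range(100)}
        a = self.table([f"g{i}" for i in range(20)], [0.001] * 20)
        b = self.table([f"g{i}" for i in range(14, 44)], [0.001] * 30)
        k, expected, p, _, _ = concordance(a, b, 0.05, 0.05, bg)
        assert k == 6
        np.testing.assert_allclose(expected, 6.0)
        np.testing.assert_allclose(p, 0.5990, atol=1e-3)

    def test_disjoint_and_identical(self):
        bg = {f"g{i}" for i in range(50)}
        a = self.table(["g1", "g2"], [0.01, 0.01])
        b = self.table(["g10", "g11"], [0.01, 0.01])
        k, _, p, _, _ = concordance(a, b, 0.05, 0.05, bg)
        assert k == 0 and p > 0.9
        k2, _, p2, _, _ = concordance(a, a, 0.05, 0.05, bg)
        assert k2 == 2 and p2 < 0.01

    def test_direction_match_required(self):
        bg = {"g1", "g2"}
        a = self.table(["g1"], [0.001], "positive")
        b = self.table(["g1"], [0.001], "negative")
        k, _, _, _, _ = concordance(a, b, 0.05, 0.05, bg)
        assert k == 0

    def test_published_concordance_percentages(self):
        # printed counts: 170 of 657 mRNA-significant genes confirmed by
        # protein (26%); filtered mRNA dataset: 180 of 574 (31%)
        assert concordance_percentage(170, 657) == 26
        assert concordance_percentage(180, 574) == 31
        assert concordance_percentage(140, 245) == 57


class TestMaskMrna:
    def make(self, arr, genes, samples=("S1", "S2")):
        return Matrix(pd.DataFrame(np.asarray(arr, dtype=float),
                                   index=list(genes),
                                   columns=list(samples)))

    def test_identity_when_protein_complete(self):
        mrna = self.make([[1, 2], [3, 4]], "ab")
        prot = self.make([[5, 6], [7, 8]], "ab")
        out = mask_mrna_to_protein(mrna, prot)
        pd.testing.assert_frame_equal(out.values, mrna.values)

    def test_protein_missing_gene_absent(self):
        mrna = self.make([[1, 2], [3, 4]], "ab")
        prot = self.make([[5, 6]], "a")
        out = mask_mrna_to_protein(mrna, prot)
        assert list(out.values.index) == ["a"]

    def test_n_used_monotone(self):
        mrna = self.make([[1, 2], [3, 4]], "ab")
        prot = self.make([[5, np.nan], [np.nan, np.nan]], "ab")
        out = mask_mrna_to_protein(mrna, prot)
        assert out.mask.sum(axis=1).le(mrna.mask.sum(axis=1)).all()
        assert np.isnan(out.values.at["a", "S2"])


class TestCountImpacted:
    def test_rules(self):
        expr = pd.Series([1.0, 0.2, 0.9, -0.8], index=list("abcd"))
        bp = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        cna = pd.Series([0, 0, 2, 0], index=list("abcd"))
        # c is amplified: excluded from the positive tally
        assert count_impacted_tumors(expr, bp, cna, "positive") == 1
        assert count_impacted_tumors(expr, bp, cna, "negative") == 1
        assert count_impacted_tumors(expr, bp * 0, cna, "positive") == 0
        with pytest.raises(ValueError):
            count_impacted_tumors(expr, bp, cna, "sideways")


class TestRunScan:
    def make_inputs(self, rng, n_feat=30, n=60):
        samples = [f"S{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(n_feat)]
        expr = Matrix(pd.DataFrame(rng.normal(0, 1, (n_feat, n)),
                                   index=genes, columns=samples))
        bp = pd.DataFrame((rng.random((n_feat, n)) < 0.1).astype(float),
                          index=genes, columns=samples)
        mat = BreakpointMatrix(bp, "binary", RegionSpec("gene_body", 0),
                               pd.DataFrame(columns=["gene_id", "sample_id",
                                                     "sv_id", "distance"]))
        groups = pd.Series("ct0", index=samples)
        return expr, mat, groups

    def test_min_obs_filter_excludes_sparse_features(self, rng):
        expr, mat, groups = self.make_inputs(rng)
        expr.values.iloc[0, 10:] = np.nan
        table = run_scan(expr, mat, None, groups,
                         ScanFilterPolicy(min_obs=50, min_bp_tumors=1))
        assert "g0" not in set(table["feature_id"])

    def test_fdr_computed_within_filter_passers(self, rng):
        expr, mat, groups = self.make_inputs(rng)
        policy = ScanFilterPolicy(min_obs=10, min_bp_tumors=3)
        table = run_scan(expr, mat, None, groups, policy)
        eligible = table["min_bp_pass"] & ~table["untestable"]
        assert table.loc[~eligible, "fdr_bh"].isna().all()
        sub = table.loc[eligible]
        np.testing.assert_allclose(
            sub["fdr_bh"].to_numpy(),
            bh_fdr(sub["p_two_sided"].to_numpy()), atol=1e-12)
        assert (sub["fdr_bh"] >= sub["p_two_sided"] - 1e-12).all()

    def test_per_type_mode_equals_stratum_fit(self, rng):
        """Restricting the scan to one cancer type with the covariate
        dropped equals fitting within that stratum alone."""
        from svcis.association import fit_association
        n = 80
        samples = [f"S{i}" for i in range(n)]
        grp = pd.Series(["ct0"] * 40 + ["ct1"] * 40, index=samples)
        rng2 = np.random.default_rng(3)
        y = rng2.normal(0, 1, n)
        bp = (rng2.random(n) < 0.2).astype(float)
        sub = grp == "ct0"
        r_strat = fit_association(y[sub.to_numpy()], bp[sub.to_numpy()],
                                  None, grp[sub].to_numpy())
        r_direct = fit_association(y[:40], bp[:40], None, ["ct0"] * 40)
        np.testing.assert_allclose(r_strat.coefficient,
                                   r_direct.coefficient, atol=1e-12)
        np.testing.assert_allclose(r_strat.p_two_sided,
                                   r_direct.p_two_sided, atol=1e-12)
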