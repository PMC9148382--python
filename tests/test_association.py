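"""Statistical core: PCs, logistic null, SKAT-O, Fisher, Bonferroni, scan."""

import logging
import math

import numpy as np
import pytest
from scipy import stats

from twinrare.association import (
    DEFAULT_RHO_GRID,
    PhenotypeContrast,
    bonferroni,
    compute_pcs,
    fisher_exact_2x2,
    fit_null_logistic,
    odds_ratio_ci,
    quadform_pvalue,
    run_scan,
    skat_o,
    standard_contrasts,
    write_results_tsv,
)
from twinrare.region_mapper import GeneModel, Region
from twinrare.twin_genomics import SampleRecord

from conftest import build_matrix, variant


def independent_burden_pvalue(G, null, weights):
    """Score test of the weighted burden as a single added covariate.

    Implemented directly from the logistic score-test formulas as an oracle
    for the rho = 1 branch of SKAT-O.
    """
    b = G @ weights
    mu = null.fitted_probabilities
    w = mu * (1 - mu)
    X = null.design
    u = float(b @ (null.residuals))
    bw = b * w
    xtwx = X.T @ (X * w[:, None])
    v = float(b @ bw - bw @ X @ np.linalg.solve(xtwx, X.T @ bw))
    return float(stats.chi2.sf(u * u / v, df=1))


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _sample(sid, dx, severity="none", symptoms=None, onset=None):
    if dx == 1 and severity == "none":
        severity = "mild"
    return SampleRecord(sid, None, "SINGLETON", "EUR", dx=dx, severity=severity,
                        symptom_count=symptoms, onset_age=onset)


class TestStandardContrasts:
    def grid(self):
        return [
            _sample("sev", 1, "severe", symptoms=9, onset=25),
            _sample("mild", 1, "mild", symptoms=5, onset=45),
            _sample("none", 0, symptoms=0),
            _sample("late", 1, "moderate", symptoms=8, onset=40),
            SampleRecord("ber", None, "SINGLETON", "EUR", dx="bereavement"),
            SampleRecord("mis", None, "SINGLETON", "EUR", dx="missing"),
        ]

    def test_four_families(self):
        names = [c.name for c in standard_contrasts()]
        assert names == ["severity", "lifetime_dx", "early_onset", "symptom_count"]

    def test_rules_disjoint_and_bereavement_excluded(self):
        for c in standard_contrasts():
            for s in self.grid():
                assert not (c.case_rule(s) and c.control_rule(s))
                if s.dx in ("bereavement", "missing"):
                    assert not c.case_rule(s) and not c.control_rule(s)

    def test_severity_controls_include_not_severe(self):
        sev = standard_contrasts()[0]
        by_id = {s.sample_id: s for s in self.grid()}
        assert sev.case_rule(by_id["sev"])
        assert sev.control_rule(by_id["mild"])
        assert sev.control_rule(by_id["none"])

    def test_early_onset_split(self):
        eo = standard_contrasts()[2]
        by_id = {s.sample_id: s for s in self.grid()}
        assert eo.case_rule(by_id["sev"])  # onset 25
        assert eo.control_rule(by_id["late"])  # onset 40
        assert eo.control_rule(by_id["none"])

    def test_symptom_count_dichotomy(self):
        sc = standard_contrasts()[3]
        by_id = {s.sample_id: s for s in self.grid()}
        assert sc.case_rule(by_id["sev"])  # 9 symptoms
        assert sc.control_rule(by_id["late"])  # 8 symptoms
        missing = _sample("m2", 1, "mild", symptoms=None)
        assert not sc.case_rule(missing) and not sc.control_rule(missing)


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

class TestComputePcs:
    def _two_pop_matrix(self, n=400, m=60, fst_shift=0.3, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], n // 2)
        p0 = rng.uniform(0.2, 0.5, m)
        p1 = np.clip(p0 + rng.choice([-1, 1], m) * fst_shift, 0.05, 0.95)
        p = np.where(labels[:, None] == 0, p0[None, :], p1[None, :])
        return build_matrix(rng.binomial(2, p)), labels

    def test_orthonormal_columns(self):
        m, _ = self._two_pop_matrix()
        pcs = compute_pcs(m, k=4)
        assert np.allclose(pcs.T @ pcs, np.eye(4), atol=1e-8)

    def test_pc1_separates_subpopulations(self):
        m, labels = self._two_pop_matrix(n=1000, seed=1)
        pc1 = compute_pcs(m, k=1)[:, 0]
        thr = np.median(pc1)
        pred = (pc1 > thr).astype(int)
        acc = max((pred == labels).mean(), (pred != labels).mean())
        assert acc >= 0.99

    def test_duplicated_samples_share_coordinates(self):
        m, _ = self._two_pop_matrix(seed=2)
        dup = m.subset_samples(list(range(m.n_samples)) + [0])
        pcs = compute_pcs(dup, k=3)
        assert np.allclose(pcs[0], pcs[-1], atol=1e-10)

    def test_k_beyond_available_raises(self):
        m = build_matrix(np.tile([[0], [2]], (5, 1)))
        with pytest.raises(ValueError):
            compute_pcs(m, k=4)

    def test_rare_variants_ignored(self):
        rng = np.random.default_rng(3)
        common = rng.binomial(2, 0.4, (200, 6))
        rare = np.zeros((200, 4), dtype=int)
        rare[:2] = 1
        a = compute_pcs(build_matrix(np.column_stack([common, rare])), k=3)
        b = compute_pcs(build_matrix(common), k=3)
        assert np.allclose(a, b, atol=1e-10)


# ---------------------------------------------------------------------------
# Logistic null
# ---------------------------------------------------------------------------

class TestFitNullLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        null = fit_null_logistic(y, np.ones((10, 1)))
        assert np.allclose(null.fitted_probabilities, 0.2, atol=1e-8)
        assert abs(null.residuals.sum()) < 1e-8
        assert null.converged and not null.ridged

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(7)
        n = 5000
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
        beta_true = np.array([-1.0, 0.8, -0.5])
        y = rng.binomial(1, 1 / (1 + np.exp(-X @ beta_true)))
        null = fit_null_logistic(y, X)
        w = null.fitted_probabilities * (1 - null.fitted_probabilities)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(null.coefficients - beta_true) < 3 * se)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            fit_null_logistic(np.ones(5), np.ones((5, 1)))

    def test_separation_falls_back_to_ridge(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        null = fit_null_logistic(y, np.column_stack([np.ones(6), x]))
        assert null.ridged
        assert np.all((null.fitted_probabilities > 0) & (null.fitted_probabilities < 1))


# ---------------------------------------------------------------------------
# Quadratic-form tail probabilities
# ---------------------------------------------------------------------------

class TestQuadformPvalue:
    def test_single_eigenvalue_chi2_tail(self):
        assert quadform_pvalue([1.0], 3.841458820694124) == pytest.approx(0.05, abs=1e-9)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.5])
    def test_equal_eigenvalue_scaling_identity(self, c):
        q = 5.3
        assert quadform_pvalue([c, c], q) == pytest.approx(
            stats.chi2.sf(q / c, df=2), abs=1e-12
        )

    def test_zero_statistic_gives_one(self):
        assert quadform_pvalue([1.0, 2.0], 0.0) == 1.0

    def test_monotone_decreasing_in_q(self):
        lam = [2.3, 1.1, 0.4]
        qs = np.linspace(0.1, 30, 40)
        ps = [quadform_pvalue(lam, q) for q in qs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_eigenvalues_raise(self):
        with pytest.raises(ValueError):
            quadform_pvalue([], 1.0)

    def test_negative_statistic_raises(self):
        with pytest.raises(ValueError):
            quadform_pvalue([1.0], -1.0)

    def test_extreme_tail_stays_in_unit_interval(self):
        p = quadform_pvalue([1e-3, 4e-4], 200.0)
        assert 0 < p < 1e-20


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------

def _null_and_genotypes(n=600, m=8, seed=0, with_covariate=True):
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.005, 0.04, m)
    G = rng.binomial(2, maf, (n, m)).astype(float)
    if with_covariate:
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    else:
        X = np.ones((n, 1))
    y = rng.binomial(1, 0.25, n)
    return G, fit_null_logistic(y, X)


class TestSkatO:
    def test_rho_one_matches_independent_burden_test(self):
        G, null = _null_and_genotypes(seed=1)
        maf = G.mean(axis=0) / 2
        w = stats.beta.pdf(np.minimum(maf, 1 - maf), 1, 25)
        res = skat_o(G, null, weights=w, rho_grid=[1.0])
        oracle = independent_burden_pvalue(G, null, w)
        assert res.p_value == pytest.approx(oracle, abs=1e-8)

    def test_variant_order_invariance(self):
        G, null = _null_and_genotypes(seed=2)
        perm = np.random.default_rng(0).permutation(G.shape[1])
        p1 = skat_o(G, null).p_value
        p2 = skat_o(G[:, perm], null).p_value
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_joint_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n = 500
        G = rng.binomial(2, 0.02, (n, 6)).astype(float)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.binomial(1, 0.3, n)
        perm = rng.permutation(n)
        p1 = skat_o(G, fit_null_logistic(y, X)).p_value
        p2 = skat_o(G[perm], fit_null_logistic(y[perm], X[perm])).p_value
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_omnibus_p_at_most_bonferroni_over_grid(self):
        G, null = _null_and_genotypes(seed=4)
        res = skat_o(G, null)
        assert res.p_value <= min(res.p_per_rho) * len(DEFAULT_RHO_GRID) + 1e-12
        assert res.p_value >= min(res.p_per_rho) * 0.5  # sane calibration scale

    def test_single_variant_block_equals_its_burden_test(self):
        G, null = _null_and_genotypes(m=1, seed=5)
        res = skat_o(G, null)
        oracle = independent_burden_pvalue(G, null, np.ones(1))
        # weights cancel for a single variant
        assert res.p_value == pytest.approx(oracle, abs=1e-8)

    def test_missing_dosages_mean_imputed(self):
        G, null = _null_and_genotypes(seed=6)
        G2 = G.copy()
        G2[0, 0] = -1
        p = skat_o(G2, null).p_value
        assert 0 < p <= 1

    def test_zero_variance_block_raises(self):
        G, null = _null_and_genotypes(seed=7)
        with pytest.raises(ValueError, match="untestable"):
            skat_o(np.zeros_like(G), null)

    def test_sample_count_mismatch_raises(self):
        G, null = _null_and_genotypes(seed=8)
        with pytest.raises(ValueError, match="sample"):
            skat_o(G[:-1], null)

    def test_weight_length_checked(self):
        G, null = _null_and_genotypes(seed=9)
        with pytest.raises(ValueError, match="weight"):
            skat_o(G, null, weights=np.ones(3))

    def test_rho_outside_unit_interval_rejected(self):
        G, null = _null_and_genotypes(seed=10)
        with pytest.raises(ValueError, match="rho"):
            skat_o(G, null, rho_grid=[0.0, 1.5])


# ---------------------------------------------------------------------------
# Fisher's exact test and odds ratios
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_no_signal_tables(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == 1.0
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_matches_scipy_reference(self):
        table = [[7, 87], [19, 1995]]
        assert fisher_exact_2x2(table) == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-9
        )

    def test_small_table_enumeration(self):
        # [[2,1],[0,3]]: support {0,1,2}; direct hypergeometric enumeration
        pmf = [stats.hypergeom.pmf(k, 6, 3, 2) for k in range(3)]
        expected = sum(v for v in pmf if v <= pmf[2] * (1 + 1e-11))
        assert fisher_exact_2x2([[2, 0], [1, 3]]) == pytest.approx(expected, abs=1e-12)

    def test_zero_row_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_non_integer_counts_raise(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    def test_integral_floats_accepted(self):
        assert fisher_exact_2x2([[7.0, 87.0], [19.0, 1995.0]]) == pytest.approx(
            fisher_exact_2x2([[7, 87], [19, 1995]])
        )


class TestOddsRatioCI:
    def test_reference_gene_burden_exact_values(self):
        res = odds_ratio_ci([[3, 91], [1, 2013]])
        assert round(res.odds_ratio, 4) == 66.3626
        assert res.ci_low == pytest.approx(6.8359, rel=1e-3)
        assert res.ci_high == pytest.approx(644.2420, rel=1e-3)
        assert not res.corrected

    def test_reference_variant_table_value(self):
        res = odds_ratio_ci([[7, 87], [19, 1995]])
        assert round(res.odds_ratio, 2) == 8.45

    def test_unit_table_symmetric_ci(self):
        res = odds_ratio_ci([[1, 1], [1, 1]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = odds_ratio_ci([[0, 10], [5, 5]])
        assert res.corrected
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            odds_ratio_ci([[-1, 1], [1, 1]])


class TestBonferroni:
    def test_reference_arithmetic(self):
        assert bonferroni(0.000123, 226) == pytest.approx(0.027798)
        assert round(bonferroni(0.000123, 226), 3) == 0.028

    def test_identity_and_cap(self):
        assert bonferroni(0.3, 1) == 0.3
        assert bonferroni(0.5, 3) == 1.0

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 5)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------

class TestRunScan:
    def _scenario(self, seed=0):
        """60 cases / 140 controls; one region; two genes; 5 region variants."""
        rng = np.random.default_rng(seed)
        n = 200
        y = np.array([1] * 60 + [0] * 140)
        cols, vs = [], []

        def add(pos, af_case, af_ctrl, func="nonsynonymous", gene=None, vid=None):
            col = np.concatenate([
                rng.binomial(2, af_case, 60), rng.binomial(2, af_ctrl, 140)
            ])
            cols.append(col)
            vs.append(variant(pos=pos, func_class=func, gene=gene, vid=vid))

        add(100, 0.06, 0.005, gene="G1", vid="sig")      # enriched rare variant
        add(200, 0.01, 0.01, func="synonymous", gene="G1", vid="silent")
        add(300, 0.0, 0.0, gene="G2", vid="mac2")        # exactly 2 alt alleles
        cols[-1][:2] = 1
        add(400, 0.3, 0.3, gene="G2", vid="common")      # fails MAF < 0.05
        add(500, 0.01, 0.01, gene="G2", vid="quiet")
        for j in range(6):                               # common PCA variants
            add(3000 + j, 0.4, 0.4, func="intronic", vid=f"pc{j}")
        matrix = build_matrix(np.stack(cols, axis=1),
                              variant_ids=[v.variant_id for v in vs])
        samples = [
            _sample(f"S{i:03d}", int(y[i]), "mild" if y[i] else "none")
            for i in range(n)
        ]
        regions = [Region("1", 1, 1000, "sig", 100)]
        genes = [GeneModel("1", 0, 350, "G1"), GeneModel("1", 350, 1000, "G2")]
        contrasts = [c for c in standard_contrasts() if c.name == "lifetime_dx"]
        return matrix, vs, samples, regions, genes, contrasts

    def test_variant_units_apply_inclusion_rules(self):
        matrix, vs, samples, regions, genes, contrasts = self._scenario()
        res = run_scan(matrix, vs, samples, regions, genes, contrasts,
                       unit_kind="variant")
        ids = {r.unit_id for r in res}
        assert "sig" in ids and "quiet" in ids
        assert "mac2" not in ids      # MAC 2 < 3
        assert "common" not in ids    # MAF 0.3
        assert "silent" not in ids    # synonymous
        assert "pc0" not in ids       # outside the region

    def test_variant_table_margins_match_counts(self):
        matrix, vs, samples, regions, genes, contrasts = self._scenario()
        res = run_scan(matrix, vs, samples, regions, genes, contrasts,
                       unit_kind="variant")
        for r in res:
            (a, b), (c, d) = r.table
            assert a + b <= 2 * r.case_n
            assert c + d <= 2 * r.control_n
            assert r.p_adjusted >= r.p_raw
            assert r.n_tests == len(res)

    def test_gene_units_require_qualifying_variants(self):
        matrix, vs, samples, regions, genes, contrasts = self._scenario()
        res = run_scan(matrix, vs, samples, regions, genes, contrasts,
                       unit_kind="gene")
        by_id = {r.unit_id: r for r in res}
        assert set(by_id) == {"G1", "G2"}
        assert by_id["G1"].n_variants == 1  # only "sig" qualifies
        assert by_id["G2"].n_variants == 1  # only "quiet" qualifies
        assert by_id["G1"].p_raw < by_id["G2"].p_raw

    def test_results_sorted_by_raw_p(self):
        matrix, vs, samples, regions, genes, contrasts = self._scenario()
        res = run_scan(matrix, vs, samples, regions, genes, contrasts,
                       unit_kind="variant")
        ps = [r.p_raw for r in res]
        assert ps == sorted(ps)

    def test_empty_arm_contrast_skipped_with_warning(self, caplog):
        matrix, vs, samples, regions, genes, _ = self._scenario()
        sev = [c for c in standard_contrasts() if c.name == "severity"]
        with caplog.at_level(logging.WARNING, logger="twinrare"):
            res = run_scan(matrix, vs, samples, regions, genes, sev,
                           unit_kind="variant")
        assert res == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_overlapping_rules_rejected(self):
        matrix, vs, samples, regions, genes, _ = self._scenario()
        bad = [PhenotypeContrast("bad", lambda s: True, lambda s: True)]
        with pytest.raises(ValueError, match="overlap"):
            run_scan(matrix, vs, samples, regions, genes, bad, unit_kind="variant")

    def test_misaligned_inputs_rejected(self):
        matrix, vs, samples, regions, genes, contrasts = self._scenario()
        with pytest.raises(ValueError, match="misaligned"):
            run_scan(matrix, vs, samples[:-1], regions, genes, contrasts)
        with pytest.raises(ValueError, match="unit_kind"):
            run_scan(matrix, vs, samples, regions, genes, contrasts,
                     unit_kind="exon")

    def test_results_tsv_written(self, tmp_path):
        matrix, vs, samples, regions, genes, contrasts = self._scenario()
        res = run_scan(matrix, vs, samples, regions, genes, contrasts,
                       unit_kind="variant")
        out = tmp_path / "results.tsv"
        write_results_tsv(out, res)
        lines = out.read_text().splitlines()
        assert len(lines) == len(res) + 1
        assert lines[0].startswith("contrast\tunit_kind\tunit_id")
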