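"""The four association methods, the naive scan, and multiplicity control."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from monoqtl.eqtl import (
    bh_fdr,
    bonferroni_threshold,
    fit_gaussian_nonzero_mixed,
    fit_logistic_mixed,
    fit_proportion_anova,
    fit_tweedie_mixed,
    naive_mw_fit,
    naive_mw_scan,
    run_eqtl_scan,
    significant_hits,
)
from monoqtl.qc import ct_to_expression
from monoqtl.simulate import PlantedEffect, SimConfig, simulate_expression


def _null_gene(seed, n_ind=15, cells=30, person_sd=1.0, maf=0.3):
    cfg = SimConfig(n_individuals=n_ind, cells_per_individual=cells, n_genes=1,
                    snp_mafs=(maf,), cell_types=("CL",),
                    person_intercept_sd=person_sd)
    ct, truth = simulate_expression(cfg, seed)
    expr = ct_to_expression(ct)
    inds = expr.cell_meta["individual_id"]
    dose = inds.map(truth.genotypes.dosages["rs0001"]).to_numpy(float)
    return expr.values["G001"].to_numpy(), dose, inds.to_numpy()


class TestProportionAnova:
    def test_hand_computed_f(self):
        # SSB = 0.16, SSW = 0.01, df (1, 2) -> F = 32
        mf = fit_proportion_anova([0.2, 0.3, 0.6, 0.7], [0, 0, 1, 1])
        assert mf.extra["F"] == pytest.approx(32.0, rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(2)
        props = rng.uniform(0, 1, 12)
        dose = np.array([0] * 5 + [1] * 5 + [2] * 2)
        mf = fit_proportion_anova(props, dose, min_per_group=2)
        ref = f_oneway(props[:5], props[5:10], props[10:])
        assert mf.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_equal_proportions_give_f_zero_p_one(self):
        mf = fit_proportion_anova([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1])
        assert mf.extra["F"] == 0.0 and mf.p_value == 1.0

    def test_rare_homozygote_group_collapsed(self):
        mf = fit_proportion_anova([0.1, 0.2, 0.5, 0.6, 0.9], [0, 0, 1, 1, 2])
        assert mf.extra["collapsed"]

    def test_zero_within_variance_flagged(self):
        mf = fit_proportion_anova([0.2, 0.2, 0.8, 0.8], [0, 0, 1, 1])
        assert not mf.converged and "variance" in mf.skip_reason

    def test_direction_from_carrier_mean(self):
        mf = fit_proportion_anova([0.2, 0.3, 0.6, 0.7], [0, 0, 1, 1])
        assert mf.direction == "+"


class TestGaussianNonzero:
    def test_ols_limit(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        g = [f"I{i:02d}" for i in np.repeat(np.arange(10), 20)]
        d = np.repeat(rng.choice([0, 1, 2], 10, p=[.49, .42, .09]), 20).astype(float)
        y = 20.0 + rng.normal(0, 2, 200) + 13.0   # nonzero, no person effect
        mf = fit_gaussian_nonzero_mixed(y, d, g)
        ref = stats.linregress(d, y)
        assert abs(mf.p_value - ref.pvalue) < 0.01

    def test_constant_dosage_is_error(self):
        with pytest.raises(ValueError, match="contrast"):
            fit_gaussian_nonzero_mixed([13.0, 14.0], [1, 1], ["a", "b"])

    def test_identical_nonzero_values_skipped(self):
        y = np.full(60, 15.0)
        g = [f"I{i}" for i in np.repeat(np.arange(6), 10)]
        d = np.repeat([0, 0, 1, 1, 2, 2], 10).astype(float)
        mf = fit_gaussian_nonzero_mixed(y, d, g)
        assert mf.skip_reason != ""

    def test_too_few_individuals_with_nonzero_cells_skipped(self):
        y = np.array([15.0, 16.0, 0.0, 0.0, 0.0, 0.0])
        g = ["a", "a", "b", "b", "c", "c"]
        d = np.array([0, 0, 1, 1, 2, 2], float)
        mf = fit_gaussian_nonzero_mixed(y, d, g)
        assert "3 individuals" in mf.skip_reason


class TestLogisticMixed:
    def test_single_class_outcome_skipped(self):
        y = np.ones(40)
        g = [f"I{i}" for i in np.repeat(np.arange(4), 10)]
        d = np.repeat([0, 1, 1, 2], 10).astype(float)
        mf = fit_logistic_mixed(y, d, g)
        assert mf.skip_reason == "single-class outcome"

    def test_matches_lme4_glmer(self, tmp_path):
        """Estimate and SE agree with the reference GLMM fitter in R."""
        y, d, g = _null_gene(17)
        on = (y > 0).astype(int)
        df = pd.DataFrame({"y": on, "dose": d, "ind": g})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ dose + (1|ind), data=d, family=binomial)
            co <- summary(m)$coefficients
            cat(co["dose",1], co["dose",2], sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=180)
        assert out.returncode == 0, out.stderr
        est_ref, se_ref = (float(v) for v in out.stdout.split())
        mf = fit_logistic_mixed(y, d, g)
        assert mf.effect == pytest.approx(est_ref, abs=0.02)
        assert mf.se == pytest.approx(se_ref, rel=0.10)

    def test_cell_order_and_id_relabel_invariance(self):
        y, d, g = _null_gene(23)
        mf1 = fit_logistic_mixed(y, d, g)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        relabel = {u: f"P{j}" for j, u in enumerate(np.unique(g))}
        g2 = np.array([relabel[v] for v in g])[perm]
        mf2 = fit_logistic_mixed(y[perm], d[perm], g2)
        assert mf1.p_value == pytest.approx(mf2.p_value, abs=1e-5)


class TestTweedieMixed:
    def test_all_zero_gene_skipped(self):
        y = np.zeros(40)
        g = [f"I{i}" for i in np.repeat(np.arange(4), 10)]
        d = np.repeat([0, 1, 1, 2], 10).astype(float)
        mf = fit_tweedie_mixed(y, d, g)
        assert mf.skip_reason == "all-zero gene"

    def test_constant_dosage_is_error(self):
        with pytest.raises(ValueError, match="contrast"):
            fit_tweedie_mixed([0.0, 13.0], [2, 2], ["a", "b"])

    def test_power_outside_range_rejected(self):
        y, d, g = _null_gene(3)
        with pytest.raises(ValueError, match="power"):
            fit_tweedie_mixed(y, d, g, power=2.5)

    def test_profiled_power_in_grid(self):
        y, d, g = _null_gene(5)
        mf = fit_tweedie_mixed(y, d, g)
        assert 1.0 < mf.extra["power"] < 2.0

    def test_recovers_planted_log_mean_effect(self):
        """Mean estimate near the planted 0.5 log-mean shift per allele."""
        ests = []
        for seed in range(1, 41):
            cfg = SimConfig(n_individuals=15, cells_per_individual=40, n_genes=1,
                            snp_mafs=(0.3,), cell_types=("CL",),
                            baseline_log_mean=(2.6, 2.6), within_cell_sd=0.5,
                            person_intercept_sd=0.2, person_shared_sd=0.0,
                            mcar_detection_prob=0.7,
                            planted_effects=(PlantedEffect("G001", "rs0001",
                                                           "mean", 0.5),))
            ct, truth = simulate_expression(cfg, seed)
            expr = ct_to_expression(ct)
            inds = expr.cell_meta["individual_id"]
            dose = inds.map(truth.genotypes.dosages["rs0001"]).to_numpy(float)
            mf = fit_tweedie_mixed(expr.values["G001"].to_numpy(), dose,
                                   inds.to_numpy(), power=1.5)
            ests.append(mf.effect)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)


class TestNaiveMW:
    def test_all_tied_values_give_p_one(self):
        y = np.full(20, 15.0)
        d = np.repeat([0, 1], 10).astype(float)
        assert naive_mw_fit(y, d).p_value == 1.0

    def test_empty_group_skipped(self):
        mf = naive_mw_fit(np.arange(10, dtype=float), np.zeros(10))
        assert mf.skip_reason != ""

    def test_scan_shape(self):
        cfg = SimConfig(n_individuals=6, cells_per_individual=8, n_genes=3,
                        snp_mafs=(0.3, 0.4), cell_types=("CL", "NCL"))
        ct, truth = simulate_expression(cfg, 0)
        expr = ct_to_expression(ct)
        tab = naive_mw_scan(expr, truth.genotypes)
        assert len(tab) == 3 * 2 * 2
        assert (tab["method"] == "naive_mw").all()


def _bh_oracle(p, q):
    """Independent brute-force BH: sort, step-up, cummin of p*m/rank."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted, adjusted < q


class TestBH:
    def test_worked_example(self):
        q, keep = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.1)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])
        assert keep.sum() == 3

    def test_all_ones_retain_nothing(self):
        _, keep = bh_fdr([1.0, 1.0, 1.0])
        assert not keep.any()

    def test_single_p_identity(self):
        q, _ = bh_fdr([0.05])
        assert q[0] == pytest.approx(0.05)

    def test_empty_input(self):
        q, keep = bh_fdr([])
        assert len(q) == 0 and len(keep) == 0

    def test_nan_excluded_from_ranks(self):
        q, keep = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1]) and not keep[1]
        ref, _ = _bh_oracle([0.01, 0.02], 0.1)
        assert q[[0, 2]] == pytest.approx(ref)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, pvals):
        q, keep = bh_fdr(pvals, q=0.1)
        ref_q, ref_keep = _bh_oracle(pvals, 0.1)
        assert q == pytest.approx(ref_q, abs=1e-12)
        assert (keep == ref_keep).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            q, _ = bh_fdr(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert q == pytest.approx(q_ref, abs=1e-12)


class TestBonferroni:
    def test_study_panel(self):
        # 90 genes x 7 SNPs at alpha 0.05
        assert bonferroni_threshold(90, 7) == pytest.approx(7.94e-5, rel=1e-3)

    @pytest.mark.parametrize("genes,snps,expected", [(1, 1, 0.05), (10, 10, 5e-4)])
    def test_arithmetic(self, genes, snps, expected):
        assert bonferroni_threshold(genes, snps) == pytest.approx(expected)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 7)


class TestScan:
    def test_empty_gene_list_empty_table(self):
        cfg = SimConfig(n_individuals=6, cells_per_individual=8, n_genes=2,
                        snp_mafs=(0.3,), cell_types=("CL",))
        ct, truth = simulate_expression(cfg, 0)
        expr = ct_to_expression(ct)
        expr.values = expr.values.iloc[:, :0]
        tab = run_eqtl_scan(expr, truth.genotypes)
        assert tab.empty

    def test_fdr_within_cell_type_method_family(self):
        cfg = SimConfig(n_individuals=10, cells_per_individual=12, n_genes=4,
                        snp_mafs=(0.3, 0.4), cell_types=("CL", "NCL"))
        ct, truth = simulate_expression(cfg, 1)
        expr = ct_to_expression(ct)
        tab = run_eqtl_scan(expr, truth.genotypes, methods=("gaussian_nonzero",))
        for (_, _), sub in tab.groupby(["cell_type", "method"]):
            ok = sub["converged"] & sub["p_value"].notna()
            ref, _ = _bh_oracle(sub.loc[ok, "p_value"].to_numpy(), 0.1)
            assert sub.loc[ok, "fdr_q"].to_numpy() == pytest.approx(ref, abs=1e-12)

    def test_direction_matches_effect_sign(self):
        cfg = SimConfig(n_individuals=10, cells_per_individual=12, n_genes=3,
                        snp_mafs=(0.4,), cell_types=("CL",))
        ct, truth = simulate_expression(cfg, 2)
        expr = ct_to_expression(ct)
        tab = run_eqtl_scan(expr, truth.genotypes)
        est = tab[tab["effect"].notna() & (tab["effect"] != 0)]
        assert (np.sign(est["effect"]) == est["direction"].map({"+": 1, "-": -1})).all()

    def test_skips_recorded_not_raised(self):
        # one SNP monomorphic in the sample -> every fit for it is a recorded skip
        cfg = SimConfig(n_individuals=8, cells_per_individual=10, n_genes=2,
                        snp_mafs=(0.01, 0.4), cell_types=("CL",))
        ct, truth = simulate_expression(cfg, 11)
        assert truth.genotypes.dosages["rs0001"].nunique() == 1  # realized monomorphic
        expr = ct_to_expression(ct)
        tab = run_eqtl_scan(expr, truth.genotypes, methods=("gaussian_nonzero",))
        mono = tab[tab["rsid"] == "rs0001"]
        assert (mono["skip_reason"] == "no genotype contrast").all()
        assert not mono["significant"].any()

    def test_planted_logistic_effect_found(self):
        found = 0
        for seed in (4, 5, 9):
            cfg = SimConfig(n_individuals=15, cells_per_individual=30, n_genes=6,
                            snp_mafs=(0.4,), cell_types=("CL",),
                            detection_intercept=-3.0,
                            planted_effects=(PlantedEffect("G001", "rs0001",
                                                           "detection", 2.0),))
            ct, truth = simulate_expression(cfg, seed)
            expr = ct_to_expression(ct)
            tab = run_eqtl_scan(expr, truth.genotypes)
            hits = significant_hits(tab)
            found += (hits[["rsid", "gene"]].apply(tuple, axis=1)
                      == ("rs0001", "G001")).any()
        assert found >= 2
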