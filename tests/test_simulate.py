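"""Synthetic-data generator: distributions, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from monoqtl.qc import ct_to_expression, on_proportions
from monoqtl.simulate import (
    CoexpressionBlock,
    PlantedEffect,
    SimConfig,
    make_null_fixture,
    make_powered_fixture,
    simulate_expression,
    simulate_genotypes,
)


class TestGenotypes:
    def test_frequencies_follow_hwe(self):
        rng = np.random.default_rng(1)
        d = simulate_genotypes(0.3, 10_000, rng)
        freqs = np.bincount(d, minlength=3) / 10_000
        assert freqs == pytest.approx([0.49, 0.42, 0.09], abs=0.02)

    def test_low_maf_mostly_zero(self):
        rng = np.random.default_rng(2)
        d = simulate_genotypes(0.01, 15, rng)
        assert (d == 0).mean() > 0.8

    def test_same_seed_identical(self):
        d1 = simulate_genotypes(0.25, 50, np.random.default_rng(9))
        d2 = simulate_genotypes(0.25, 50, np.random.default_rng(9))
        assert (d1 == d2).all()

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0.6, 10, np.random.default_rng(0))


class TestSimulateExpression:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_individuals=5, cells_per_individual=6, n_genes=4,
                        snp_mafs=(0.3,), cell_types=("CL",))
        ct1, t1 = simulate_expression(cfg, 42)
        ct2, t2 = simulate_expression(cfg, 42)
        pd.testing.assert_frame_equal(ct1.values, ct2.values)
        pd.testing.assert_frame_equal(t1.genotypes.dosages, t2.genotypes.dosages)

    def test_zero_pattern_matches_lod_mask(self):
        ct, _ = make_null_fixture(3, n_individuals=5, cells_per_individual=10,
                                  n_genes=6)
        expr = ct_to_expression(ct, 40, 28)
        assert (((expr.values == 0) == (ct.values >= 28)).all()).all()

    def test_iid_gaussian_limit_recovers_sigma(self):
        """No person effects, full detection: per-gene sample sd ~ sigma."""
        cfg = SimConfig(n_individuals=10, cells_per_individual=1000, n_genes=2,
                        snp_mafs=(0.3,), cell_types=("CL",),
                        baseline_log_mean=(3.2, 3.2), within_cell_sd=1.5,
                        person_intercept_sd=0.0, person_shared_sd=0.0,
                        mcar_detection_prob=1.0)
        ct, _ = simulate_expression(cfg, 4)
        expr = ct_to_expression(ct)
        sds = expr.values.std(ddof=1)
        assert sds.to_numpy() == pytest.approx(1.5, rel=0.10)

    def test_detection_plant_orders_on_proportions_with_dosage(self):
        majority = 0
        for seed in range(10):
            cfg = SimConfig(n_individuals=30, cells_per_individual=20, n_genes=1,
                            snp_mafs=(0.4,), cell_types=("CL",),
                            detection_intercept=-3.0,
                            planted_effects=(PlantedEffect("G001", "rs0001",
                                                           "detection", 1.5),))
            ct, truth = simulate_expression(cfg, seed)
            expr = ct_to_expression(ct)
            props = on_proportions(expr, "individual")["G001"]
            dose = truth.genotypes.dosages["rs0001"].reindex(props.index)
            means = props.groupby(dose.values).mean()
            if len(means) == 3 and means.is_monotonic_increasing:
                majority += 1
        assert majority >= 6

    def test_on_off_switch_silences_every_cell(self):
        cfg = SimConfig(n_individuals=8, cells_per_individual=12, n_genes=2,
                        snp_mafs=(0.3,), cell_types=("CL", "NCL"),
                        on_off_genes={"G001": 0.5})
        ct, truth = simulate_expression(cfg, 6)
        expr = ct_to_expression(ct)
        off_inds = truth.off_states.index[truth.off_states["G001"]]
        assert len(off_inds) > 0
        for ind in off_inds:
            cells = expr.cell_meta["individual_id"] == ind
            assert (expr.values.loc[cells, "G001"] == 0).all()

    def test_config_validation_catches_unknown_names(self):
        with pytest.raises(ValueError, match="unknown gene"):
            SimConfig(n_genes=2, planted_effects=(
                PlantedEffect("G099", "rs0001", "mean", 1.0),)).validate()
        with pytest.raises(ValueError, match="unknown SNP"):
            SimConfig(n_genes=2, planted_effects=(
                PlantedEffect("G001", "rs9999", "mean", 1.0),)).validate()
        with pytest.raises(ValueError, match="channel"):
            SimConfig(n_genes=2, planted_effects=(
                PlantedEffect("G001", "rs0001", "variance", 1.0),)).validate()
        with pytest.raises(ValueError, match="block"):
            SimConfig(n_genes=2, coexpression_blocks=(
                CoexpressionBlock(("G001", "G077"), 4.0),)).validate()


class TestFixtures:
    def test_null_fixture_truth_registry_empty(self):
        _, truth = make_null_fixture(1)
        assert truth.planted_effects == ()

    def test_powered_fixture_registry_matches_config(self):
        _, truth = make_powered_fixture(1)
        assert {p.channel for p in truth.planted_effects} == {"mean", "detection"}
        assert all(p.cell_type == "NCL" for p in truth.planted_effects)

    def test_fixture_round_trips_through_io(self, tmp_path):
        from monoqtl.datamodel import read_ct_matrix, write_ct_matrix

        ct, _ = make_null_fixture(2, n_individuals=4, cells_per_individual=5,
                                  n_genes=3)
        write_ct_matrix(ct, tmp_path / "ct.csv")
        back = read_ct_matrix(tmp_path / "ct.csv")
        pd.testing.assert_frame_equal(back.values, ct.values)


def test_null_pvalues_uniform_without_person_effects():
    """With person effects off and no plants, every method's p-value is
    uniform (cells are genuinely independent)."""
    from monoqtl.eqtl import (fit_gaussian_nonzero_mixed, fit_logistic_mixed,
                              fit_proportion_anova, fit_tweedie_mixed,
                              naive_mw_fit)

    pvals = {k: [] for k in ("tweedie", "logistic", "gaussian", "anova", "mw")}
    for seed in range(150):
        cfg = SimConfig(n_individuals=15, cells_per_individual=20, n_genes=1,
                        snp_mafs=(0.4,), cell_types=("CL",),
                        person_intercept_sd=0.0, person_shared_sd=0.0)
        ct, truth = simulate_expression(cfg, seed)
        expr = ct_to_expression(ct)
        inds = expr.cell_meta["individual_id"]
        dose = inds.map(truth.genotypes.dosages["rs0001"]).to_numpy(float)
        y = expr.values["G001"].to_numpy()
        ia = inds.to_numpy()
        try:
            pvals["tweedie"].append(fit_tweedie_mixed(y, dose, ia, power=1.5).p_value)
            pvals["logistic"].append(fit_logistic_mixed(y, dose, ia).p_value)
            pvals["gaussian"].append(fit_gaussian_nonzero_mixed(y, dose, ia).p_value)
            props = on_proportions(expr, "individual")["G001"]
            pd_dose = truth.genotypes.dosages["rs0001"].reindex(props.index)
            pvals["anova"].append(
                fit_proportion_anova(props.to_numpy(), pd_dose.to_numpy(float)).p_value)
            pvals["mw"].append(naive_mw_fit(y, dose).p_value)
        except ValueError:
            continue
    for name, p in pvals.items():
        p = np.array([v for v in p if np.isfinite(v)])
        assert len(p) > 100
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01, f"{name}: KS p = {ks.pvalue}"


def test_person_effects_inflate_mw_but_not_mixed():
    """Raising the person-intercept sd inflates the naive per-cell test's
    false-positive rate monotonically."""
    rates = []
    for sd in (0.0, 0.5, 1.0):
        rej = 0
        n = 60
        for seed in range(n):
            cfg = SimConfig(n_individuals=12, cells_per_individual=25, n_genes=1,
                            snp_mafs=(0.4,), cell_types=("CL",),
                            person_intercept_sd=sd, person_shared_sd=0.0)
            ct, truth = simulate_expression(cfg, 1000 + seed)
            expr = ct_to_expression(ct)
            inds = expr.cell_meta["individual_id"]
            dose = inds.map(truth.genotypes.dosages["rs0001"]).to_numpy(float)
            from monoqtl.eqtl import naive_mw_fit

            mf = naive_mw_fit(expr.values["G001"].to_numpy(), dose)
            if np.isfinite(mf.p_value):
                rej += mf.p_value < 0.05
        rates.append(rej / n)
    assert rates[0] < rates[1] < rates[2]
    assert rates[0] < 0.15 and rates[2] > 0.3
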