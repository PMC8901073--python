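import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pigbiome as pb
from pigbiome.models import (bootstrap_fb, fb_cell_medians, fb_model,
                             fb_ratio, fit_repeated_model, per_otu_tests,
                             reml_loglik)


@pytest.fixture(scope="module")
def design17():
    return pb.generate_design(pb.SimParams(seed=1))


class TestFitRepeatedModel:
    def test_reduces_to_ols_anova_when_pinned(self, design17):
        y = pb.simulate_response(design17, sigma_pig=0.0, rho=0.0,
                                 sigma_noise=1.0, seed=21)
        fit = fit_repeated_model(y, design17, factors=("treatment",),
                                 fix_rho=0.0, fix_gamma=0.0)
        groups = [y[design17["treatment"] == t]
                  for t in ("white", "traditional", "oil")]
        f_ref, _ = stats.f_oneway(*groups)
        assert fit.terms.loc["treatment", "F"] == pytest.approx(
            f_ref, abs=1e-8)

    def test_independence_data_matches_anova_on_average(self):
        # free REML fit on data without pig effects or autocorrelation:
        # with enough pigs the variance components shrink to zero and the
        # treatment F tracks the one-way ANOVA F
        params = pb.SimParams(n_pigs=120,
                              group_sizes={"white": 40, "traditional": 40,
                                           "oil": 40}, seed=3)
        design = pb.generate_design(params)
        fs, refs = [], []
        for i in range(30):
            y = pb.simulate_response(design, sigma_pig=0.0, rho=0.0,
                                     sigma_noise=1.0, seed=500 + i)
            fit = fit_repeated_model(y, design, factors=("treatment",))
            groups = [y[design["treatment"] == t]
                      for t in ("white", "traditional", "oil")]
            f_ref, _ = stats.f_oneway(*groups)
            fs.append(fit.terms.loc["treatment", "F"])
            refs.append(f_ref)
        assert np.mean(fs) / np.mean(refs) == pytest.approx(1.0, abs=0.02)

    def test_constant_response(self, design17):
        y = pd.Series(5.0, index=design17.index)
        fit = fit_repeated_model(y, design17)
        assert (fit.terms["F"] == 0).all()
        assert (fit.terms["p_value"] == 1).all()

    def test_parameter_recovery_large_design(self):
        params = pb.SimParams(n_pigs=500,
                              group_sizes={"white": 250, "oil": 250},
                              seed=2)
        design = pb.generate_design(params)
        y = pb.simulate_response(design, sigma_pig=1.0, sigma_noise=1.0,
                                 rho=0.5, seed=22,
                                 treatment_effects={"oil": 1.0},
                                 timepoint_effects={"T2": 0.5, "T3": 0.5})
        fit = fit_repeated_model(y, design)
        assert fit.rho == pytest.approx(0.5, abs=0.12)
        assert fit.sigma2_pig == pytest.approx(1.0, rel=0.3)
        assert fit.sigma2_e == pytest.approx(1.0, rel=0.2)

    def test_reml_optimum_beats_random_points(self, design17):
        y = pb.simulate_response(design17, sigma_pig=0.5, sigma_noise=1.0,
                                 rho=0.3, seed=23)
        fit = fit_repeated_model(y, design17)
        rng = np.random.default_rng(0)
        for _ in range(50):
            ll = reml_loglik(y, design17,
                             sigma2_pig=float(rng.uniform(0.01, 3)),
                             sigma2_e=float(rng.uniform(0.05, 3)),
                             rho=float(rng.uniform(-0.95, 0.95)))
            assert fit.reml >= ll - 1e-6

    def test_rank_deficient_design_errors(self, design17):
        meta = design17.copy()
        meta["treatment"] = "white"  # single level -> no dummies, fine
        y = pb.simulate_response(design17, seed=24)
        # duplicated factor makes the design collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_repeated_model(y, meta, factors=("timepoint", "timepoint"))


class TestPerOtuTests:
    def test_alpha_zero_flags_nothing(self, sim_dataset):
        out = per_otu_tests(sim_dataset["norm"], alpha=0.0)
        assert not out["significant"].any()

    def test_strong_effect_detected(self):
        panel = pb.random_taxon_panel(30, seed=4)
        firm = panel.index[panel["phylum"] == "Firmicutes"][0]
        te = pd.DataFrame(0.0, index=panel.index,
                          columns=["white", "oil"])
        te.loc[firm, "oil"] = np.log(4.0)
        params = pb.SimParams(
            n_pigs=50, group_sizes={"white": 25, "oil": 25}, taxa=panel,
            treatment_effects=te, sigma_pig=0.2, sigma_noise=0.4, seed=5)
        design = pb.generate_design(params)
        table, _ = pb.generate_otu_table(design, params)
        norm = pb.css_normalize(pb.filter_otus(table))
        out = per_otu_tests(norm).set_index("taxon")
        assert bool(out.loc[firm, "significant"])

    def test_reports_term_columns(self, sim_dataset):
        out = per_otu_tests(sim_dataset["norm"])
        assert {"p_treatment", "p_timepoint", "F_treatment",
                "significant"} <= set(out.columns)
        assert ((out["p_treatment"] > 0) & (out["p_treatment"] <= 1)).all()


class TestFbRatio:
    def test_hand_ratio(self, small_table):
        norm = pb.css_normalize(small_table)
        fb = fb_ratio(norm)
        vals = norm.values
        firm = vals.loc[["t1", "t2"]].sum()
        bact = vals.loc[["t3"]].sum()
        expected = (firm / bact).dropna()
        for s in fb.index:
            assert fb.loc[s, "ratio"] == pytest.approx(expected[s])

    def test_equal_sums_give_one(self):
        from test_otu import make_table
        table = make_table([[10], [10]])
        table.lineages.loc["t1", "phylum"] = "Bacteroidetes"
        fb = fb_ratio(pb.css_normalize(table))
        assert fb["ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_bacteroidetes_excluded(self, small_table):
        # sample s1 has zero count for the single Bacteroidetes taxon
        norm = pb.css_normalize(small_table)
        fb = fb_ratio(norm)
        assert "s1" not in fb.index
        assert set(fb.index) == {"s2", "s3", "s4"}

    def test_generator_truth_recovered_at_scale(self):
        mult = {"white": 1.0, "oil": 2.0}
        params = pb.SimParams(
            n_pigs=60, group_sizes={"white": 30, "oil": 30},
            treatment_multipliers=mult, sigma_pig=0.1, sigma_noise=0.2,
            seed=6)
        design = pb.generate_design(params)
        table, truth = pb.generate_otu_table(design, params)
        norm = pb.css_normalize(pb.filter_otus(table))
        med = fb_cell_medians(fb_ratio(norm), norm.metadata)
        tf = truth["true_fb"]
        merged = med.merge(tf, on=["treatment", "period"])
        ratio = merged["median_FB"] / merged["true_FB"]
        assert np.all(np.abs(ratio - 1) < 0.15)


class TestFbModel:
    def test_constant_ratio_no_effects(self, design17):
        fb = pd.DataFrame({"ratio": 2.0}, index=design17.index)
        fit = fb_model(fb, design17)
        assert (fit.terms["F"] == 0).all()

    def test_timepoint_effect_detected(self, design17):
        y = pb.simulate_response(design17, sigma_pig=0.2, sigma_noise=0.3,
                                 rho=0.3, seed=30,
                                 timepoint_effects={"T2": 1.5, "T3": 1.5})
        fb = pd.DataFrame({"ratio": np.exp(y)}, index=design17.index)
        fit = fb_model(fb, design17)
        assert fit.terms.loc["period", "p_value"] < 0.05

    def test_three_terms_reported(self, sim_dataset):
        fb = fb_ratio(sim_dataset["norm"])
        fit = fb_model(fb, sim_dataset["norm"].metadata)
        assert list(fit.terms.index) == ["period", "treatment",
                                         "period:treatment"]


class TestBootstrapFb:
    def test_identity_resample_equals_single_fit(self, sim_dataset):
        norm = sim_dataset["norm"]
        boot = bootstrap_fb(norm, n_boot=3, seed=7, unit="identity")
        fit = fb_model(fb_ratio(norm), norm.metadata)
        for term in fit.terms.index:
            assert boot.term_summary.loc[term, "statistic_bstr"] == \
                pytest.approx(fit.terms.loc[term, "F"])
            assert boot.term_summary.loc[term, "p_value_bstr"] == \
                pytest.approx(fit.terms.loc[term, "p_value"])

    def test_replicate_count_and_determinism(self, sim_dataset):
        norm = sim_dataset["norm"]
        b1 = bootstrap_fb(norm, n_boot=20, seed=8)
        b2 = bootstrap_fb(norm, n_boot=20, seed=8)
        assert len(b1.replicate_terms) == 20
        pd.testing.assert_frame_equal(b1.replicate_terms,
                                      b2.replicate_terms)

    def test_quartiles_ordered(self, sim_dataset):
        boot = bootstrap_fb(sim_dataset["norm"], n_boot=30, seed=9)
        cs = boot.cell_summary
        assert (cs["Q1_bstr"] <= cs["median_FB"] + 1e-9).all()
        assert (cs["median_FB"] <= cs["Q3_bstr"] + 1e-9).all()

    def test_null_median_p_not_extreme(self):
        # with no effects at all, the median bootstrap p per term sits in
        # the middle of the unit interval (averaged over datasets)
        panel = pb.random_taxon_panel(60, seed=10)
        meds = []
        for i in range(4):
            params = pb.SimParams(
                seed=40 + i, taxa=panel,
                treatment_multipliers={"white": 1, "traditional": 1,
                                       "oil": 1})
            design = pb.generate_design(params)
            table, _ = pb.generate_otu_table(design, params)
            norm = pb.css_normalize(pb.filter_otus(table))
            boot = bootstrap_fb(norm, n_boot=60, seed=40 + i)
            meds.append(boot.term_summary["p_value_bstr"])
        mean_meds = pd.concat(meds, axis=1).mean(axis=1)
        assert ((mean_meds > 0.2) & (mean_meds < 0.8)).all()

    def test_pig_unit_runs(self, sim_dataset):
        boot = bootstrap_fb(sim_dataset["norm"], n_boot=5, seed=11,
                            unit="pig")
        assert len(boot.replicate_terms) == 5
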