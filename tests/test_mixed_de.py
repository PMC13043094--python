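import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import layerprot as lp
from layerprot.mixed_de import fit_protein_model, contrast_emm
from layerprot.preprocess import NormTable

from conftest import paired_values


def paired_t_oracle(values, design):
    """Closed-form paired t-test on within-individual STR-NSTR differences."""
    samp = design.samples(layer="SM")
    samp = samp[samp["group"].isin(["STR", "NSTR"])].set_index("sample_id")
    wide = samp.reset_index().pivot(index="individual_id", columns="group",
                                    values="sample_id")
    d = np.array([values[wide.loc[i, "STR"]] - values[wide.loc[i, "NSTR"]]
                  for i in wide.index])
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    return 2 * stats.t.sf(abs(t), len(d) - 1), d.mean()


class TestFitAndContrast:
    def test_constant_observations_degenerate(self, small_design):
        samp = small_design.samples(layer="SM")
        y = pd.Series(7.0, index=samp["sample_id"])
        fit = fit_protein_model(y, small_design.subset("SM"))
        assert fit.sigma2_e < 1e-12 and fit.sigma2_b < 1e-12
        rec = contrast_emm(fit, "STRvCTRL")
        assert rec["delta_emm"] == pytest.approx(0.0)
        assert rec["p"] == 1.0

    def test_paired_estimate_is_mean_within_individual_difference(self, small_design):
        rng = np.random.default_rng(5)
        y = paired_values(small_design, effect=0.7, rng=rng)
        fit = fit_protein_model(y, small_design.subset("SM"))
        rec = contrast_emm(fit, "STRvNSTR")
        _, dbar = paired_t_oracle(y, small_design)
        assert rec["delta_emm"] == pytest.approx(dbar, abs=1e-10)

    def test_paired_t_oracle_equivalence(self, small_design):
        """Balanced paired two-group data, no set term: p matches paired t to 1e-8."""
        rng = np.random.default_rng(42)
        design = small_design.subset("SM")
        n_singular = 0
        for _ in range(50):
            y = paired_values(small_design, effect=rng.normal(0, 0.5), rng=rng)
            fit = fit_protein_model(y, design)
            if fit.singular:
                # boundary REML solution (between-individual variance 0):
                # the paired-t equivalence applies to interior fits
                n_singular += 1
                continue
            rec = contrast_emm(fit, "STRvNSTR")
            p_oracle, _ = paired_t_oracle(y, small_design)
            assert rec["p"] == pytest.approx(p_oracle, abs=1e-8)
            assert rec["df"] == pytest.approx(5.0, abs=1e-6)  # n_pairs - 1
        assert n_singular <= 3

    def test_ctrl_singletons_estimable(self, default_design):
        rng = np.random.default_rng(3)
        design = default_design.subset("SM")
        samp = design.samples()
        b = {i: rng.normal(0, 0.4) for i in samp["individual_id"].unique()}
        y = pd.Series({r["sample_id"]: 10 + b[r["individual_id"]] + rng.normal(0, 0.2)
                       for _, r in samp.iterrows()})
        fit = fit_protein_model(y, design)
        rec = contrast_emm(fit, "STRvCTRL")
        assert np.isfinite(rec["p"]) and rec["fit_status"] == "ok"

    def test_planted_effect_noise_free(self, small_design):
        design = small_design.subset("SM")
        samp = design.samples()
        y = pd.Series({r["sample_id"]: 10.0 + (1.0 if r["group"] == "STR" else 0.0)
                       for _, r in samp.iterrows()})
        fit = fit_protein_model(y, design)
        rec = contrast_emm(fit, "STRvCTRL")
        assert rec["delta_emm"] == pytest.approx(1.0, abs=1e-10)

    def test_missing_group_not_estimable(self, small_design):
        design = small_design.subset("SM")
        samp = design.samples()
        keep = samp[samp["group"] != "CTRL"]
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(10, 1, len(keep)), index=keep["sample_id"])
        fit = fit_protein_model(y, design)
        rec = contrast_emm(fit, "STRvCTRL")
        assert rec["fit_status"] == "not_estimable"
        assert np.isnan(rec["p"])

    def test_contrast_antisymmetric(self, default_design):
        rng = np.random.default_rng(9)
        design = default_design.subset("SM")
        samp = design.samples()
        y = pd.Series(rng.normal(10, 1, len(samp)), index=samp["sample_id"])
        fit = fit_protein_model(y, design)
        ab = contrast_emm(fit, "STRvCTRL")
        ba = contrast_emm(fit, "CTRLvSTR")
        assert ab["delta_emm"] == pytest.approx(-ba["delta_emm"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_refined_grouping_contrasts(self, default_design):
        design = default_design.subset("SM")
        samp = design.samples()
        eff = {"CTRL": 0.0, "Dist": 0.25, "Adj": 0.5, "STR": 1.0}
        y = pd.Series({r["sample_id"]: 10.0 + eff[r["refined_group"]]
                       for _, r in samp.iterrows()})
        y += np.random.default_rng(2).normal(0, 1e-6, len(y))
        fit = fit_protein_model(y, design, refined=True)
        for cmp_name, want in (("AdjvCTRL", 0.5), ("DistvCTRL", 0.25),
                               ("STRvAdj", 0.5), ("AdjvDist", 0.25)):
            assert contrast_emm(fit, cmp_name)["delta_emm"] == pytest.approx(want, abs=1e-4)


class TestAgainstStatsmodels:
    def test_reml_components_match_mixedlm(self, default_design):
        """Independent route: statsmodels MixedLM REML on the same data."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(17)
        design = default_design.subset("SM")
        samp = design.samples()
        for rep in range(5):
            b = {i: rng.normal(0, 0.4) for i in samp["individual_id"].unique()}
            se = {s: rng.normal(0, 0.2) for s in samp["tmt_set"].unique()}
            y = pd.Series({r["sample_id"]: b[r["individual_id"]] + se[r["tmt_set"]]
                           + rng.normal(0, 0.2) for _, r in samp.iterrows()})
            fit = fit_protein_model(y, design)
            df = samp.assign(y=y.loc[samp["sample_id"]].to_numpy())
            m = smf.mixedlm("y ~ C(group, Treatment('CTRL')) + C(tmt_set)", df,
                            groups=df["individual_id"]).fit(reml=True)
            assert fit.sigma2_e == pytest.approx(m.scale, rel=1e-3)
            assert fit.sigma2_b == pytest.approx(float(m.cov_re.iloc[0, 0]),
                                                 rel=1e-2, abs=1e-4)
            rec = contrast_emm(fit, "STRvCTRL")
            sm_beta = m.params["C(group, Treatment('CTRL'))[T.STR]"]
            assert rec["delta_emm"] == pytest.approx(sm_beta, abs=1e-5)


class TestAgainstLmerTest:
    def test_satterthwaite_close_to_lmertest(self, tmp_path, default_design):
        """R lmerTest/emmeans as the field-standard oracle on a tiny fixture."""
        rng = np.random.default_rng(23)
        design = default_design.subset("SM")
        samp = design.samples()
        rows, ours = [], []
        for i in range(4):
            b = {ind: rng.normal(0, 0.35) for ind in samp["individual_id"].unique()}
            se = {s: rng.normal(0, 0.2) for s in samp["tmt_set"].unique()}
            y = pd.Series({r["sample_id"]: b[r["individual_id"]] + se[r["tmt_set"]]
                           + rng.normal(0, 0.15) for _, r in samp.iterrows()})
            fit = fit_protein_model(y, design)
            ours.append(contrast_emm(fit, "STRvCTRL"))
            for sid, v in y.items():
                m = samp.set_index("sample_id").loc[sid]
                rows.append({"protein": i, "y": v, "group": m["group"],
                             "tset": m["tmt_set"], "id": m["individual_id"]})
        fixture = tmp_path / "lmm.csv"
        pd.DataFrame(rows).to_csv(fixture, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent("""
            suppressMessages({library(lmerTest); library(emmeans)})
            args <- commandArgs(trailingOnly=TRUE)
            d <- read.csv(args[1])
            res <- do.call(rbind, lapply(split(d, d$protein), function(s) {
              m <- lmer(y ~ group + tset + (1|id), data=s, REML=TRUE)
              em <- emmeans(m, "group", lmer.df="satterthwaite")
              ct <- as.data.frame(contrast(em, method=list(x=c(-1,0,1))))
              data.frame(delta=ct$estimate, se=ct$SE, df=ct$df, p=ct$p.value)
            }))
            write.csv(res, args[2], row.names=FALSE)
        """))
        out = tmp_path / "r.csv"
        subprocess.run(["Rscript", str(script), str(fixture), str(out)],
                       check=True, capture_output=True)
        r = pd.read_csv(out)
        for rec, (_, rrow) in zip(ours, r.iterrows()):
            assert rec["delta_emm"] == pytest.approx(rrow["delta"], abs=1e-6)
            assert rec["se"] == pytest.approx(rrow["se"], rel=1e-4)
            # df methods differ (expected vs observed information); p stays close
            assert rec["p"] == pytest.approx(rrow["p"], abs=2e-3)


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            lp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        assert (lp.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()
        assert lp.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.bh_adjust([0.5, 1.5])

    def test_monotone_in_input_order_statistics(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        fdr = lp.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def de_with_effects(default_design):
    truth = lp.generate_truth(150, fractions={"up": 0.2}, seed=31,
                              frac_single_set=0.0)
    noise = lp.NoiseConfig(seed=32)
    tmt = lp.simulate_tmt(default_design, truth, noise)
    design = default_design.subset("SM")
    norm = lp.normalize_tmt(tmt[tmt["layer"] == "SM"], design)
    return lp.run_de(norm, design), truth


class TestRunDe:

    def test_one_record_per_protein_per_comparison(self, de_with_effects):
        de, _ = de_with_effects
        counts = de.groupby("comparison")["protein_id"].nunique()
        assert (counts == 150).all()
        assert not de.duplicated(subset=["protein_id", "comparison"]).any()

    def test_de_flag_thresholds_strict(self):
        de = pd.DataFrame({
            "protein_id": ["a", "b"], "comparison": "STRvCTRL",
            "delta_emm": [0.35, 0.30], "p": [0.01, 0.01],
        })
        flag = (pd.Series([0.04, 0.04]) < 0.05) & (de["delta_emm"].abs() > 0.3)
        assert flag.tolist() == [True, False]  # |dEMM| must exceed 0.3 strictly

    def test_flags_follow_fdr_and_effect_rule(self, de_with_effects):
        de, _ = de_with_effects
        expect = (de["fdr"] < 0.05) & (de["delta_emm"].abs() > 0.3)
        assert (de["de_flag"] == expect.fillna(False)).all()

    def test_planted_up_proteins_recovered(self, de_with_effects):
        de, truth = de_with_effects
        t = truth.subset("SM").set_index("protein_id")
        sub = de[de["comparison"] == "STRvCTRL"].set_index("protein_id")
        up = t.index[t["de_class"] == "up"]
        sens = sub.loc[up, "de_flag"].mean()
        assert sens > 0.9
        null_fp = sub.loc[t.index[t["de_class"] == "null"], "de_flag"].mean()
        assert null_fp < 0.05

    def test_power_monotone_in_effect_size(self, default_design):
        design = default_design.subset("SM")
        power = []
        for i, eff in enumerate((0.5, 1.0, 2.0)):
            truth = lp.generate_truth(
                120, fractions={"up": 0.5}, seed=40 + i, frac_single_set=0.0,
                effect_params={"mean": eff, "sd": 0.0, "min": 0.0}, layers=("SM",))
            tmt = lp.simulate_tmt(design, truth, lp.NoiseConfig(seed=50 + i))
            norm = lp.normalize_tmt(tmt, design)
            de = lp.run_de(norm, design, comparisons=("STRvCTRL",)).set_index("protein_id")
            t = truth.subset("SM").set_index("protein_id")
            up = t.index[t["de_class"] == "up"]
            power.append(de.loc[up, "de_flag"].mean())
        assert power[0] < power[1] <= power[2]
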