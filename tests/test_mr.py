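"""Instrument selection, harmonization, and the MR estimator suite."""

import numpy as np
import pandas as pd
import pytest

from adipomet import synthetic
from adipomet.mr import (
    HarmonizedSet,
    MrEstimate,
    harmonize,
    ivw,
    mediation_mr,
    mr_egger,
    mr_presso,
    mvmr_ivw,
    run_mvmr,
    run_univariable,
    select_instruments,
    steiger_filter,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from tests.conftest import make_harmonized


def snp_table(rows):
    cols = ["snp", "chr", "pos", "effect_allele", "other_allele", "eaf",
            "beta", "se", "pval", "n"]
    return pd.DataFrame(rows, columns=cols)


class TestSelectInstruments:
    def test_same_position_proxy_keeps_best(self):
        t = snp_table([
            ("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1e5),
            ("rs2", 1, 100, "C", "T", 0.3, 0.1, 0.01, 1e-9, 1e5),
        ])
        kept = select_instruments(t)
        assert list(kept["snp"]) == ["rs1"]

    def test_different_chromosomes_all_kept(self):
        t = snp_table([
            (f"rs{i}", i + 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1e5)
            for i in range(10)
        ])
        assert len(select_instruments(t)) == 10

    def test_supplied_r2_prunes_cluster(self):
        t = snp_table([
            (f"rs{i}", 1, 1_000_000 * (i + 1), "A", "G", 0.3, 0.1, 0.01,
             1e-10 * (i + 1), 1e5)
            for i in range(5)
        ])
        ld = pd.DataFrame(
            [{"snp_a": f"rs{i}", "snp_b": f"rs{j}", "r2": 0.9}
             for i in range(5) for j in range(i + 1, 5)]
        )
        kept = select_instruments(t, ld_reference=ld)
        assert len(kept) == 1
        assert kept["snp"].iloc[0] == "rs0"  # smallest p wins greedily

    def test_empty_when_nothing_passes(self):
        t = snp_table([("rs1", 1, 100, "A", "G", 0.3, 0.01, 0.01, 0.5, 1e5)])
        assert select_instruments(t).empty


class TestHarmonize:
    def exposure_row(self, **over):
        d = {"snp": "rs1", "chr": 1, "pos": 100, "effect_allele": "A",
             "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01,
             "pval": 1e-10, "n": 1e5}
        d.update(over)
        return pd.DataFrame([d])

    def test_swapped_alleles_flip_beta(self):
        exp = self.exposure_row()
        out = self.exposure_row(effect_allele="G", other_allele="A",
                                beta=-0.05, eaf=0.7)
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.05)
        assert h.table["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_ambiguous_palindrome_dropped(self):
        exp = self.exposure_row(other_allele="T", eaf=0.5)
        out = self.exposure_row(other_allele="T", eaf=0.5)
        h = harmonize(exp, out)
        assert len(h) == 0
        assert h.exclusions["reason"].iloc[0] == "palindromic_ambiguous"

    def test_clear_palindrome_retained(self):
        exp = self.exposure_row(other_allele="T", eaf=0.10)
        out = self.exposure_row(other_allele="T", eaf=0.12, beta=0.07)
        h = harmonize(exp, out)
        assert len(h) == 1
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.07)

    def test_strand_flip_resolved(self):
        exp = self.exposure_row()  # A/G
        out = self.exposure_row(effect_allele="T", other_allele="C",
                                beta=0.07)
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.07)

    def test_unresolvable_alleles_dropped_with_reason(self):
        exp = self.exposure_row()
        out = self.exposure_row(effect_allele="A", other_allele="C")
        h = harmonize(exp, out)
        assert len(h) == 0
        assert h.exclusions["reason"].iloc[0] == "allele_mismatch"


class TestWaldRatio:
    def test_arithmetic(self):
        h = make_harmonized([0.1], [0.02], [0.05], [0.01])
        e = wald_ratio(h)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        e = wald_ratio(make_harmonized([0.1], [0.02], [0.0], [0.01]))
        assert e.beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_harmonized([0.0], [0.02], [0.05], [0.01]))

    def test_second_order_close_for_strong_instrument(self):
        h = make_harmonized([0.2], [0.01], [0.1], [0.02])  # |b|/se = 20
        first = wald_ratio(h).se
        second = wald_ratio(h, second_order=True).se
        assert abs(second - first) / first < 0.10


class TestIvw:
    def test_homogeneous_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                            [0.05, 0.10, 0.20], [0.01] * 3)
        e = ivw(h)
        assert e.beta == pytest.approx(0.5)
        assert e.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_weighted_ls_worked_example(self):
        h = make_harmonized([0.1, 0.2, 0.1], [0.01] * 3,
                            [0.05, 0.08, 0.04], [0.01, 0.01, 0.02])
        assert ivw(h).beta == pytest.approx(220 / 525, abs=1e-12)

    def test_two_ratio_hand_arithmetic(self):
        h = make_harmonized([1.0, 1.0], [1e-6] * 2, [0.4, 0.6], [0.1, 0.1])
        e = ivw(h)
        assert e.beta == pytest.approx(0.5)
        assert e.q_stat == pytest.approx(2.0, abs=1e-9)

    def test_equals_origin_wls_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(50):
            k = rng.integers(3, 20)
            bx = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.005, 0.05, k)
            by = 0.3 * bx + rng.normal(0, sy)
            h = make_harmonized(bx, np.full(k, 0.01), by, sy)
            wls = sm.WLS(by, bx, weights=1 / sy**2).fit()
            assert ivw(h).beta == pytest.approx(wls.params[0], abs=1e-10)

    def test_single_snp_defers_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.01])
        assert ivw(h).method == "wald_ratio"

    def test_sign_flip_invariance(self, rng):
        bx = rng.normal(0, 0.1, 8)
        by = 0.4 * bx + rng.normal(0, 0.01, 8)
        h1 = make_harmonized(bx, np.full(8, 0.01), by, np.full(8, 0.01))
        flip = np.ones(8)
        flip[::2] = -1
        h2 = make_harmonized(bx * flip, np.full(8, 0.01), by * flip,
                             np.full(8, 0.01))
        for est in (ivw, mr_egger):
            assert est(h1).beta == pytest.approx(est(h2).beta, abs=1e-10)


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, [0.01] * 4, 0.02 + 0.5 * bx, [0.01] * 4)
        e = mr_egger(h)
        assert e.beta == pytest.approx(0.5, abs=1e-10)
        assert e.intercept == pytest.approx(0.02, abs=1e-10)

    def test_balanced_pleiotropy_calibrated(self):
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            g = np.random.default_rng(s)
            k = 30
            bx = g.uniform(0.05, 0.2, k)
            pleio = g.normal(0.0, 0.02, k)  # mean-zero
            sy = np.full(k, 0.01)
            by = 0.3 * bx + pleio + g.normal(0, sy)
            e = mr_egger(make_harmonized(bx, np.full(k, 0.005), by, sy))
            rejections += e.intercept_p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_directional_pleiotropy_detected(self):
        positive = 0
        for s in range(20):
            g = np.random.default_rng(s)
            k = 30
            bx = g.uniform(0.05, 0.2, k)
            by = 0.3 * bx + g.normal(0.03, 0.01, k)  # mean-positive direct
            e = mr_egger(make_harmonized(bx, np.full(k, 0.005), by,
                                         np.full(k, 0.01)))
            positive += e.intercept > 0
        assert positive >= 18


class TestRobustEstimators:
    def test_weighted_median_constant_and_symmetric(self):
        h = make_harmonized([1.0] * 3, [1e-4] * 3, [0.3] * 3, [0.1] * 3)
        assert weighted_median(h, seed=0).beta == pytest.approx(0.3)
        h2 = make_harmonized([1.0] * 3, [1e-4] * 3, [0.1, 0.5, 0.9],
                             [0.1] * 3)
        assert weighted_median(h2, seed=0).beta == pytest.approx(0.5)

    def test_weighted_median_breakdown(self):
        bx = np.ones(14)
        by = np.array([0.3] * 10 + [1.5] * 4)
        h = make_harmonized(bx, np.full(14, 1e-4), by, np.full(14, 0.1))
        assert 0.25 <= weighted_median(h, seed=0).beta <= 0.40

    def test_weighted_mode_constant(self):
        h = make_harmonized([1.0] * 3, [1e-4] * 3, [0.7] * 3, [0.1] * 3)
        assert weighted_mode(h, seed=0).beta == pytest.approx(0.7, abs=0.02)

    def test_weighted_mode_plurality(self, rng):
        bx = np.ones(10)
        by = np.concatenate([0.3 + 0.01 * rng.standard_normal(7),
                             2.0 + 0.01 * rng.standard_normal(3)])
        h = make_harmonized(bx, np.full(10, 1e-4), by, np.full(10, 0.1))
        assert 0.2 <= weighted_mode(h, seed=0).beta <= 0.4

    def test_too_few_snps_rejected(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        for est in (mr_egger, weighted_median, weighted_mode):
            with pytest.raises(ValueError):
                est(h)


class TestPresso:
    def test_consistency_when_no_outliers(self, rng):
        bx = rng.uniform(0.05, 0.2, 15)
        by = 0.3 * bx + rng.normal(0, 0.01, 15)
        h = make_harmonized(bx, np.full(15, 0.005), by, np.full(15, 0.01))
        res = mr_presso(h, n_sim=300, seed=0)
        if not res.outliers:
            assert res.corrected.beta == pytest.approx(res.uncorrected.beta)

    def test_planted_outlier_flagged_and_corrected(self):
        flagged = 0
        err_unc, err_cor = [], []
        n_rep = 20
        for s in range(n_rep):
            g = np.random.default_rng(s)
            bx = g.uniform(0.05, 0.2, 20)
            sy = np.full(20, 0.01)
            by = 0.3 * bx + g.normal(0, sy)
            by[0] += 10 * sy[0]
            h = make_harmonized(bx, np.full(20, 0.005), by, sy)
            res = mr_presso(h, n_sim=400, seed=s)
            flagged += "rs0" in res.outliers
            err_unc.append(abs(res.uncorrected.beta - 0.3))
            err_cor.append(abs(res.corrected.beta - 0.3))
        assert flagged >= 19
        # removing the planted outlier shrinks the error on aggregate
        assert np.mean(err_cor) < np.mean(err_unc)

    def test_minimum_snp_count(self):
        h = make_harmonized([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.01] * 3)
        with pytest.raises(ValueError):
            mr_presso(h)


class TestSteiger:
    def test_dominant_exposure_variance_retained(self):
        # strong instrument for the exposure, weak for the outcome
        h = make_harmonized([0.1], [0.005], [0.01], [0.008],
                            n_exp=1e5, n_out=1e5)
        filtered, flags = steiger_filter(h)
        assert flags["direction"].iloc[0] == "forward"
        assert len(filtered) == 1

    def test_exact_tie_dropped(self):
        h = make_harmonized([0.1], [0.01], [0.1], [0.01],
                            n_exp=5e4, n_out=5e4)
        filtered, flags = steiger_filter(h)
        assert flags["direction"].iloc[0] == "indeterminate"
        assert len(filtered) == 0

    def test_reverse_causal_simulation_flagged(self):
        wrong = 0
        total = 0
        for s in range(10):
            # SNPs act on the 'outcome' trait; analysis assumes forward
            cfg = synthetic.SumStatsSimConfig(
                n_snps=40, theta_xm=0.0, theta_my=0.0, theta_xy_direct=0.0,
                n_exposure=50_000, n_outcome=50_000, seed=s)
            out_s, _, _ = synthetic.generate_sumstats(cfg)
            exp_s = out_s.copy()
            # forward trait has no true signal: resimulate noise-only betas
            g = np.random.default_rng(1000 + s)
            exp_s["beta"] = g.normal(0, exp_s["se"])
            h = harmonize(out_s, out_s.assign(beta=exp_s["beta"]))
            # here "exposure" carries the true effects reversed
            h.table[["beta_exp", "beta_out"]] = \
                h.table[["beta_out", "beta_exp"]].to_numpy()
            filtered, flags = steiger_filter(h)
            wrong += (flags["direction"] == "reverse").sum()
            total += len(flags)
        assert wrong / total > 0.5


class TestMvmr:
    def test_null_second_exposure_matches_univariable(self, rng):
        k = 20
        bx = rng.uniform(0.05, 0.2, k)
        sy = np.full(k, 0.01)
        by = 0.3 * bx + rng.normal(0, sy)
        h = make_harmonized(bx, np.full(k, 0.005), by, sy)
        uni = ivw(h).beta
        X = pd.DataFrame({"e1": bx, "e2": np.zeros(k)})
        mv = mvmr_ivw(X, by, sy)
        assert mv.set_index("exposure").loc["e1", "beta"] == \
            pytest.approx(uni, abs=1e-10)

    def test_duplicated_exposure_collinear(self, rng):
        bx = rng.uniform(0.05, 0.2, 10)
        X = pd.DataFrame({"e1": bx, "e2": bx})
        with pytest.raises(ValueError, match="collinear"):
            mvmr_ivw(X, bx * 0.3, np.full(10, 0.01))

    def test_conditional_effect_recovery(self, rng):
        # truth: (0.3, 0.0) conditional effects
        ests = []
        for s in range(20):
            g = np.random.default_rng(s)
            k = 40
            b1 = g.normal(0, 0.1, k)
            b2 = g.normal(0, 0.1, k)
            sy = np.full(k, 0.01)
            by = 0.3 * b1 + 0.0 * b2 + g.normal(0, sy)
            mv = mvmr_ivw(pd.DataFrame({"e1": b1, "e2": b2}), by, sy)
            ests.append(mv.set_index("exposure")["beta"])
        M = pd.DataFrame(ests).mean()
        assert M["e1"] == pytest.approx(0.3, abs=0.01)
        assert M["e2"] == pytest.approx(0.0, abs=0.01)


class TestMediationMr:
    def _est(self, beta, se):
        return MrEstimate("ivw", beta, se, beta - 2 * se, beta + 2 * se,
                          0.01, 10)

    def test_difference_arithmetic(self):
        diff, prod = mediation_mr(self._est(0.3, 0.05), self._est(0.2, 0.05),
                                  self._est(0.0, 0.01), self._est(0.5, 0.1))
        assert diff.indirect == pytest.approx(0.1)
        assert diff.proportion_mediated == pytest.approx(1 / 3)
        assert prod.indirect == 0.0  # beta_xm = 0

    def test_product_delta_se(self):
        _, prod = mediation_mr(self._est(0.3, 0.05), self._est(0.2, 0.05),
                               self._est(0.2, 0.05), self._est(0.5, 0.1))
        expected = np.sqrt(0.2**2 * 0.1**2 + 0.5**2 * 0.05**2)
        assert prod.indirect == pytest.approx(0.1)
        assert prod.indirect_se == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.0320, abs=2e-4)

    def test_zero_total_undefined_proportion(self):
        diff, prod = mediation_mr(self._est(0.0, 0.05), self._est(0.0, 0.05),
                                  self._est(0.2, 0.05), self._est(0.5, 0.1))
        assert diff.proportion_mediated is None
        assert prod.proportion_mediated is None


class TestEndToEnd:
    def test_no_pleiotropy_estimators_agree(self):
        betas = {"ivw": [], "mr_egger": [], "weighted_median": [],
                 "weighted_mode": []}
        for s in range(10):
            cfg = synthetic.SumStatsSimConfig(
                n_snps=60, theta_xy_direct=0.2, h2_mediator=0.0, seed=s)
            e, _, o = synthetic.generate_sumstats(cfg)
            res = run_univariable(e, o, seed=s)
            for est in res["estimates"]:
                betas[est.method].append(est.beta)
        means = {k: np.mean(v) for k, v in betas.items()}
        mc = {k: np.std(v) / np.sqrt(len(v)) for k, v in betas.items()}
        for k in means:
            assert abs(means[k] - means["ivw"]) <= 3 * (mc[k] + mc["ivw"])

    def test_directional_pleiotropy_median_robust_ivw_biased(self):
        ivws, medians = [], []
        for s in range(15):
            cfg = synthetic.SumStatsSimConfig(
                n_snps=60, theta_xy_direct=0.2, pleiotropy_frac=0.3,
                pleiotropy_mean=0.02, pleiotropy_sd=0.005,
                h2_mediator=0.0, seed=s)
            e, _, o = synthetic.generate_sumstats(cfg)
            h = harmonize(select_instruments(e), o)
            ivws.append(ivw(h).beta)
            medians.append(weighted_median(h, seed=s).beta)
        ivw_bias = np.mean(ivws) - 0.2
        med_bias = abs(np.mean(medians) - 0.2)
        assert ivw_bias > 0.04  # visibly biased upward
        # robustness ordering: the weighted median absorbs most of the
        # directional pleiotropy that IVW passes straight through
        assert med_bias < ivw_bias / 2

    def test_reverse_direction_centers_on_zero(self):
        # purely forward model X -> Y.  The outcome also has its own
        # variants (panel B) with no effect on X; the reverse run selects
        # instruments from the Y statistics independently and, after
        # Steiger filtering removes the X-first variants, the reverse
        # effect is centred on zero.
        revs = []
        for s in range(10):
            cfg_a = synthetic.SumStatsSimConfig(
                n_snps=40, theta_xy_direct=0.3, h2_mediator=0.0, seed=s)
            ea, _, oa = synthetic.generate_sumstats(cfg_a)
            cfg_b = synthetic.SumStatsSimConfig(
                n_snps=40, theta_xy_direct=0.0, h2_mediator=0.0,
                seed=s + 500)
            eb, _, ob = synthetic.generate_sumstats(cfg_b)
            for t in (eb, ob):
                t["snp"] = t["snp"].str.replace("rs", "rb")
                t["pos"] = t["pos"] + 7_000_000
            y_stats = pd.concat([oa, eb], ignore_index=True)
            x_stats = pd.concat([ea, ob], ignore_index=True)
            res = run_univariable(y_stats, x_stats, p_threshold=5e-8,
                                  seed=s)
            if res["status"] == "ok" and "ivw_steiger" in res:
                revs.append(res["ivw_steiger"].beta)
        assert len(revs) >= 8
        mc = np.std(revs) / np.sqrt(len(revs))
        assert abs(np.mean(revs)) <= 3 * mc + 0.02

    def test_run_mvmr_separates_paths(self):
        dirs = []
        for s in range(10):
            cfg = synthetic.SumStatsSimConfig(
                n_snps=50, theta_xm=0.3, theta_my=0.4, theta_xy_direct=0.1,
                n_mediator=200_000, seed=s)
            e, m, o = synthetic.generate_sumstats(cfg)
            mv = run_mvmr(o, {"exp": e, "med": m},
                          {"exp": 5e-8, "med": 5e-6}).set_index("exposure")
            dirs.append(mv.loc["exp", "beta"])
        mc = np.std(dirs) / np.sqrt(len(dirs))
        assert abs(np.mean(dirs) - 0.1) <= max(2 * mc, 0.01)
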