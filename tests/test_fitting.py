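"""Tests for the saturation / dissociation / retardation fitting pipeline."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tandemsite.errors import FitError, ValidationError
from tandemsite.fitting import (
    analyze_dissociation_experiment,
    fit_allosteric,
    fit_dissociation,
    fit_saturation,
    normalize_timecourse,
    run_pipeline,
)
from tandemsite.synthetic_data import (
    TABLE_PRESETS,
    AssayDesign,
    gen_dissociation_series,
    gen_saturation,
)


def saturation_frame(pk_d=9.43, bmax=1000.0, concs=None, scale=1.0):
    kd = 10.0 ** -pk_d
    x = np.asarray(concs if concs is not None
                   else np.geomspace(32e-12, 1e-9, 8))
    return pd.DataFrame({
        "conc_tracer_M": x,
        "specific_binding": scale * bmax * x / (kd + x),
    })


def decay_frame(times, rates, amplitudes):
    y = np.zeros(len(times))
    for a, k in zip(amplitudes, rates):
        y = y + a * np.exp(-k * np.asarray(times))
    return pd.DataFrame({"time_min": times, "bound_pct": y})


class TestFitSaturation:
    def test_noise_free_recovery_is_exact(self):
        fit = fit_saturation(saturation_frame(pk_d=9.43))
        assert fit.pK_D == pytest.approx(9.43, abs=1e-6)
        assert fit.B_MAX == pytest.approx(1000.0, rel=1e-6)
        assert fit.identifiable

    def test_scale_equivariance(self):
        a = fit_saturation(saturation_frame())
        b = fit_saturation(saturation_frame(scale=2.0))
        assert b.B_MAX == pytest.approx(2.0 * a.B_MAX, rel=1e-8)
        assert b.pK_D == pytest.approx(a.pK_D, abs=1e-8)

    def test_top_plateau_only_flagged_unidentifiable(self):
        # all concentrations far above K_D: K_D cannot be resolved and the
        # standard error blows up
        rng = np.random.default_rng(0)
        df = saturation_frame(pk_d=9.43,
                              concs=np.geomspace(1e-6, 1e-5, 8))
        df["specific_binding"] *= 1 + 0.01 * rng.standard_normal(len(df))
        fit = fit_saturation(df)
        assert not fit.identifiable

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(FitError):
            df = saturation_frame()
            df["specific_binding"] = 0.0
            fit_saturation(df)
        with pytest.raises(ValidationError):
            fit_saturation(saturation_frame(concs=[1e-9, 2e-9, 3e-9]))
        with pytest.raises(ValidationError):
            fit_saturation(pd.DataFrame({"conc_tracer_M": [1e-9] * 5}))

    def test_nonspecific_subtraction_path(self, m2_truth):
        design = AssayDesign(noise_cv=0.0, n_experiments=1, rng_seed=0)
        df = gen_saturation(m2_truth, design)
        fit = fit_saturation(df)
        assert fit.pK_D == pytest.approx(m2_truth.pK_D, abs=1e-6)


class TestFitDissociation:
    times = np.linspace(0, 25, 10)

    def test_mono_noise_free(self):
        fit = fit_dissociation(decay_frame(self.times, [0.27], [100.0]))
        assert fit.model == "mono"
        assert fit.selected_rate == pytest.approx(0.27, abs=1e-8)

    def test_bi_selects_slower_phase(self):
        tc = decay_frame(np.linspace(0, 60, 15), [0.5, 0.05], [50.0, 50.0])
        fit = fit_dissociation(tc)
        assert fit.model == "bi"
        assert fit.selected_rate == pytest.approx(0.05, rel=1e-4)
        assert fit.f == pytest.approx(50.0, abs=0.01)

    def test_constant_signal_flagged_no_dissociation(self):
        tc = pd.DataFrame({"time_min": self.times,
                           "bound_pct": np.full(len(self.times), 100.0)})
        fit = fit_dissociation(tc)
        assert fit.no_dissociation
        assert fit.selected_rate <= 2e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_dissociation(decay_frame([0, 1, 2, 3], [0.3], [100.0]))

    @given(k1=st.floats(0.2, 2.0), ratio=st.floats(5.0, 50.0),
           f=st.floats(20.0, 80.0))
    @settings(max_examples=25, deadline=None)
    def test_slower_phase_rule_never_violated(self, k1, ratio, f):
        k2 = k1 / ratio
        t = np.linspace(0, 4.0 / k2, 12)
        fit = fit_dissociation(decay_frame(t, [k1, k2], [100 - f, f]))
        rates = [fit.k_off] + ([fit.k_off2] if fit.k_off2 else [])
        assert fit.selected_rate <= min(rates) + 1e-12


class TestFitAllosteric:
    def kobs_frame(self, truth, concs=None, include_zero=True):
        x = np.asarray(concs if concs is not None
                       else np.geomspace(1e-5, 1e-2, 7))
        if include_zero:
            x = np.concatenate([[0.0], x])
        return pd.DataFrame({"conc_competitor_M": x,
                             "k_obs": [truth.k_obs(c) for c in x]})

    def test_noise_free_eq4_recovery(self):
        truth = TABLE_PRESETS["M3_wt"]
        fit = fit_allosteric(self.kobs_frame(truth), slope_model="eq4")
        assert fit.pK_A == pytest.approx(3.25, abs=1e-6)
        assert fit.k_0 == pytest.approx(truth.k_off, rel=1e-6)

    def test_steep_data_needs_slope_factor(self):
        # generated with nH = 1.5: eq4 misfits systematically, eq5 recovers
        truth = TABLE_PRESETS["M2_wt"]
        table = self.kobs_frame(truth)
        eq4 = fit_allosteric(table, slope_model="eq4")
        eq5 = fit_allosteric(table, slope_model="eq5")
        assert eq5.rss < 0.01 * eq4.rss
        assert eq5.nH == pytest.approx(1.5, abs=1e-4)
        auto = fit_allosteric(table, slope_model="auto")
        assert auto.slope_model == "eq5"

    def test_auto_keeps_simple_model_on_unit_slope_data(self):
        truth = TABLE_PRESETS["M3_wt"]
        fit = fit_allosteric(self.kobs_frame(truth), slope_model="auto")
        assert fit.slope_model == "eq4"
        assert fit.pK_A == pytest.approx(3.25, abs=1e-6)

    def test_half_rate_at_k_a(self):
        truth = TABLE_PRESETS["M3_wt"]
        fit = fit_allosteric(self.kobs_frame(truth), slope_model="eq4")
        assert truth.k_obs(fit.K_A) == pytest.approx(fit.k_0 / 2.0, rel=1e-6)

    def test_fix_k0_option(self):
        truth = TABLE_PRESETS["M3_wt"]
        fit = fit_allosteric(self.kobs_frame(truth, include_zero=False),
                             slope_model="eq4", fix_k_0=truth.k_off)
        assert fit.k_0 == truth.k_off
        assert fit.pK_A == pytest.approx(3.25, abs=1e-6)

    def test_flat_kobs_warns_unbounded(self):
        x = np.geomspace(1e-5, 1e-2, 7)
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "conc_competitor_M": x,
            "k_obs": 0.27 * (1 + 0.01 * rng.standard_normal(len(x)))})
        with pytest.warns(UserWarning, match="unbounded"):
            fit = fit_allosteric(table, slope_model="eq4")
        assert fit.unbounded_K_A

    def test_insufficient_span_rejected(self):
        truth = TABLE_PRESETS["M3_wt"]
        with pytest.raises(ValidationError):
            fit_allosteric(self.kobs_frame(truth, concs=[1e-5, 2e-5, 3e-5,
                                                         4e-5]))


class TestPipeline:
    def _experiments(self, name, seed, n=4, noise=0.03):
        truth = TABLE_PRESETS[name]
        design = AssayDesign(n_experiments=n, noise_cv=noise, rng_seed=seed)
        return gen_dissociation_series(truth, design)

    def test_identical_noise_free_experiments_have_zero_sem(self):
        truth = TABLE_PRESETS["M3_wt"]
        design = AssayDesign(n_experiments=1, noise_cv=0.0, rng_seed=0)
        one = gen_dissociation_series(truth, design)
        stacked = pd.concat(
            [one.assign(experiment_id=i) for i in range(4)],
            ignore_index=True)
        summary = run_pipeline({"wt": stacked, "wt2": stacked.copy()},
                               reference="wt")
        assert summary.table.loc["wt", "pK_A_sem"] == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_wt_vs_wt_not_significant(self):
        a = self._experiments("M2_wt", seed=1)
        b = self._experiments("M2_wt", seed=2)
        summary = run_pipeline({"wt": a, "wt_again": b}, reference="wt")
        assert not summary.comparisons["significant"].any()

    def test_wt_vs_n419a_pk_a_flagged_significant(self):
        # the N419A vestibule mutant has ~3x lower allosteric affinity;
        # Dunnett's many-to-one comparison must flag pK_A (and the faster
        # k_off) against wild type
        a = self._experiments("M2_wt", seed=3)
        b = self._experiments("M2_N419A", seed=4)
        summary = run_pipeline({"M2_wt": a, "M2_N419A": b},
                               reference="M2_wt")
        row = summary.comparisons.set_index(["condition", "parameter"])
        assert row.loc[("M2_N419A", "pK_A"), "significant"]

    def test_mixed_designs_rejected(self):
        a = self._experiments("M2_wt", seed=5, n=2)
        bad = a[~((a["experiment_id"] == 1)
                  & (a["conc_competitor_M"] == 1e-5))]
        with pytest.raises(ValidationError, match="mixed"):
            run_pipeline({"wt": bad, "other": a}, reference="wt")

    def test_missing_reference_rejected(self):
        a = self._experiments("M2_wt", seed=6, n=2)
        with pytest.raises(ValidationError):
            run_pipeline({"wt": a}, reference="nope")

    def test_saturation_branch_adds_pk_d(self):
        truth = TABLE_PRESETS["M2_wt"]
        diss = self._experiments("M2_wt", seed=7, n=2)
        sat = gen_saturation(truth, AssayDesign(n_experiments=2, rng_seed=8))
        summary = run_pipeline({"wt": diss, "wt2": diss.copy()},
                               reference="wt",
                               saturation_experiments={"wt": sat})
        assert summary.table.loc["wt", "pK_D_mean"] == pytest.approx(
            truth.pK_D, abs=0.05)


class TestRecoveryStatistics:
    def test_pk_a_recovery_median_and_coverage(self):
        # repeated wild-type M2 experiments at the standard design: the
        # median recovered pK_A stays within 0.05 of truth and the
        # +/- 2 SEM interval covers the truth in >= 90% of replications
        truth = TABLE_PRESETS["M2_wt"]
        medians, covered = [], 0
        n_rep = 40
        for rep in range(n_rep):
            design = AssayDesign(rng_seed=10_000 + rep)
            df = gen_dissociation_series(truth, design)
            pkas = [analyze_dissociation_experiment(g)["allosteric"].pK_A
                    for _, g in df.groupby("experiment_id")]
            m, sem = np.mean(pkas), np.std(pkas, ddof=1) / math.sqrt(len(pkas))
            medians.append(m)
            if abs(m - truth.pK_A) <= 2 * sem:
                covered += 1
        assert abs(np.median(medians) - truth.pK_A) < 0.05
        assert covered / n_rep >= 0.9
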