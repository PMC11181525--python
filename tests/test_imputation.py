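import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survimpute.aftmodel import fit_weibull_aft
from survimpute.imputation import (
    ImputationConfig,
    complete_case,
    fcs_impute,
    impute,
    low_prevalence_fill,
    mode_impute,
    outcome_representation,
)
from survimpute.roster import CategoricalSpec
from survimpute.synthcohort import (
    MissingnessSpec,
    VariableMissingness,
    apply_missingness,
    default_female_config,
    generate_cohort,
)

from conftest import make_surv_frame


def _cond_roster():
    return [
        CategoricalSpec(
            name="income", levels=("Q1", "Q2"), probs=(0.5, 0.5), kind="ordinal"
        ),
        CategoricalSpec(
            name="copd",
            levels=("No", "Yes"),
            probs=(0.98, 0.02),
            kind="binary",
            is_condition=True,
            absent_level="No",
        ),
    ]


class TestCompleteCase:
    def test_counting(self, surv_frame_factory):
        frame = surv_frame_factory(
            [1, 2, 3, 4, 5], [0, 1, 0, 0, 0],
            income=["Q1", None, "Q2", "Q1", "Q2"],
        )
        out = complete_case(frame, ["income"])
        assert len(out.datasets[0]) == 4
        assert out.method == "complete_case"

    def test_complete_cohort_identity(self, female_cohort_small, female_cfg_small):
        preds = ["age"] + list(female_cfg_small.predictor_names)
        out = complete_case(female_cohort_small, preds)
        pd.testing.assert_frame_equal(out.datasets[0], female_cohort_small)

    def test_all_missing_rejected(self, surv_frame_factory):
        frame = surv_frame_factory([1, 2], [1, 0], income=[None, None])
        with pytest.raises(ValueError):
            complete_case(frame, ["income"])

    def test_retained_fraction_order_of_magnitude(self, punctured_20k, female_cfg_20k):
        # per-variable rates mirror the published per-variable missingness;
        # with independent mechanisms the retained share lands near ~0.78
        cohort, _ = punctured_20k
        preds = ["age"] + list(female_cfg_20k.predictor_names)
        out = complete_case(cohort, preds)
        retained = len(out.datasets[0]) / len(cohort)
        assert 0.72 <= retained <= 0.90

    def test_weights_time_event_untouched(self, punctured_20k):
        cohort, _ = punctured_20k
        out = complete_case(cohort, ["income"])
        ds = out.datasets[0]
        kept = cohort.loc[ds.index]
        pd.testing.assert_series_equal(ds["weight"], kept["weight"])
        pd.testing.assert_series_equal(ds["time"], kept["time"])
        pd.testing.assert_series_equal(ds["event"], kept["event"])


class TestModeImpute:
    def test_simple_mode(self, surv_frame_factory):
        frame = surv_frame_factory(
            [1, 2, 3, 4], [0] * 4, income=["Q1", "Q1", "Q2", None]
        )
        roster = [_cond_roster()[0]]
        out = mode_impute(frame, roster, strata=())
        assert out.datasets[0].loc[3, "income"] == "Q1"
        assert out.masks[0].loc[3, "income"]

    def test_tie_broken_by_roster_order(self, surv_frame_factory):
        frame = surv_frame_factory([1, 2, 3], [0] * 3, income=["Q2", "Q1", None])
        roster = [_cond_roster()[0]]
        out = mode_impute(frame, roster, strata=())
        assert out.datasets[0].loc[2, "income"] == "Q1"  # first roster label wins

    def test_two_strata_counting_oracle(self, surv_frame_factory):
        rng = np.random.default_rng(0)
        n = 400
        cycle = rng.integers(1, 3, size=n)
        income = rng.choice(["Q1", "Q2"], size=n, p=[0.5, 0.5]).astype(object)
        miss = rng.uniform(size=n) < 0.2
        income[miss] = None
        frame = make_surv_frame(np.ones(n), np.zeros(n, int), income=income)
        frame["cycle"] = cycle
        roster = [_cond_roster()[0]]
        out = mode_impute(frame, roster, strata=("cycle",))
        ds = out.datasets[0]
        for c in (1, 2):
            sub = frame[frame["cycle"] == c]
            observed = sub["income"].dropna()
            counts = observed.value_counts()
            best = counts.max()
            mode = next(l for l in ("Q1", "Q2") if counts.get(l, 0) == best)
            imputed = ds.loc[(frame["cycle"] == c) & miss, "income"]
            assert (imputed == mode).all()

    def test_empty_stratum_needs_fallback(self, surv_frame_factory):
        frame = surv_frame_factory([1, 2, 3, 4], [0] * 4,
                                   income=[None, None, "Q2", "Q2"])
        frame["cycle"] = [1, 1, 2, 2]
        roster = [_cond_roster()[0]]
        with pytest.raises(ValueError):
            mode_impute(frame, roster, strata=("cycle",))
        out = mode_impute(
            frame, roster, strata=("cycle",), fallback_strata={"income": ((2,),)}
        )
        assert (out.datasets[0]["income"] == ["Q2", "Q2", "Q2", "Q2"]).all()


class TestLowPrevalenceFill:
    def test_below_threshold_filled(self, surv_frame_factory):
        n = 1000
        copd = np.array(["No"] * n, dtype=object)
        copd[:5] = None  # 0.5% missing
        frame = make_surv_frame(np.ones(n), np.zeros(n, int), copd=copd)
        out, filled = low_prevalence_fill(frame, _cond_roster(), threshold=0.01)
        assert filled == ["copd"]
        assert (out["copd"] == "No").all()

    def test_above_threshold_untouched(self, surv_frame_factory):
        n = 100
        copd = np.array(["No"] * n, dtype=object)
        copd[:2] = None  # 2%
        frame = make_surv_frame(np.ones(n), np.zeros(n, int), copd=copd)
        out, filled = low_prevalence_fill(frame, _cond_roster(), threshold=0.01)
        assert filled == []
        assert out["copd"].isna().sum() == 2

    def test_zero_threshold_fills_nothing(self, surv_frame_factory):
        n = 100
        copd = np.array(["No"] * n, dtype=object)
        copd[0] = None
        frame = make_surv_frame(np.ones(n), np.zeros(n, int), copd=copd)
        out, filled = low_prevalence_fill(frame, _cond_roster(), threshold=0.0)
        assert filled == []

    def test_non_condition_variables_never_filled(self, surv_frame_factory):
        n = 1000
        income = np.array(["Q1"] * n, dtype=object)
        income[:5] = None  # 0.5% missing but not a condition variable
        frame = make_surv_frame(
            np.ones(n), np.zeros(n, int), income=income, copd=["No"] * n
        )
        out, filled = low_prevalence_fill(frame, _cond_roster(), threshold=0.01)
        assert filled == []
        assert out["income"].isna().sum() == 5


class TestOutcomeRepresentation:
    def test_event_row(self, surv_frame_factory):
        frame = surv_frame_factory([2.5], [1])
        rep = outcome_representation(frame)
        assert rep.loc[0, "event"] == 1.0
        assert rep.loc[0, "log_time"] == pytest.approx(np.log(2.5))

    def test_censored_row(self, surv_frame_factory):
        frame = surv_frame_factory([5.0], [0])
        rep = outcome_representation(frame)
        assert rep.loc[0, "event"] == 0.0
        assert rep.loc[0, "log_time"] == pytest.approx(np.log(5.0))

    def test_nonpositive_time_rejected(self, surv_frame_factory):
        frame = surv_frame_factory([0.0], [1])
        with pytest.raises(ValueError):
            outcome_representation(frame)

    def test_outcome_in_models_reduces_scale_bias(self):
        # MAR-on-outcome: dropping the outcome from the conditionals pushes the
        # downstream fitted scale away from the full-data fit
        bias = {True: [], False: []}
        for seed in range(200, 205):
            cfg = default_female_config(n=20_000, seed=seed)
            coh = generate_cohort(cfg)
            spec = MissingnessSpec(
                variables={
                    "health": VariableMissingness("MAR", 0.40, ("event",), (3.0,))
                },
                seed=seed,
            )
            pun, _ = apply_missingness(coh, spec)
            preds = ["age"] + list(cfg.predictor_names)
            sigma_full = fit_weibull_aft(coh, preds, cfg.roster).sigma
            for inc in (True, False):
                icfg = ImputationConfig(
                    method="fcs_single", m=1, include_outcome=inc, seed=seed
                )
                ds = impute(pun, list(cfg.roster), icfg, preds).datasets[0]
                sigma = fit_weibull_aft(ds, preds, cfg.roster).sigma
                bias[inc].append(abs(sigma - sigma_full))
        assert np.mean(bias[False]) > np.mean(bias[True])


class TestFCS:
    def test_identity_on_complete(self, female_cohort_small, female_cfg_small):
        roster = list(female_cfg_small.roster)
        cfg = ImputationConfig(method="fcs_multiple", m=3, seed=1)
        out = fcs_impute(female_cohort_small, roster, cfg)
        assert out.m == 3
        for ds in out.datasets:
            for spec in roster:
                assert (
                    ds[spec.name].astype(str)
                    == female_cohort_small[spec.name].astype(str)
                ).all()

    def test_m_datasets_preserve_observed(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:6000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        cfg = ImputationConfig(method="fcs_multiple", m=5, n_burnin=2, seed=2)
        out = impute(sub, roster, cfg)
        assert out.m == 5
        for ds in out.datasets:
            assert ds[[s.name for s in roster]].isna().sum().sum() == 0
            for spec in roster:
                obs = ~sub[spec.name].isna()
                assert (
                    ds.loc[obs, spec.name].astype(str)
                    == sub.loc[obs, spec.name].astype(str)
                ).all()

    def test_chains_differ(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:5000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        cfg = ImputationConfig(method="fcs_multiple", m=2, n_burnin=2, seed=3)
        out = impute(sub, roster, cfg)
        d1, d2 = out.datasets
        assert (d1["income"].astype(str) != d2["income"].astype(str)).any()

    def test_no_novel_labels(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:5000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        out = impute(sub, roster, ImputationConfig(method="fcs_single", n_burnin=2, seed=4))
        for spec in roster:
            got = set(out.datasets[0][spec.name].astype(str).unique())
            assert got <= set(spec.levels)

    def test_determinism(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:4000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        cfg = ImputationConfig(method="fcs_single", n_burnin=2, seed=5)
        d1 = impute(sub, roster, cfg).datasets[0]
        d2 = impute(sub, roster, cfg).datasets[0]
        pd.testing.assert_frame_equal(d1, d2)

    def test_mcar_marginal_matching(self):
        # pooled over seeds, imputed-cell distribution of an MCAR variable
        # must match the observed-cell distribution (chi-square GOF)
        pooled_imputed = None
        expected_probs = None
        for seed in range(5):
            cfg = default_female_config(n=6000, seed=300 + seed)
            coh = generate_cohort(cfg)
            spec = MissingnessSpec(
                variables={"income": VariableMissingness("MCAR", 0.10)},
                seed=300 + seed,
            )
            pun, mask = apply_missingness(coh, spec)
            roster = list(cfg.roster)
            out = impute(
                pun, roster, ImputationConfig(method="fcs_single", n_burnin=3, seed=seed)
            )
            ds = out.datasets[0]
            imp_vals = ds.loc[mask["income"], "income"].astype(str)
            obs_vals = pun["income"].dropna().astype(str)
            counts = imp_vals.value_counts()
            probs = obs_vals.value_counts(normalize=True)
            levels = [l for l in roster[0].levels]
            c = np.array([counts.get(l, 0) for l in levels], float)
            p = np.array([probs.get(l, 0) for l in levels], float)
            pooled_imputed = c if pooled_imputed is None else pooled_imputed + c
            expected_probs = p if expected_probs is None else expected_probs + p
        expected_probs /= 5.0
        stat = stats.chisquare(pooled_imputed, pooled_imputed.sum() * expected_probs)
        assert stat.pvalue > 0.001

    def test_stratum_leakage_control(self, monkeypatch):
        # instrument the conditional-model fit: every training row must come
        # from the stratum being imputed
        import survimpute.imputation as imp_mod
        from survimpute._multinomial import RidgeMultinomial

        cfg = default_female_config(n=4000, seed=6, n_cycles=2)
        coh = generate_cohort(cfg)
        spec = MissingnessSpec(
            variables={"income": VariableMissingness("MCAR", 0.15)}, seed=6
        )
        pun, _ = apply_missingness(coh, spec)
        seen_sizes = []
        orig_fit = RidgeMultinomial.fit

        def spy(self, X, y, warm_start=None, sample_weight=None):
            seen_sizes.append(len(y))
            return orig_fit(self, X, y, warm_start=warm_start,
                            sample_weight=sample_weight)

        monkeypatch.setattr(RidgeMultinomial, "fit", spy)
        impute(
            pun,
            list(cfg.roster),
            ImputationConfig(method="fcs_single", n_burnin=2, seed=6),
        )
        # strata are sex x cycle (2 strata of ~2000): no fit may see more rows
        # than the largest stratum's observed subset
        per_stratum = pun.groupby(["sex", "cycle"], observed=True).size().max()
        assert seen_sizes and max(seen_sizes) <= per_stratum

    def test_fallback_strata_for_unobserved_variable(self):
        # variable entirely missing in cycle 1 (as for early-cycle questions):
        # imputed from designated fallback cycles
        cfg = default_female_config(n=6000, seed=8, n_cycles=3)
        coh = generate_cohort(cfg)
        pun = coh.copy()
        c1 = pun["cycle"] == 1
        pun["phys_act"] = pun["phys_act"].astype(object)
        pun.loc[c1, "phys_act"] = None
        icfg = ImputationConfig(
            method="fcs_single",
            n_burnin=2,
            fallback_strata={"phys_act": (("female", 2), ("female", 3))},
            seed=8,
        )
        out = impute(pun, list(cfg.roster), icfg)
        ds = out.datasets[0]
        assert ds["phys_act"].isna().sum() == 0
        got = set(ds.loc[c1.to_numpy(), "phys_act"].astype(str).unique())
        assert got <= {"Active", "Moderate", "Inactive"}


    def test_weighted_conditionals_run_complete(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:4000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        cfg = ImputationConfig(method="fcs_single", n_burnin=2, use_weights=True, seed=12)
        out = impute(sub, roster, cfg)
        assert out.datasets[0][[s.name for s in roster]].isna().sum().sum() == 0


class TestDispatch:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ImputationConfig(method="hotdeck")

    def test_single_is_m1(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:3000].reset_index(drop=True)
        out = impute(
            sub,
            list(female_cfg_20k.roster),
            ImputationConfig(method="fcs_single", m=5, n_burnin=2, seed=9),
        )
        assert out.m == 1
        assert out.method == "fcs_single"

    def test_provenance_mask_matches_original_missingness(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:3000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        out = impute(sub, roster, ImputationConfig(method="fcs_single", n_burnin=2, seed=10))
        expected = sub[[s.name for s in roster]].isna()
        pd.testing.assert_frame_equal(out.masks[0], expected)

    def test_low_prevalence_fill_recorded(self, punctured_20k, female_cfg_20k):
        cohort, _ = punctured_20k
        sub = cohort.iloc[:10_000].reset_index(drop=True)
        roster = list(female_cfg_20k.roster)
        out = impute(sub, roster, ImputationConfig(method="fcs_single", n_burnin=2, seed=11))
        # chronic conditions carry ~0.1% missingness -> deterministic fill
        assert any(v in out.filled_variables for v in
                   ("copd", "heart_disease", "diabetes", "cancer", "stroke"))
        for v in out.filled_variables:
            assert out.model_types[v] == "low_prevalence_fill"
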