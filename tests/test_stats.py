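"""Mixed-model, hazard and survival-stage contracts."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import timetopo as tt


def null_dataset(seed, n_patients=20, patient_sd=0.5, noise_sd=0.3):
    """Two AOIs per patient, within-patient two-level group, no effect."""
    rng = np.random.default_rng(seed)
    patients = pd.Series(np.repeat([f"P{i}" for i in range(n_patients)], 2))
    groups = pd.Series(np.tile(["A", "B"], n_patients))
    y = np.exp(
        rng.normal(0, patient_sd, n_patients).repeat(2)
        + rng.normal(0, noise_sd, 2 * n_patients)
    )
    return pd.DataFrame({"M": y}), groups, patients


class TestLMMDifferential:
    def test_agrees_with_ols_when_no_patient_variance(self):
        rng = np.random.default_rng(0)
        n = 40
        x = np.tile([0.0, 1.0], n // 2)
        y = np.exp(1.0 + 0.8 * x + rng.normal(0, 0.2, n))
        values = pd.DataFrame({"M": y})
        groups = pd.Series(np.where(x == 0, "A", "B"))
        patients = pd.Series([f"P{i}" for i in range(n)])  # one AOI per patient
        res = tt.lmm_differential(values, groups, patients).iloc[0]
        ols = sm.OLS(np.log(y), sm.add_constant(x)).fit()
        assert res.coefficient == pytest.approx(ols.params[1], rel=1e-6)

    def test_single_group_rejected(self):
        values, groups, patients = null_dataset(1)
        with pytest.raises(ValueError, match="single group"):
            tt.lmm_differential(values, pd.Series(["A"] * len(groups)), patients)

    def test_null_type_one_error_calibrated(self):
        """Empirical rejection rate at alpha = 0.05 within [0.02, 0.09]."""
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            values, groups, patients = null_dataset(rep)
            res = tt.lmm_differential(values, groups, patients).iloc[0]
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_true_effect_marker_ranks_first(self):
        """A beta = 1 marker outranks ten null markers nearly always."""
        firsts = 0
        n_rep = 20
        for rep in range(n_rep):
            markers = ["HIT"] + [f"N{i}" for i in range(10)]
            cfg = tt.DSPSimConfig(
                markers=markers, fixed_effects={"B": {"HIT": 1.0}}, seed=rep
            )
            design = tt.make_design(20, rois_per_patient=(2, 2),
                                    segments=("tumor",), seed=rep, group_col="grp")
            m = tt.simulate_counts(cfg, design, group_col="grp")
            norm = tt.housekeeper_normalize(m)
            res = tt.lmm_differential(
                norm.counts[markers], norm.meta["grp"], norm.meta["patient_id"]
            )
            firsts += res.sort_values("p_value")["marker"].iloc[0] == "HIT"
        assert firsts / n_rep >= 0.9

    def test_pvalues_in_unit_interval_and_volcano_rows(self):
        values, groups, patients = null_dataset(3)
        values["M2"] = values["M"] * 2.0
        values["CONST"] = 1.0  # zero variance -> not converged
        res = tt.lmm_differential(values, groups, patients)
        conv = res[res.converged]
        assert ((conv.p_value > 0) & (conv.p_value <= 1)).all()
        assert not res[res.marker == "CONST"].converged.iloc[0]
        assert len(tt.volcano_table(res)) == res.converged.sum()


class TestLMMFeatureRegression:
    def test_slope_recovered_within_ci(self):
        from scipy import stats as sps

        cover = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n_pat = 20
            stage = rng.integers(1, 5, n_pat).astype(float)
            patients = pd.Series(np.repeat([f"P{i}" for i in range(n_pat)], 2))
            cov = pd.Series(np.repeat(stage, 2))
            y = np.exp(
                0.5 * cov.to_numpy()
                + rng.normal(0, 0.4, n_pat).repeat(2)
                + rng.normal(0, 0.2, 2 * n_pat)
            )
            res = tt.lmm_feature_regression(
                pd.DataFrame({"M": y}), cov, patients
            ).iloc[0]
            tcrit = sps.t.ppf(0.975, res.ddf)
            cover += abs(res.coefficient - 0.5) <= tcrit * res.se
        assert cover / n_rep >= 0.9

    def test_constant_covariate_rejected(self):
        values, _, patients = null_dataset(5)
        with pytest.raises(ValueError, match="single unique value"):
            tt.lmm_feature_regression(values, pd.Series([2.0] * len(patients)), patients)


def cox_simulation(beta, seed, n_patients=100, aois_per_patient=2):
    rng = np.random.default_rng(seed)
    x_pat = rng.normal(size=n_patients)
    hazard = 0.2 * np.exp(beta * x_pat)
    t = rng.exponential(1 / hazard)
    censor = 15.0
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_patients)],
            "pfs_years": np.minimum(t, censor),
            "pfs_event": (t <= censor).astype(int),
        }
    )
    patients = pd.Series(np.repeat(clinical.patient_id.to_numpy(), aois_per_patient))
    x_aoi = np.repeat(x_pat, aois_per_patient) + rng.normal(0, 0.3, len(patients))
    return clinical, pd.DataFrame({"F": x_aoi}), patients


class TestCoxScreen:
    def test_protective_covariate_recovered(self):
        clinical, values, patients = cox_simulation(np.log(0.5), seed=1)
        res = tt.coxme_screen(clinical, values, patients).iloc[0]
        assert res.coefficient < 0
        assert res.p_value < 0.05

    def test_null_type_one_error(self):
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            clinical, values, patients = cox_simulation(0.0, seed=300 + rep)
            rejections += tt.coxme_screen(clinical, values, patients).iloc[0].p_value < 0.05
        assert 0.01 <= rejections / n_rep <= 0.1

    def test_no_events_rejected(self):
        clinical, values, patients = cox_simulation(0.0, seed=2)
        clinical["pfs_event"] = 0
        with pytest.raises(ValueError, match="no events"):
            tt.coxme_screen(clinical, values, patients)

    def test_single_patient_rejected(self):
        clinical, values, patients = cox_simulation(0.0, seed=3, n_patients=1)
        with pytest.raises(ValueError, match="two patients"):
            tt.coxme_screen(clinical, values, patients)


class TestKaplanMeier:
    def test_identical_groups_give_logrank_p_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(5, 30)
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(60)],
                "consensus_label": ["diffuse"] * 30 + ["focal"] * 30,
                "pfs_years": np.r_[t, t],
                "pfs_event": 1,
            }
        )
        out = tt.km_compare(df)
        assert out["p_value"] == pytest.approx(1.0)

    def test_hazard_ratio_three_detected(self):
        """HR = 3, n = 60/60 uncensored: log-rank p < 0.01 in >= 95% of reps."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(700 + rep)
            df = pd.DataFrame(
                {
                    "patient_id": [f"P{i}" for i in range(120)],
                    "consensus_label": ["diffuse"] * 60 + ["focal"] * 60,
                    "pfs_years": np.r_[rng.exponential(3, 60), rng.exponential(1, 60)],
                    "pfs_event": 1,
                }
            )
            hits += tt.km_compare(df)["p_value"] < 0.01
        assert hits / n_rep >= 0.95

    def test_empty_group_dropped_with_warning(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P0", "P1", "P2", "P3"],
                "consensus_label": ["diffuse", "diffuse", "focal", "focal"],
                "pfs_years": [1.0, 2.0, 3.0, 4.0],
                "pfs_event": [1, 1, 1, 0],
            }
        )
        with pytest.warns(UserWarning, match="zero patients"):
            out = tt.km_compare(df, groups=("diffuse", "focal", "insignificant"))
        assert set(out["fits"]) == {"diffuse", "focal"}

    def test_all_censored_at_zero_rejected(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P0", "P1", "P2", "P3"],
                "consensus_label": ["diffuse", "diffuse", "focal", "focal"],
                "pfs_years": [0.0] * 4,
                "pfs_event": [0] * 4,
            }
        )
        with pytest.raises(ValueError, match="no events"):
            tt.km_compare(df)


class TestPresenceSurvivalCorrelation:
    def test_perfect_linear_relation(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        r, p = tt.presence_survival_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_independent_pairs_rarely_correlated(self):
        small = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            r, _ = tt.presence_survival_correlation(
                pd.Series(rng.normal(size=50)), pd.Series(rng.normal(size=50))
            )
            small += abs(r) < 0.3
        assert small / n_rep >= 0.9

    def test_constant_covariate_is_nan_with_warning(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            r, p = tt.presence_survival_correlation(
                pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0])
            )
        assert np.isnan(r) and any("constant" in str(x.message) for x in w)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="three patients"):
            tt.presence_survival_correlation(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))
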