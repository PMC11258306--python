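"""Differential expression and survival models for AOI-level protein data.

AOIs are repeated measures within patients (1-3 ROIs per tumor, up to two
segments per ROI), so every model here accounts for patient-level
dependence:

* :func:`lmm_differential` / :func:`lmm_feature_regression` — per-marker
  linear mixed models, ``log signal ~ fixed effect + (1 | patient)``, with a
  between-within denominator-df approximation for small-sample p-values;
* :func:`coxme_screen` — marginal proportional-hazards screen with
  patient-clustered robust variance (the sandwich analogue of a
  patient-frailty Cox model);
* :func:`km_compare` — per-patient Kaplan-Meier curves and log-rank test;
* :func:`presence_survival_correlation` — Pearson correlation between
  per-patient immune presence and survival time.

Raw p < 0.05 is the significance convention throughout; a
Benjamini-Hochberg column is emitted for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class LMMResult:
    marker: str
    coefficient: float
    se: float
    ddf: float
    p_value: float
    converged: bool
    n_obs: int
    n_patients: int


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = sm.stats.multipletests(p[ok], method="fdr_bh")[1]
    return out


def _between_within_ddf(x: np.ndarray, patients: np.ndarray, n_params: int) -> float:
    """Containment-type denominator df for a single tested covariate.

    If the covariate varies within any patient it is a within-cluster
    effect (ddf = N - n_patients - (n_params - 1)); otherwise it is a
    between-cluster effect (ddf = n_patients - n_params).
    """
    df = pd.DataFrame({"x": x, "p": patients})
    within = (df.groupby("p")["x"].nunique() > 1).any()
    n = len(x)
    n_pat = df["p"].nunique()
    if within:
        ddf = n - n_pat - (n_params - 1)
    else:
        ddf = n_pat - n_params
    return float(max(ddf, 1))


def _fit_one_lmm(y: np.ndarray, x: np.ndarray, patients: np.ndarray,
                 ddf_method: str) -> tuple[float, float, float, float, bool]:
    exog = sm.add_constant(x)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=patients)
        # lbfgs occasionally hits a singular profiled score; fall back to
        # gradient-free optimizers before declaring non-convergence
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except Exception:
                continue
    if fit is None:
        return np.nan, np.nan, np.nan, np.nan, False
    coef = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
        return coef, se, np.nan, np.nan, False
    if ddf_method == "z":
        ddf = np.inf
        p = 2 * sps.norm.sf(abs(coef / se))
    else:
        ddf = _between_within_ddf(x, patients, n_params=2)
        p = 2 * sps.t.sf(abs(coef / se), ddf)
    return coef, se, ddf, float(p), True


def _prepare_values(values: pd.DataFrame, log_transform: bool) -> pd.DataFrame:
    vals = values.astype(float)
    if log_transform:
        if (vals <= 0).any().any():
            raise ValueError("log transform requires strictly positive values")
        vals = np.log(vals)
    return vals


def lmm_differential(
    values: pd.DataFrame,
    groups: pd.Series,
    patients: pd.Series,
    log_transform: bool = True,
    ddf_method: str = "between-within",
) -> pd.DataFrame:
    """Per-marker LMM contrasting two groups with a patient random intercept.

    ``values`` is AOI x marker (normalized counts; log-transformed here by
    default), ``groups`` a two-level label per AOI, ``patients`` the patient
    id per AOI.  The returned table has one row per marker: coefficient
    (log-scale effect of the second level vs the first, levels sorted),
    p_value (t test on ``ddf_method`` denominator df), a BH-adjusted column
    for information, and a ``converged`` flag; non-converged or
    zero-variance markers carry NA p-values.
    """
    groups = pd.Series(groups).astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("single group: need two group levels to contrast")
    if len(levels) > 2:
        raise ValueError(
            f"{len(levels)} group levels; encode a binary contrast (e.g. one-vs-rest)"
        )
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs at least two AOIs")
    x = (groups == levels[1]).to_numpy(dtype=float)
    return _lmm_table(values, x, patients, log_transform, ddf_method,
                      contrast=f"{levels[1]} vs {levels[0]}")


def lmm_feature_regression(
    values: pd.DataFrame,
    covariate: pd.Series,
    patients: pd.Series,
    log_transform: bool = True,
    ddf_method: str = "between-within",
) -> pd.DataFrame:
    """Per-marker LMM on a numeric/ordinal covariate (stage 1-4, gdc, ...)."""
    x = pd.Series(covariate).astype(float)
    if x.isna().any():
        raise ValueError("covariate contains NA; drop those AOIs first")
    if x.nunique() < 2:
        raise ValueError("covariate has a single unique value")
    return _lmm_table(values, x.to_numpy(), patients, log_transform, ddf_method,
                      contrast="per covariate unit")


def _lmm_table(values, x, patients, log_transform, ddf_method, contrast):
    vals = _prepare_values(values, log_transform)
    patients = pd.Series(patients).astype(str).to_numpy()
    rows = []
    for marker in vals.columns:
        y = vals[marker].to_numpy()
        if np.ptp(y) == 0:
            rows.append(
                dict(marker=marker, coefficient=np.nan, se=np.nan, ddf=np.nan,
                     p_value=np.nan, converged=False)
            )
            continue
        coef, se, ddf, p, ok = _fit_one_lmm(y, x, patients, ddf_method)
        rows.append(
            dict(marker=marker, coefficient=coef, se=se, ddf=ddf,
                 p_value=p if ok else np.nan, converged=ok)
        )
    out = pd.DataFrame(rows)
    out["p_adj_bh"] = _bh_adjust(out["p_value"].to_numpy())
    out["contrast"] = contrast
    out["n_obs"] = len(vals)
    out["n_patients"] = len(pd.unique(patients))
    return out


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """One row per converged marker: coefficient and -log10 p, volcano-ready."""
    conv = results[results["converged"]].copy()
    conv["neg_log10_p"] = -np.log10(conv["p_value"])
    return conv[["marker", "coefficient", "p_value", "neg_log10_p", "p_adj_bh"]]


def coxme_screen(
    clinical: pd.DataFrame,
    values: pd.DataFrame,
    patients: pd.Series,
    duration_col: str = "pfs_years",
    event_col: str = "pfs_event",
) -> pd.DataFrame:
    """Proportional-hazards screen of AOI-level covariates on survival.

    Each AOI inherits its patient's duration and event flag; per marker a
    Cox model is fit with patient-clustered robust (sandwich) variance to
    absorb the within-patient correlation of repeated AOIs.  A CR1-type
    small-sample correction is applied: the robust SE is inflated by
    sqrt(G/(G-1)) and the Wald statistic referred to a t distribution with
    G-1 degrees of freedom (G = number of patients).  Returns log-hazard
    coefficient and p-value per marker.
    """
    patients = pd.Series(patients).astype(str)
    if patients.nunique() < 2:
        raise ValueError("need at least two patients for a clustered hazard model")
    clin = clinical.set_index("patient_id")
    missing = set(patients) - set(clin.index)
    if missing:
        raise ValueError(f"patients without clinical records: {sorted(missing)[:5]}")
    durations = clin.loc[patients, duration_col].to_numpy(dtype=float)
    events = clin.loc[patients, event_col].to_numpy(dtype=float)
    if events.sum() == 0:
        raise ValueError("no events observed; hazard model is inestimable")
    n_clusters = patients.nunique()
    rows = []
    for marker in values.columns:
        df = pd.DataFrame(
            {
                "duration": durations,
                "event": events,
                "x": values[marker].to_numpy(dtype=float),
                "patient_id": patients.to_numpy(),
            }
        )
        if df["x"].nunique() < 2:
            rows.append(dict(marker=marker, coefficient=np.nan, p_value=np.nan,
                             converged=False))
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    df,
                    duration_col="duration",
                    event_col="event",
                    cluster_col="patient_id",
                    formula="x",
                )
            coef = float(cph.params_["x"])
            se = float(cph.standard_errors_["x"]) * np.sqrt(
                n_clusters / (n_clusters - 1)
            )
            p = 2 * sps.t.sf(abs(coef / se), n_clusters - 1)
            rows.append(
                dict(marker=marker, coefficient=coef, se=se,
                     p_value=float(p), converged=True)
            )
        except Exception:
            rows.append(dict(marker=marker, coefficient=np.nan, p_value=np.nan,
                             converged=False))
    out = pd.DataFrame(rows)
    out["p_adj_bh"] = _bh_adjust(out["p_value"].to_numpy())
    return out


def km_compare(
    clinical: pd.DataFrame,
    group_col: str = "consensus_label",
    groups: tuple[str, ...] | None = None,
    duration_col: str = "pfs_years",
    event_col: str = "pfs_event",
) -> dict:
    """Kaplan-Meier curves per patient group and two-sided log-rank p.

    One row per patient is expected (consensus topology label).  Requested
    groups with zero patients are dropped with a warning.  Returns a dict
    with fitted KaplanMeierFitter objects per group, the log-rank test
    result, and ``p_value``.
    """
    df = clinical.copy()
    if groups is not None:
        present = [g for g in groups if (df[group_col] == g).any()]
        for g in set(groups) - set(present):
            warnings.warn(f"group {g!r} has zero patients; dropped")
        df = df[df[group_col].isin(present)]
    if df[group_col].nunique() < 2:
        raise ValueError("need at least two non-empty groups for log-rank")
    durations = df[duration_col].astype(float)
    events = df[event_col].astype(float)
    if (durations < 0).any():
        raise ValueError("negative survival durations")
    if events.sum() == 0:
        raise ValueError("degenerate survival input: no events observed")
    fits = {}
    for g, sub in df.groupby(group_col):
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub[duration_col], event_observed=sub[event_col])
        fits[g] = kmf
    test = multivariate_logrank_test(durations, df[group_col], events)
    return {"fits": fits, "test": test, "p_value": float(test.p_value)}


def presence_survival_correlation(
    presence: pd.Series, survival_years: pd.Series
) -> tuple[float, float]:
    """Pearson r and two-sided p between immune presence and survival time."""
    x = pd.Series(presence).astype(float)
    y = pd.Series(survival_years).astype(float)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least three patients")
    if x.nunique() < 2 or y.nunique() < 2:
        warnings.warn("constant input: correlation undefined")
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
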