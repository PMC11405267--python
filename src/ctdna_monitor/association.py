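"""Prespecified association testing of ctDNA metrics with clinical outcomes.

The analysis plan mirrors a two-arm monitoring substudy: per-arm one-sided
tests of baseline ctDNA levels and C2/C1 change ratios against best overall
response (logistic regression), PFS and OS (Cox proportional hazards, Efron
ties), an adjustment ladder (ECOG PS; plus baseline tumor size and the
TMBxPD-L1 subgroup factor; plus radiographic response), Hochberg step-up
family-wise-error control across the metrics of each family, pooled-median
dichotomization of change ratios with Kaplan-Meier displays, and between-arm
hazard ratios.

Hypotheses are one-sided for a negative association between ctDNA and
benefit: every metric is oriented so that a *higher* value (higher baseline
level; smaller reduction, i.e. larger C2/C1 ratio) is hypothesized to mean
worse outcome.  For the response model the alternative is therefore a
negative log-odds coefficient; for the survival models a positive
log-hazard coefficient.

The user-facing surface is :class:`CtdnaAssociationModel` (built from an
analysis table or a :class:`~ctdna_monitor.cohort.SyntheticCohort`), whose
``fit()`` returns a :class:`CtdnaAssociationResults` carrying one
:class:`AssociationResult` per test plus the multiplicity decisions, with a
``summary()`` table and Kaplan-Meier helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .config import RESPONDER_CLASSES
from .errors import ConfigError, DataError
from .metrics import BASELINE_METRICS, MONITORING_METRICS

OUTCOMES = ("BOR", "PFS", "OS")
ADJUSTMENTS = ("ecog_ps", "baseline_tumor_size", "ttmb_pdl1_factor", "bor", "tumor_change_9wk")
LARGE_REDUCTION = "large_reduction"
NOT_LARGE = "not_large"

_SUBGROUP_REFERENCE = "tmb_low_pdl1_low"


@dataclass(frozen=True)
class AnalysisSpec:
    """One metric x outcome x arm test with its adjustment set."""

    metric: str
    outcome: str
    arm: Optional[str] = None
    adjust: tuple[str, ...] = ("ecog_ps",)
    transform: str = "log_shifted"
    alpha: float = 0.05
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"unknown outcome {self.outcome!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.transform not in ("identity", "log_shifted"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        unknown = set(self.adjust) - set(ADJUSTMENTS)
        if unknown:
            raise ConfigError(f"unknown adjustment(s): {sorted(unknown)}")
        if self.outcome == "BOR" and "bor" in self.adjust:
            raise ConfigError("BOR cannot be both the outcome and an adjustment")


@dataclass
class AssociationResult:
    """Estimate and one-sided inference for one test."""

    spec: AnalysisSpec
    n: int
    estimate: Optional[float]
    se: Optional[float]
    p_one_sided: Optional[float]
    p_two_sided: Optional[float] = None
    p_adjusted: Optional[float] = None
    reject: Optional[bool] = None
    delta: Optional[float] = None
    note: str = ""

    @property
    def estimable(self) -> bool:
        return self.estimate is not None and self.se is not None


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate."""

    times: np.ndarray          # event times (steps)
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # subjects at risk at each event time
    median: Optional[float]    # first time S(t) <= 0.5, None if never reached


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def transform_metric(values: np.ndarray, transform: str) -> tuple[np.ndarray, dict]:
    """Apply the analysis-scale transform.

    ``log_shifted`` computes ``ln(x + delta)`` with ``delta`` half the
    smallest positive value in the analysis set (recorded in the returned
    metadata); zeros from clearance stay finite and ordered below every
    positive value.  Rank order is always preserved.
    """
    values = np.asarray(values, dtype=float)
    if np.nanmin(values) < 0:
        raise DataError("metric values must be nonnegative")
    if transform == "identity":
        return values.copy(), {"transform": "identity", "delta": None}
    positive = values[values > 0]
    if len(positive) == 0:
        raise DataError("log_shifted transform requires at least one positive value")
    delta = float(positive.min()) / 2.0
    return np.log(values + delta), {"transform": "log_shifted", "delta": delta}


def one_sided_p(estimate: float, se: float, outcome: str) -> float:
    """One-sided Wald p for the negative-association alternative.

    Response (benefit) models test ``beta < 0``; hazard models test
    ``beta > 0`` — both correspond to "more ctDNA, worse outcome".
    """
    z = estimate / se
    if outcome == "BOR":
        return float(stats.norm.cdf(z))
    return float(stats.norm.sf(z))


def hochberg_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Hochberg step-up adjusted p values and rejection flags for one family.

    Step-up: with ascending ``p_(1..m)``, reject hypotheses ``1..k`` for the
    largest ``k`` with ``p_(k) <= alpha/(m-k+1)``.  Adjusted p values are the
    running minima of ``(m-j+1) * p_(j)`` from the largest p downwards,
    clipped to 1; rejection is equivalent to ``adjusted <= alpha``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise DataError("empty p-value family")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DataError(f"p values must lie in [0, 1], got {p}")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    mult = (m - np.arange(m)) * ranked          # (m-j+1) * p_(j), j 1-based
    adj_sorted = np.minimum.accumulate(mult[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def km_estimate(
    times: Sequence[float], event_flags: Sequence[int]
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with median survival.

    Censored subjects at time t are counted at risk at t; the curve steps
    only at event times.  The median is the first time S(t) <= 0.5 and is
    ``None`` when the curve never reaches 0.5.
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(event_flags), dtype=int)
    if len(times) == 0:
        raise DataError("empty survival input")
    if np.any(times <= 0):
        raise DataError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    ev_times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(steps.index).to_numpy()
    at_risk = steps["at_risk"].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return SurvivalCurve(ev_times, surv, at_risk, median)


def dichotomize_by_pooled_median(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Label change ratios by the pooled (both-arm) median.

    Strictly below the median -> ``large_reduction``; at or above ->
    ``not_large`` (ties go to "not large"); NaN (not evaluable) -> ``None``.
    Returns the labels and the cutoff used.
    """
    values = np.asarray(list(values), dtype=float)
    evaluable = values[~np.isnan(values)]
    if len(evaluable) < 2:
        raise DataError("need at least two evaluable values to dichotomize")
    cutoff = float(np.median(evaluable))
    labels = np.where(values < cutoff, LARGE_REDUCTION, NOT_LARGE).astype(object)
    labels[np.isnan(values)] = None
    return labels, cutoff


# ---------------------------------------------------------------------------
# model fitting internals
# ---------------------------------------------------------------------------

def _design_matrix(
    data: pd.DataFrame, spec: AnalysisSpec
) -> tuple[pd.DataFrame, dict]:
    """Analysis subset and covariate matrix for one spec."""
    df = data
    if spec.arm is not None:
        df = df[df["arm"] == spec.arm]
        if len(df) == 0:
            raise DataError(f"no patients in arm {spec.arm!r}")
    cols: dict[str, pd.Series] = {}
    needed = [spec.metric]
    if spec.outcome == "BOR":
        needed.append("bor")
    else:
        t_col = "pfs_time" if spec.outcome == "PFS" else "os_time"
        e_col = "pfs_event" if spec.outcome == "PFS" else "os_event"
        needed += [t_col, e_col]
    for adj in spec.adjust:
        needed.append("subgroup" if adj == "ttmb_pdl1_factor" else adj)
    missing = [c for c in set(needed) if c not in df.columns]
    if missing:
        raise DataError(f"analysis table lacks column(s): {sorted(missing)}")
    df = df.dropna(subset=[c for c in set(needed)])
    if len(df) == 0:
        raise DataError(f"no complete cases for {spec.metric} x {spec.outcome}")

    x, meta = transform_metric(df[spec.metric].to_numpy(), spec.transform)
    cols["metric"] = pd.Series(x, index=df.index)
    for adj in spec.adjust:
        if adj == "ttmb_pdl1_factor":
            dummies = pd.get_dummies(df["subgroup"], prefix="sub", dtype=float)
            ref = f"sub_{_SUBGROUP_REFERENCE}"
            for col in dummies.columns:
                if col != ref:
                    cols[col] = dummies[col]
        elif adj == "bor":
            cols["responder"] = df["bor"].isin(RESPONDER_CLASSES).astype(float)
        else:
            cols[adj] = df[adj].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    # drop constant adjustment columns (degenerate covariates)
    dropped = [c for c in X.columns if c != "metric" and X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    meta["dropped_constant"] = dropped
    return df.assign(**{f"_x_{c}": X[c] for c in X.columns}), {
        **meta,
        "covariates": list(X.columns),
    }


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, lam: float = 0.5, n_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """L2-penalized logistic Newton fit; fallback under separation.

    The intercept is unpenalized.  Standard errors come from the inverse
    penalized information, which is what makes the fit usable when the
    unpenalized MLE diverges.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.full(k, lam)
    pen[0] = 0.0
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        info = (X.T * w) @ X + np.diag(pen)
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = (X.T * w) @ X + np.diag(pen)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def test_bor_association(data: pd.DataFrame, spec: AnalysisSpec) -> AssociationResult:
    """Logistic regression of responder (CR/PR) on a transformed ctDNA metric.

    One-sided p for a negative coefficient.  Under complete separation the
    maximum-likelihood fit diverges; the result is then flagged and computed
    from a documented L2-penalized fit instead of failing silently.
    """
    import statsmodels.api as sm

    df, meta = _design_matrix(data, spec)
    y = df["bor"].isin(RESPONDER_CLASSES).to_numpy(float)
    xcols = [c for c in df.columns if c.startswith("_x_")]
    X = sm.add_constant(df[xcols].to_numpy(float), has_constant="add")
    n = len(df)
    if y.sum() == 0 or y.sum() == n:
        return AssociationResult(
            spec, n, None, None, None, delta=meta.get("delta"),
            note="not_estimable:all_one_class",
        )
    j = 1 + xcols.index("_x_metric")
    note = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        bad = (
            not fit.mle_retvals.get("converged", True)
            or not np.all(np.isfinite(fit.bse))
            or np.any(np.abs(np.asarray(fit.params)) > 30)
            or fit.bse[j] > 50
        )
        if bad:
            raise RuntimeError("separation or non-convergence")
        est, se = float(fit.params[j]), float(fit.bse[j])
    except Exception:
        beta, bse = _ridge_logistic(X, y)
        est, se = float(beta[j]), float(bse[j])
        note = "penalized:separation_or_nonconvergence"
    p1 = one_sided_p(est, se, "BOR")
    p2 = 2 * stats.norm.sf(abs(est / se))
    return AssociationResult(
        spec, n, est, se, p1, p_two_sided=float(p2), delta=meta.get("delta"), note=note
    )


def test_survival_association(data: pd.DataFrame, spec: AnalysisSpec) -> AssociationResult:
    """Cox PH regression (Efron ties) of PFS/OS on a transformed ctDNA metric.

    One-sided p for a positive log-hazard coefficient.  Non-convergence is
    retried with a small L2 penalty and flagged; zero events yield a
    not-estimable result.
    """
    df, meta = _design_matrix(data, spec)
    t_col = "pfs_time" if spec.outcome == "PFS" else "os_time"
    e_col = "pfs_event" if spec.outcome == "PFS" else "os_event"
    xcols = [c for c in df.columns if c.startswith("_x_")]
    fit_df = df[[t_col, e_col, *xcols]].astype(float)
    n = len(fit_df)
    if fit_df[e_col].sum() == 0:
        return AssociationResult(
            spec, n, None, None, None, delta=meta.get("delta"), note="not_estimable:no_events"
        )
    note = ""
    est = se = None
    for penalizer in (0.0, 0.1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=penalizer)
                cph.fit(
                    fit_df, duration_col=t_col, event_col=e_col,
                    fit_options={"precision": 1e-9, "max_steps": 500},
                )
            est = float(cph.params_["_x_metric"])
            se = float(cph.standard_errors_["_x_metric"])
            if penalizer > 0:
                note = "penalized:nonconvergence"
            break
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue
    if est is None:
        return AssociationResult(
            spec, n, None, None, None, delta=meta.get("delta"), note="not_estimable:nonconvergence"
        )
    p1 = one_sided_p(est, se, spec.outcome)
    p2 = 2 * stats.norm.sf(abs(est / se))
    return AssociationResult(
        spec, n, est, se, p1, p_two_sided=float(p2), delta=meta.get("delta"), note=note
    )


def run_test(data: pd.DataFrame, spec: AnalysisSpec) -> AssociationResult:
    """Dispatch one spec to the logistic or Cox fitter."""
    if spec.outcome == "BOR":
        return test_bor_association(data, spec)
    return test_survival_association(data, spec)


def joint_orthogonality_test(
    data: pd.DataFrame,
    spec: AnalysisSpec,
    radiographic: str,
) -> tuple[AssociationResult, AssociationResult]:
    """Joint model: ctDNA change plus a radiographic response covariate.

    Tests whether the ctDNA metric explains outcome beyond radiographic
    response (``bor`` or ``tumor_change_9wk``).  Returns the metric term
    (one-sided p) and the radiographic term (two-sided p).  A constant
    radiographic covariate is dropped, reducing to the unadjusted model.
    """
    if radiographic not in ("bor", "tumor_change_9wk"):
        raise ConfigError(f"radiographic covariate must be bor or tumor_change_9wk, got {radiographic!r}")
    joint_spec = replace(spec, adjust=tuple(dict.fromkeys([*spec.adjust, radiographic])))
    metric_res = run_test(data, joint_spec)

    rad_col = "_x_responder" if radiographic == "bor" else "_x_tumor_change_9wk"
    df, _meta = _design_matrix(data, joint_spec)
    if rad_col not in df.columns:
        rad_res = AssociationResult(
            joint_spec, metric_res.n, None, None, None, note="degenerate:constant_covariate"
        )
        return metric_res, rad_res

    # refit exposing the radiographic coefficient
    if joint_spec.outcome == "BOR":
        import statsmodels.api as sm

        xcols = [c for c in df.columns if c.startswith("_x_")]
        y = df["bor"].isin(RESPONDER_CLASSES).to_numpy(float)
        X = sm.add_constant(df[xcols].to_numpy(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)
            bse = np.asarray(fit.bse)
        except Exception:
            params, bse = _ridge_logistic(X, y)
        j = 1 + xcols.index(rad_col)
        est, se = float(params[j]), float(bse[j])
    else:
        t_col = "pfs_time" if joint_spec.outcome == "PFS" else "os_time"
        e_col = "pfs_event" if joint_spec.outcome == "PFS" else "os_event"
        xcols = [c for c in df.columns if c.startswith("_x_")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df[[t_col, e_col, *xcols]].astype(float), duration_col=t_col, event_col=e_col)
        est = float(cph.params_[rad_col])
        se = float(cph.standard_errors_[rad_col])
    p2 = float(2 * stats.norm.sf(abs(est / se)))
    rad_res = AssociationResult(
        joint_spec, metric_res.n, est, se, None, p_two_sided=p2, note="radiographic_term"
    )
    return metric_res, rad_res


def between_arm_hr(data: pd.DataFrame, outcome: str) -> dict:
    """Univariable between-arm hazard ratio with Wald 95% CI (log scale)."""
    if outcome not in ("PFS", "OS"):
        raise ConfigError(f"between-arm HR requires PFS or OS, got {outcome!r}")
    arms = sorted(data["arm"].dropna().unique())
    if len(arms) != 2:
        raise DataError(f"between-arm HR needs exactly two arms, got {arms}")
    t_col = "pfs_time" if outcome == "PFS" else "os_time"
    e_col = "pfs_event" if outcome == "PFS" else "os_event"
    df = data.dropna(subset=[t_col, e_col]).copy()
    df["_arm_ind"] = (df["arm"] == arms[1]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter()
        cph.fit(df[[t_col, e_col, "_arm_ind"]], duration_col=t_col, event_col=e_col)
    log_hr = float(cph.params_["_arm_ind"])
    se = float(cph.standard_errors_["_arm_ind"])
    return {
        "comparison": f"{arms[1]} vs {arms[0]}",
        "hr": float(np.exp(log_hr)),
        "ci_low": float(np.exp(log_hr - 1.959963984540054 * se)),
        "ci_high": float(np.exp(log_hr + 1.959963984540054 * se)),
        "log_hr": log_hr,
        "se": se,
        "n": len(df),
    }


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

def default_specs(data: pd.DataFrame, alpha: float = 0.05) -> list[AnalysisSpec]:
    """The prespecified testing plan for an analysis table.

    Two multiplicity families per outcome x arm x adjustment rung: the
    baseline metrics (tumor-informed and tumor-uninformed maxVAF at C1) and
    the monitoring metrics (the three C2/C1 VAF ratios plus, when present,
    the external change score).  No penalty is shared across outcomes.
    """
    arms = sorted(data["arm"].dropna().unique())
    baseline = [f"{m}_c1" for m in BASELINE_METRICS]
    monitoring = [f"ratio_{m}" for m in MONITORING_METRICS]
    if "external_change_score" in data.columns and data["external_change_score"].notna().any():
        monitoring.append("external_change_score")
    ladders = {
        "ecog": ("ecog_ps",),
        "full": ("ecog_ps", "baseline_tumor_size", "ttmb_pdl1_factor"),
    }
    specs = []
    for arm in arms:
        for outcome in OUTCOMES:
            for rung, adjust in ladders.items():
                for metric in baseline:
                    specs.append(
                        AnalysisSpec(
                            metric, outcome, arm, adjust, alpha=alpha,
                            family=f"baseline|{outcome}|{arm}|{rung}",
                        )
                    )
                for metric in monitoring:
                    specs.append(
                        AnalysisSpec(
                            metric, outcome, arm, adjust, alpha=alpha,
                            family=f"monitoring|{outcome}|{arm}|{rung}",
                        )
                    )
    return specs


class CtdnaAssociationModel:
    """The association-testing plan applied to one analysis table.

    Parameters
    ----------
    data:
        One row per patient: clinical columns (``arm``, ``ecog_ps``,
        ``baseline_tumor_size``, ``subgroup``, ``bor``, ``pfs_time``,
        ``pfs_event``, ``os_time``, ``os_event``, ``tumor_change_9wk`` and
        optionally ``external_change_score``) merged with the per-patient
        metric profile from :func:`ctdna_monitor.metrics.compute_profiles`.
    specs:
        Tests to run; defaults to the prespecified plan
        (:func:`default_specs`).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        specs: Optional[Sequence[AnalysisSpec]] = None,
        alpha: float = 0.05,
    ) -> None:
        if "arm" not in data.columns:
            raise DataError("analysis table requires an 'arm' column")
        self.data = data.reset_index(drop=True)
        self.alpha = alpha
        self.specs = list(specs) if specs is not None else default_specs(data, alpha)

    @classmethod
    def from_cohort(cls, cohort, specs=None, alpha: float = 0.05) -> "CtdnaAssociationModel":
        """Build the analysis table from a synthetic cohort (clinical + profiles)."""
        from .metrics import compute_profiles

        profiles = compute_profiles(
            cohort.variants, patient_ids=cohort.clinical["patient_id"]
        )
        data = cohort.clinical.merge(profiles, on="patient_id", how="left")
        return cls(data, specs=specs, alpha=alpha)

    def fit(self) -> "CtdnaAssociationResults":
        """Run every spec and apply Hochberg adjustment within each family."""
        results = [run_test(self.data, spec) for spec in self.specs]
        by_family: dict[str, list[int]] = {}
        for i, res in enumerate(results):
            fam = res.spec.family
            if fam is not None and res.estimable:
                by_family.setdefault(fam, []).append(i)
        for fam, idx in by_family.items():
            p = [results[i].p_one_sided for i in idx]
            alpha = results[idx[0]].spec.alpha
            adjusted, reject = hochberg_adjust(p, alpha)
            for j, i in enumerate(idx):
                results[i].p_adjusted = float(adjusted[j])
                results[i].reject = bool(reject[j])
        return CtdnaAssociationResults(self, results)


@dataclass
class CtdnaAssociationResults:
    """Fitted analysis plan: per-test results, multiplicity decisions, displays."""

    model: CtdnaAssociationModel
    results: list[AssociationResult] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """One row per test: estimate, SE, one-sided p, Hochberg-adjusted p, decision."""
        rows = []
        for r in self.results:
            s = r.spec
            rows.append(
                {
                    "metric": s.metric,
                    "outcome": s.outcome,
                    "arm": s.arm,
                    "adjust": "+".join(s.adjust),
                    "family": s.family,
                    "n": r.n,
                    "estimate": r.estimate,
                    "se": r.se,
                    "p_one_sided": r.p_one_sided,
                    "p_adjusted": r.p_adjusted,
                    "reject": r.reject,
                    "delta": r.delta,
                    "note": r.note,
                }
            )
        return pd.DataFrame(rows)

    def km_by_median_reduction(
        self, metric: str, outcome: str, arm: Optional[str] = None
    ) -> dict:
        """KM curves by pooled-median dichotomization of a change ratio.

        The cutoff is the median over evaluable patients of *both* arms; the
        curves are then estimated within ``arm`` (or pooled when ``None``).
        Returns the cutoff, per-group curves and per-group medians.
        """
        data = self.model.data
        labels, cutoff = dichotomize_by_pooled_median(data[metric].to_numpy(float))
        df = data.assign(_group=labels)
        if arm is not None:
            df = df[df["arm"] == arm]
        t_col = "pfs_time" if outcome == "PFS" else "os_time"
        e_col = "pfs_event" if outcome == "PFS" else "os_event"
        curves = {}
        for group in (LARGE_REDUCTION, NOT_LARGE):
            sub = df[df["_group"] == group].dropna(subset=[t_col, e_col])
            if len(sub):
                curves[group] = km_estimate(sub[t_col], sub[e_col])
        return {"cutoff": cutoff, "metric": metric, "outcome": outcome, "arm": arm, "curves": curves}

    def plot_km(self, metric: str, outcome: str, arm: Optional[str] = None, ax=None):
        """Matplotlib step plot of the median-dichotomized KM curves."""
        import matplotlib.pyplot as plt

        info = self.km_by_median_reduction(metric, outcome, arm)
        if ax is None:
            _fig, ax = plt.subplots()
        for group, curve in info["curves"].items():
            x = np.concatenate([[0.0], curve.times])
            y = np.concatenate([[1.0], curve.survival])
            ax.step(x, y, where="post", label=group)
        ax.set_xlabel("months")
        ax.set_ylabel(f"{outcome} probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        title = f"{metric} ({info['arm'] or 'both arms'}), cutoff={info['cutoff']:.3g}"
        ax.set_title(title)
        return ax

    def between_arm_hr(self, outcome: str, subset: Optional[pd.Series] = None) -> dict:
        data = self.model.data if subset is None else self.model.data[subset]
        return between_arm_hr(data, outcome)
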