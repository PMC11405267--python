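"""Patient-selection and power machinery for the monitoring substudy.

Two tools: representative stratified subsampling that matches the TMBxPD-L1
subgroup proportions of the analysis-eligible population (with a small
oversample for anticipated assay failures), and simulation/bootstrap power
estimation for the one-sided baseline-ctDNA OS test, with the Schoenfeld
approximation available as an analytic comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .association import AnalysisSpec, run_test
from .config import ARM_IMMUNO, CohortConfig
from .errors import ConfigError, DataError


@dataclass
class SamplingPlan:
    """Stratified selection plan for one or both arms.

    ``target_proportions`` optionally fixes the subgroup proportions to match
    (e.g. those of the full analysis-eligible population when the sampling
    pool is only a subset of it); by default the pool's own proportions are
    used, in which case no stratum can be exhausted.
    """

    target_n_per_arm: int
    oversample: float = 0.05     # extra fraction for anticipated QC failures
    seed: int = 0
    target_proportions: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.target_n_per_arm < 0:
            raise ConfigError("target_n_per_arm must be nonnegative")
        if self.oversample < 0:
            raise ConfigError("oversample must be nonnegative")

    @property
    def total_per_arm(self) -> int:
        return math.ceil(self.target_n_per_arm * (1.0 + self.oversample))


@dataclass
class PowerEstimate:
    """Monte-Carlo power estimate for the one-sided test."""

    n_per_arm: int
    alpha: float
    replicates: int
    power: float
    mc_se: float


def largest_remainder(proportions: Sequence[float], total: int) -> np.ndarray:
    """Integer apportionment of ``total`` seats by the largest-remainder rule.

    Quotas are ``total * proportion``; each stratum first receives the floor,
    then remaining seats go to the largest fractional remainders (ties broken
    by stratum order).  Quotas always sum exactly to ``total``.
    """
    props = np.asarray(list(proportions), dtype=float)
    if np.any(props < 0):
        raise DataError("proportions must be nonnegative")
    s = props.sum()
    if s <= 0:
        raise DataError("proportions must not all be zero")
    props = props / s
    raw = props * total
    quotas = np.floor(raw).astype(int)
    remainder = raw - quotas
    short = total - int(quotas.sum())
    if short > 0:
        # stable sort: ties by stratum index
        order = np.argsort(-remainder, kind="stable")
        quotas[order[:short]] += 1
    return quotas


def stratified_subsample(
    eligible: pd.DataFrame, plan: SamplingPlan
) -> tuple[list[str], pd.DataFrame]:
    """Select patients per arm matching the source subgroup proportions.

    ``eligible`` needs columns ``patient_id``, ``arm`` and ``subgroup``
    (every patient labelled).  Per arm, ``ceil(target*(1+oversample))``
    patients are drawn without replacement, apportioned across strata by
    largest remainder; an exhausted stratum's shortfall is reallocated to the
    remaining strata (again by largest remainder) and recorded in the
    accounting table.  A pool smaller than the total quota is an error.

    Returns the selected patient ids and a per-arm-stratum accounting frame.
    """
    for col in ("patient_id", "arm", "subgroup"):
        if col not in eligible.columns:
            raise DataError(f"eligible table lacks column {col!r}")
    if eligible["subgroup"].isna().any():
        bad = eligible[eligible["subgroup"].isna()]["patient_id"].iloc[0]
        raise DataError(f"patient {bad} has no subgroup label")

    rng = np.random.default_rng(plan.seed)
    selected: list[str] = []
    accounting_rows = []
    for arm, arm_df in eligible.groupby("arm", sort=True):
        total = plan.total_per_arm
        if len(arm_df) < total:
            raise DataError(
                f"arm {arm}: eligible pool ({len(arm_df)}) smaller than total "
                f"quota ({total}); shortfall {total - len(arm_df)}"
            )
        strata = arm_df.groupby("subgroup", sort=True).size()
        names = list(strata.index)
        avail = strata.to_numpy()
        if plan.target_proportions is not None:
            props = np.array([plan.target_proportions.get(s, 0.0) for s in names])
        else:
            props = avail.astype(float)
        quotas = largest_remainder(props, total)

        # reallocate from exhausted strata until all quotas are feasible
        realloc = np.zeros(len(names), dtype=int)
        for _ in range(len(names)):
            over = quotas - avail
            excess = int(np.clip(over, 0, None).sum())
            if excess == 0:
                break
            quotas = np.minimum(quotas, avail)
            room = avail - quotas
            weights = np.where(room > 0, avail, 0)
            extra = largest_remainder(weights, excess)
            extra = np.minimum(extra, room)
            realloc += extra
            quotas = quotas + extra

        for i, name in enumerate(names):
            ids = arm_df[arm_df["subgroup"] == name]["patient_id"].to_numpy()
            take = rng.choice(ids, size=quotas[i], replace=False)
            selected.extend(sorted(take))
            accounting_rows.append(
                {
                    "arm": arm,
                    "subgroup": name,
                    "eligible_n": int(avail[i]),
                    "source_prop": float(avail[i] / avail.sum()),
                    "quota": int(quotas[i]),
                    "reallocated_in": int(realloc[i]),
                }
            )
    accounting = pd.DataFrame(accounting_rows)
    return selected, accounting


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def schoenfeld_power(
    log_hr: float, n_events: float, var_x: float, alpha_one_sided: float = 0.025
) -> float:
    """Schoenfeld-formula power for a one-sided Cox Wald test.

    ``power = Phi( sqrt(d * var_x) * |log_hr| - z_{1-alpha} )`` with ``d``
    expected events and ``var_x`` the covariate variance (binary allocation:
    ``p*(1-p)``).
    """
    z_a = stats.norm.ppf(1.0 - alpha_one_sided)
    return float(stats.norm.cdf(math.sqrt(n_events * var_x) * abs(log_hr) - z_a))


def schoenfeld_required_log_hr(
    power: float, n_events: float, var_x: float, alpha_one_sided: float = 0.025
) -> float:
    """Invert the Schoenfeld formula for the effect size giving ``power``."""
    z_a = stats.norm.ppf(1.0 - alpha_one_sided)
    z_b = stats.norm.ppf(power)
    return (z_a + z_b) / math.sqrt(n_events * var_x)


def bootstrap_power(
    source: Union[CohortConfig, pd.DataFrame],
    n_per_arm: int,
    alpha_one_sided: float = 0.025,
    replicates: int = 200,
    seed: int = 0,
    spec: Optional[AnalysisSpec] = None,
) -> PowerEstimate:
    """Monte-Carlo power of the one-sided baseline-ctDNA OS test.

    ``source`` is either a generator config (a fresh cohort of ``n_per_arm``
    per arm is simulated per replicate) or a pilot analysis table (rows are
    resampled with replacement per arm at size ``n_per_arm``).  Power is the
    fraction of replicates whose test rejects at ``alpha_one_sided``; the
    Monte-Carlo SE is ``sqrt(p*(1-p)/replicates)``.  Fully seed-determined.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    if spec is None:
        spec = AnalysisSpec(
            metric="maxvaf_informed_c1",
            outcome="OS",
            arm=ARM_IMMUNO,
            adjust=("ecog_ps",),
            alpha=alpha_one_sided,
        )
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    pilot = None
    if isinstance(source, pd.DataFrame):
        if len(source) < 2:
            raise DataError("pilot table needs at least 2 subjects")
        pilot = source.reset_index(drop=True)

    rejections = 0
    for r in range(replicates):
        if pilot is None:
            cfg = source.replace(n_per_arm=n_per_arm, seed=int(child_seeds[r]))
            from .association import CtdnaAssociationModel
            from .cohort import generate_cohort

            cohort = generate_cohort(cfg)
            model = CtdnaAssociationModel.from_cohort(cohort, specs=[spec], alpha=alpha_one_sided)
            data = model.data
        else:
            rrng = np.random.default_rng(int(child_seeds[r]))
            parts = []
            for _, arm_df in pilot.groupby("arm", sort=True):
                idx = rrng.integers(0, len(arm_df), size=n_per_arm)
                parts.append(arm_df.iloc[idx])
            data = pd.concat(parts, ignore_index=True)
        try:
            res = run_test(data, spec)
        except DataError:
            continue
        if res.estimable and res.p_one_sided is not None and res.p_one_sided <= alpha_one_sided:
            rejections += 1
    power = rejections / replicates
    mc_se = math.sqrt(power * (1.0 - power) / replicates)
    return PowerEstimate(n_per_arm, alpha_one_sided, replicates, power, mc_se)
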