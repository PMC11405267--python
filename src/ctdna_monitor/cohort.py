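"""Synthetic two-arm ctDNA monitoring trial generator.

Produces a virtual randomized trial with an immunotherapy-like arm (A) and a
chemotherapy-like arm (B).  Each patient carries:

* a tissue whole-exome (WES) somatic truth set sized by their tissue TMB,
* a plasma panel call set at baseline (C1) — a captured subset of the WES
  truth plus low-VAF panel-only artifacts,
* a plasma panel call set at cycle 2 (C2) obtained by applying arm- and
  response-class-specific log fold-change dynamics to the C1 VAFs and
  re-sampling read counts binomially (a variant whose resampled alt count
  hits zero is emitted as absent — clearance is emergent),
* clinical outcomes (BOR, PFS, OS, 9-week tumor-size change) drawn from
  exponential proportional-hazards and logistic models linked to the
  patient's true baseline ctDNA level and true C2/C1 log fold-change.

Data live in pandas DataFrames (one row per patient / per variant call);
:class:`PatientRecord` and :class:`VariantCall` document the row schemas.
All randomness flows from ``CohortConfig.seed`` — identical configs yield
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    ARM_CHEMO,
    ARMS,
    BOR_CLASSES,
    RESPONDER_CLASSES,
    CohortConfig,
)
from .errors import DataError
from .metrics import subgroup_factor

TIMEPOINTS = ("C1", "C2")
ASSAYS = ("panel", "wes")

#: log baseline level assigned to patients with no detectable tumor variants
#: (in units of vaf_sigma below the population location).
_NEGATIVE_FLOOR_SIGMAS = 3.0

CLINICAL_COLUMNS = [
    "patient_id", "arm", "ecog_ps", "baseline_tumor_size", "ttmb", "pdl1_cps",
    "subgroup", "bor", "pfs_time", "pfs_event", "os_time", "os_event",
    "tumor_change_9wk", "external_change_score",
]

VARIANT_COLUMNS = [
    "patient_id", "timepoint", "assay", "chrom", "pos", "ref", "alt",
    "alt_reads", "total_reads", "vaf", "in_dbsnp", "in_cosmic",
    "nonsynonymous", "truth_label",
]


@dataclass
class PatientRecord:
    """Row schema of the clinical table."""

    patient_id: str
    arm: str
    ecog_ps: int
    baseline_tumor_size: float
    ttmb: float
    pdl1_cps: float
    subgroup: str
    bor: str
    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int
    tumor_change_9wk: float
    external_change_score: Optional[float] = None


@dataclass
class VariantCall:
    """Row schema of the long-format variant table.

    ``truth_label`` ("tumor_true" / "artifact") is generator-only metadata;
    real data would carry it as missing.
    """

    patient_id: str
    timepoint: str
    assay: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_reads: int
    vaf: float
    in_dbsnp: bool = False
    in_cosmic: bool = False
    nonsynonymous: bool = False
    truth_label: Optional[str] = None


@dataclass
class SyntheticCohort:
    """A generated trial: clinical table, variant calls and ground truth."""

    clinical: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig = field(repr=False)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)


_BASES = np.array(["A", "C", "G", "T"])


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "timepoint": pd.Series(dtype=str),
            "assay": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "alt_reads": pd.Series(dtype=np.int64),
            "total_reads": pd.Series(dtype=np.int64),
            "vaf": pd.Series(dtype=float),
            "in_dbsnp": pd.Series(dtype=bool),
            "in_cosmic": pd.Series(dtype=bool),
            "nonsynonymous": pd.Series(dtype=bool),
            "truth_label": pd.Series(dtype=str),
        }
    )


# ---------------------------------------------------------------------------
# baseline patients and latents
# ---------------------------------------------------------------------------

def _draw_patients(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates plus latent variables, one row per patient.

    Latent columns (``u_*``, ``sens``, ``responder``, ``log_vaf_location``,
    ``lfc``) are generator-internal and end up in the truth sidecar, never in
    the exported clinical table.
    """
    n = 2 * config.n_per_arm
    arm = np.repeat(list(ARMS), config.n_per_arm)
    pid = np.array(
        [f"{'A' if a == ARMS[0] else 'B'}-{i + 1:04d}" for i, a in enumerate(arm)]
    )

    # Gaussian copula for (tTMB, CPS, baseline VAF level, latent sensitivity)
    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = config.rho_ttmb_cps
    corr[0, 2] = corr[2, 0] = config.rho_ttmb_vaf
    corr[0, 3] = corr[3, 0] = config.rho_ttmb_sens
    chol = np.linalg.cholesky(corr)
    u = rng.standard_normal((n, 4)) @ chol.T
    u_ttmb, u_cps, u_vaf, sens = u.T

    ttmb = np.round(np.exp(config.ttmb_mu + config.ttmb_sigma * u_ttmb)).astype(int)

    # Anchor the CPS lognormal so that P(CPS >= 10) == prop_pdl1_high.
    p = min(max(config.prop_pdl1_high, 1e-12), 1 - 1e-12)
    thresh = stats.norm.ppf(1.0 - p)
    pdl1_cps = np.exp(np.log(10.0) + config.cps_sigma * (u_cps - thresh))

    ecog = rng.choice(np.array([0, 1, 2]), size=n, p=np.asarray(config.ecog_probs))
    tumor_size = np.exp(
        config.tumor_size_mu + config.tumor_size_sigma * rng.standard_normal(n)
    )

    intercept = np.where(
        arm == ARMS[0],
        config.responder_intercept[ARMS[0]],
        config.responder_intercept[ARMS[1]],
    )
    p_resp = 1.0 / (1.0 + np.exp(-(intercept + config.responder_slope * sens)))
    responder = rng.random(n) < p_resp
    split = rng.random(n)
    bor = np.where(
        responder,
        np.where(split < config.prop_cr_given_responder, "CR", "PR"),
        np.where(split < config.prop_sd_given_nonresponder, "SD", "PD"),
    )

    log_vaf_location = config.vaf_mu + config.vaf_sigma * u_vaf

    # patient-level true C2/C1 log fold-change
    lfc = np.empty(n)
    noise = rng.standard_normal(n)
    for a in ARMS:
        dyn = config.dynamics[a]
        for is_resp in (True, False):
            mask = (arm == a) & (responder == is_resp)
            law = dyn.for_class(is_resp)
            lfc[mask] = law.lfc_mu + law.lfc_sigma * noise[mask]

    subgroup = np.array([subgroup_factor(t, c) for t, c in zip(ttmb, pdl1_cps)])

    return pd.DataFrame(
        {
            "patient_id": pid,
            "arm": arm,
            "ecog_ps": ecog,
            "baseline_tumor_size": tumor_size,
            "ttmb": ttmb,
            "pdl1_cps": pdl1_cps,
            "subgroup": subgroup,
            "responder": responder,
            "bor": bor,
            "sens": sens,
            "log_vaf_location": log_vaf_location,
            "lfc": lfc,
        }
    )


# ---------------------------------------------------------------------------
# variant profiles
# ---------------------------------------------------------------------------

def generate_variant_profile(
    patients: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Baseline (C1) WES and plasma-panel calls for one or more patients.

    The WES truth-set size is Poisson with mean ``ttmb * wes_per_ttmb``; each
    truth variant enters the plasma panel independently with probability
    ``panel_capture``, with its plasma VAF drawn around the patient's latent
    baseline level and read counts binomially sampled at panel depth.  Panel
    artifacts (``truth_label='artifact'``) are Poisson extras whose keys are
    guaranteed absent from the patient's WES set.  Calls whose sampled alt
    count is zero are not emitted.
    """
    patients = patients.reset_index(drop=True)
    if len(patients) == 0:
        return _empty_variants()
    if "ttmb" not in patients or patients["ttmb"].isna().any():
        raise DataError("generate_variant_profile requires ttmb for every patient")
    if "log_vaf_location" in patients:
        loc = patients["log_vaf_location"].to_numpy(float)
    else:
        loc = config.vaf_mu + config.vaf_sigma * rng.standard_normal(len(patients))

    n_pat = len(patients)
    lam = patients["ttmb"].to_numpy(float) * config.wes_per_ttmb
    n_wes = rng.poisson(lam)
    total = int(n_wes.sum())
    pat_idx = np.repeat(np.arange(n_pat), n_wes)

    chrom = rng.integers(1, 23, size=total).astype(str)
    pos = rng.integers(1, 100_000_000, size=total)
    ref, alt = _random_alleles(rng, total)
    tissue_vaf = np.clip(
        np.exp(np.log(0.25) + 0.5 * rng.standard_normal(total)), 0.01, 0.6
    )
    wes_alt = rng.binomial(config.wes_depth, tissue_vaf)
    nonsyn = rng.random(total) < 0.75
    dbsnp = rng.random(total) < 0.10
    cosmic = rng.random(total) < 0.15

    keep = wes_alt >= 1
    wes = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy()[pat_idx[keep]],
            "timepoint": "C1",
            "assay": "wes",
            "chrom": chrom[keep],
            "pos": pos[keep],
            "ref": ref[keep],
            "alt": alt[keep],
            "alt_reads": wes_alt[keep],
            "total_reads": config.wes_depth,
            "in_dbsnp": dbsnp[keep],
            "in_cosmic": cosmic[keep],
            "nonsynonymous": nonsyn[keep],
            "truth_label": "tumor_true",
        }
    )
    wes["vaf"] = wes["alt_reads"] / wes["total_reads"]
    wes_pat_idx = pat_idx[keep]

    # plasma capture of the WES truth set
    captured = rng.random(len(wes)) < config.panel_capture
    cap_idx = np.flatnonzero(captured)
    plasma_vaf = np.clip(
        np.exp(
            loc[wes_pat_idx[cap_idx]]
            + config.vaf_within_sigma * rng.standard_normal(len(cap_idx))
        ),
        1e-6,
        0.5,
    )
    panel_alt = rng.binomial(config.panel_depth, plasma_vaf)
    det = panel_alt >= 1
    panel = wes.iloc[cap_idx[det]].copy()
    panel["assay"] = "panel"
    panel["alt_reads"] = panel_alt[det]
    panel["total_reads"] = config.panel_depth
    panel["vaf"] = panel["alt_reads"] / panel["total_reads"]

    artifacts = _draw_artifacts(
        patients, wes, config.panel_fp_rate, config, rng, timepoint="C1"
    )

    out = pd.concat([wes, panel, artifacts], ignore_index=True)
    return out[VARIANT_COLUMNS]


def _draw_artifacts(
    patients: pd.DataFrame,
    wes: pd.DataFrame,
    rate: float,
    config: CohortConfig,
    rng: np.random.Generator,
    timepoint: str,
) -> pd.DataFrame:
    """Panel-only artifact calls with keys strictly outside the WES truth set."""
    n_pat = len(patients)
    n_fp = rng.poisson(rate, size=n_pat) if rate > 0 else np.zeros(n_pat, int)
    total = int(n_fp.sum())
    if total == 0:
        return _empty_variants()
    pat_idx = np.repeat(np.arange(n_pat), n_fp)
    pid = patients["patient_id"].to_numpy()[pat_idx]

    wes_keys = set(
        zip(wes["patient_id"], wes["chrom"], wes["pos"], wes["ref"], wes["alt"])
    )
    chrom = rng.integers(1, 23, size=total).astype(str)
    pos = rng.integers(1, 100_000_000, size=total)
    ref, alt = _random_alleles(rng, total)
    # reject the (vanishingly rare) key collisions with the tumor truth set
    for _ in range(100):
        clash = np.array(
            [(p, c, q, r, a) in wes_keys for p, c, q, r, a in zip(pid, chrom, pos, ref, alt)]
        )
        if not clash.any():
            break
        k = int(clash.sum())
        chrom[clash] = rng.integers(1, 23, size=k).astype(str)
        pos[clash] = rng.integers(1, 100_000_000, size=k)
        ref[clash], alt[clash] = _random_alleles(rng, k)

    vaf = np.clip(
        np.exp(
            config.artifact_vaf_mu
            + config.artifact_vaf_sigma * rng.standard_normal(total)
        ),
        1e-6,
        0.5,
    )
    alt_reads = rng.binomial(config.panel_depth, vaf)
    keep = alt_reads >= 1
    out = pd.DataFrame(
        {
            "patient_id": pid[keep],
            "timepoint": timepoint,
            "assay": "panel",
            "chrom": chrom[keep],
            "pos": pos[keep],
            "ref": ref[keep],
            "alt": alt[keep],
            "alt_reads": alt_reads[keep],
            "total_reads": config.panel_depth,
            "in_dbsnp": False,
            "in_cosmic": False,
            "nonsynonymous": False,
            "truth_label": "artifact",
        }
    )
    out["vaf"] = out["alt_reads"] / out["total_reads"]
    return out[VARIANT_COLUMNS]


def apply_treatment_dynamics(
    c1_calls: pd.DataFrame,
    patients: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    resample_reads: bool = True,
) -> pd.DataFrame:
    """Cycle-2 plasma panel calls derived from the C1 calls.

    Tumor-true variants are multiplied by ``exp(lfc)`` where ``lfc`` is the
    patient's arm x response-class log fold-change draw (plus per-variant
    scatter ``lfc_within_sigma``); artifacts drift by a treatment-independent
    lognormal law.  With ``resample_reads`` the new VAF is re-binomialized
    against the call's total reads and zero-alt-count variants are dropped
    (clearance); without it the scaled VAF is emitted exactly.
    """
    patients = patients.reset_index(drop=True)
    if len(c1_calls) == 0:
        return _empty_variants()
    panel = c1_calls[c1_calls["assay"] == "panel"].reset_index(drop=True)

    # patient-level log fold-change: reuse the generator latent when present
    if "lfc" in patients:
        lfc_by_pid = dict(zip(patients["patient_id"], patients["lfc"]))
    else:
        lfc_by_pid = {}
        for _, row in patients.iterrows():
            arm = row.get("arm")
            if arm not in config.dynamics:
                raise DataError(f"unknown arm {arm!r} for patient {row['patient_id']}")
            bor = row.get("bor")
            if bor not in BOR_CLASSES:
                raise DataError(f"unknown response class {bor!r} for patient {row['patient_id']}")
            law = config.dynamics[arm].for_class(bor in RESPONDER_CLASSES)
            lfc_by_pid[row["patient_id"]] = law.lfc_mu + law.lfc_sigma * rng.standard_normal()

    missing = set(panel["patient_id"]) - set(lfc_by_pid)
    if missing:
        raise DataError(f"no patient record for variant patient_id(s): {sorted(missing)}")

    lfc_pat = panel["patient_id"].map(lfc_by_pid).to_numpy(float)
    is_tumor = (panel["truth_label"] == "tumor_true").to_numpy()
    n = len(panel)
    lfc_var = np.where(
        is_tumor,
        lfc_pat + config.lfc_within_sigma * rng.standard_normal(n),
        config.artifact_lfc_sigma * rng.standard_normal(n),
    )
    vaf2 = np.clip(panel["vaf"].to_numpy(float) * np.exp(lfc_var), 0.0, 0.999)

    c2 = panel.copy()
    c2["timepoint"] = "C2"
    totals = c2["total_reads"].to_numpy(int)
    if resample_reads:
        alt2 = rng.binomial(totals, vaf2)
        keep = alt2 >= 1
        c2["alt_reads"] = alt2
        c2["vaf"] = alt2 / totals
        c2 = c2[keep]
    else:
        c2["vaf"] = vaf2
        c2["alt_reads"] = np.rint(vaf2 * totals).astype(int)

    new_artifacts = _draw_artifacts(
        patients,
        c1_calls[c1_calls["assay"] == "wes"],
        config.panel_fp_rate_new_c2,
        config,
        rng,
        timepoint="C2",
    )
    out = pd.concat([c2, new_artifacts], ignore_index=True)
    return out[VARIANT_COLUMNS]


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def generate_outcomes(
    patients: pd.DataFrame,
    log_baseline: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Outcome columns from the configured proportional-hazards/logistic links.

    ``log_baseline`` is the patient's true log baseline ctDNA level (log of
    the maximum tumor-true plasma VAF at C1; floored for ctDNA-negative
    patients).  OS and progression are exponential with log-hazard::

        log h = log h0 + b_base*(zb - c_b) + b_ratio*(lfc - c_r) + b_arm*1[B]
                + b_ecog*ECOG + b_subgroup[g] + b_tc*tumor_change

    PFS is min(progression, death); censoring is independent exponential.
    The 9-week tumor-size change couples to the true log fold-change and is
    negative for responders by construction.
    """
    patients = patients.reset_index(drop=True)
    n = len(patients)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "bor", "pfs_time", "pfs_event", "os_time", "os_event",
                "tumor_change_9wk", "external_change_score",
            ]
        )
    lfc = patients["lfc"].to_numpy(float)
    bor = patients["bor"].to_numpy()
    center_r = config.expected_log_ratio()
    center_b = config.expected_log_baseline()

    tc_int = np.array([config.tc_intercepts[b] for b in bor])
    tc = tc_int + config.tc_slope * (lfc - center_r) + config.tc_sigma * rng.standard_normal(n)
    is_resp = np.isin(bor, list(RESPONDER_CLASSES))
    tc = np.where(is_resp, np.minimum(tc, -0.5), tc)
    tc = np.clip(tc, -100.0, 300.0)

    sub_beta = np.array([config.beta_subgroup[s] for s in patients["subgroup"]])
    lin = (
        config.beta_baseline * (log_baseline - center_b)
        + config.beta_ratio * (lfc - center_r)
        + config.beta_arm * (patients["arm"].to_numpy() == ARM_CHEMO)
        + config.beta_ecog * patients["ecog_ps"].to_numpy(float)
        + sub_beta
        + config.beta_tumor_change * tc
    )
    h_os = config.base_hazard_os * np.exp(lin)
    h_prog = config.base_hazard_progression * np.exp(lin)

    t_death = rng.exponential(1.0 / h_os)
    t_prog = rng.exponential(1.0 / h_prog)
    t_pfs = np.minimum(t_death, t_prog)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)

    os_time = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)
    pfs_time = np.minimum(t_pfs, t_cens)
    pfs_event = (t_pfs <= t_cens).astype(int)

    if config.emit_external_change_score:
        ext = 100.0 * np.exp(lfc + config.external_score_sigma * rng.standard_normal(n))
    else:
        ext = np.full(n, np.nan)

    return pd.DataFrame(
        {
            "bor": bor,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "os_time": os_time,
            "os_event": os_event,
            "tumor_change_9wk": tc,
            "external_change_score": ext,
        }
    )


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def true_log_baseline(
    patients: pd.DataFrame, c1_calls: pd.DataFrame, config: CohortConfig
) -> np.ndarray:
    """Log of the realized maximum tumor-true plasma VAF at C1, per patient.

    ctDNA-negative patients (no detected tumor-true panel call) get a floor
    ``vaf_mu - 3*vaf_sigma`` so the hazard model stays defined.
    """
    tumor = c1_calls[
        (c1_calls["assay"] == "panel")
        & (c1_calls["timepoint"] == "C1")
        & (c1_calls["truth_label"] == "tumor_true")
    ]
    best = tumor.groupby("patient_id")["vaf"].max()
    floor = config.vaf_mu - _NEGATIVE_FLOOR_SIGMAS * config.vaf_sigma
    vals = patients["patient_id"].map(best)
    out = np.where(vals.notna(), np.log(vals.astype(float).fillna(1.0)), floor)
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full virtual trial (see module docstring).

    Returns a :class:`SyntheticCohort` whose ``truth`` table records the
    per-patient latents (baseline level, log fold-change, latent sensitivity,
    responder flag) so downstream estimators can be checked against the
    parameters that generated the data.
    """
    rng = np.random.default_rng(config.seed)
    patients = _draw_patients(config, rng)
    if len(patients) == 0:
        clinical = pd.DataFrame(columns=CLINICAL_COLUMNS)
        truth = pd.DataFrame(
            columns=["patient_id", "sens", "responder", "log_vaf_location",
                     "lfc", "log_baseline_true"]
        )
        return SyntheticCohort(clinical, _empty_variants(), truth, config)

    c1 = generate_variant_profile(patients, config, rng)
    c2 = apply_treatment_dynamics(c1, patients, config, rng)
    variants = pd.concat([c1, c2], ignore_index=True)

    zb = true_log_baseline(patients, c1, config)
    outcomes = generate_outcomes(patients, zb, config, rng)

    clinical = pd.concat(
        [
            patients[
                ["patient_id", "arm", "ecog_ps", "baseline_tumor_size",
                 "ttmb", "pdl1_cps", "subgroup"]
            ].reset_index(drop=True),
            outcomes.reset_index(drop=True),
        ],
        axis=1,
    )[CLINICAL_COLUMNS]

    truth = patients[
        ["patient_id", "sens", "responder", "log_vaf_location", "lfc"]
    ].copy()
    truth["log_baseline_true"] = zb
    return SyntheticCohort(clinical, variants, truth, config)
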