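"""Generative configuration for the synthetic two-arm ctDNA monitoring trial.

:class:`CohortConfig` holds every parameter of the virtual trial: the tissue
biology (tTMB distribution, PD-L1 CPS), the plasma panel (capture fraction,
sequencing depth, artifact rate), arm- and response-class-specific on-treatment
VAF dynamics, the response model, and the proportional-hazards outcome model.
Defaults emulate a metastatic urothelial carcinoma trial randomising an
immunotherapy-like arm (A) against a chemotherapy-like arm (B), with ctDNA
drawn pre-treatment (C1) and at the second cycle three weeks later (C2).

Configs can be loaded from / dumped to YAML field-for-field; unknown keys are
rejected by name.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

ARM_IMMUNO = "A_immuno"
ARM_CHEMO = "B_chemo"
ARMS = (ARM_IMMUNO, ARM_CHEMO)

BOR_CLASSES = ("CR", "PR", "SD", "PD")
RESPONDER_CLASSES = frozenset({"CR", "PR"})

SUBGROUP_LEVELS = (
    "tmb_high_pdl1_high",
    "tmb_high_pdl1_low",
    "tmb_low_pdl1_high",
    "tmb_low_pdl1_low",
)


@dataclass(frozen=True)
class ResponseClassDynamics:
    """Log fold-change law for C2 VAFs in one arm x response class."""

    lfc_mu: float
    lfc_sigma: float


@dataclass(frozen=True)
class ArmDynamics:
    responder: ResponseClassDynamics
    nonresponder: ResponseClassDynamics

    def for_class(self, responder: bool) -> ResponseClassDynamics:
        return self.responder if responder else self.nonresponder


def _default_dynamics() -> dict[str, ArmDynamics]:
    # Immunotherapy: reductions concentrated in responders, nonresponders sit
    # near baseline.  Chemotherapy: deep reductions even in nonresponders.
    return {
        ARM_IMMUNO: ArmDynamics(
            responder=ResponseClassDynamics(math.log(0.08), 1.2),
            nonresponder=ResponseClassDynamics(0.0, 0.5),
        ),
        ARM_CHEMO: ArmDynamics(
            responder=ResponseClassDynamics(math.log(0.01), 1.2),
            nonresponder=ResponseClassDynamics(math.log(0.10), 1.5),
        ),
    }


def _default_subgroup_betas() -> dict[str, float]:
    return {
        "tmb_high_pdl1_high": -0.4,
        "tmb_high_pdl1_low": 0.0,
        "tmb_low_pdl1_high": 0.0,
        "tmb_low_pdl1_low": 0.0,
    }


def _default_responder_intercepts() -> dict[str, float]:
    # Roughly 30% responders in the immunotherapy arm, 45% under chemotherapy.
    return {ARM_IMMUNO: -0.85, ARM_CHEMO: -0.20}


def _default_tc_intercepts() -> dict[str, float]:
    # 9-week percent tumor-size change by best overall response class.
    return {"CR": -75.0, "PR": -45.0, "SD": -5.0, "PD": 25.0}


@dataclass
class CohortConfig:
    """Parameters of the synthetic trial generator.

    All randomness flows from ``seed``; the same config produces a
    byte-identical cohort.
    """

    n_per_arm: int = 125
    seed: int = 0

    # --- tissue biology ---------------------------------------------------
    #: log-mean / log-sd of the tissue TMB (mut/exome) lognormal.
    ttmb_mu: float = math.log(120.0)
    ttmb_sigma: float = 0.8
    #: mean somatic WES calls emitted per mut/exome of tTMB (desk-scaled).
    wes_per_ttmb: float = 0.30
    #: marginal probability that PD-L1 CPS >= 10.
    prop_pdl1_high: float = 0.30
    #: log-sd of the CPS lognormal around the CPS=10 quantile anchor.
    cps_sigma: float = 1.2

    # --- plasma panel -----------------------------------------------------
    #: probability a WES truth variant is on the plasma panel.
    panel_capture: float = 0.10
    #: mean artifact (panel-only) calls per patient at C1.
    panel_fp_rate: float = 3.0
    #: mean *new* artifact calls appearing at C2 only.
    panel_fp_rate_new_c2: float = 1.0
    panel_depth: int = 10_000
    wes_depth: int = 150
    #: patient-level location/scale of baseline log plasma VAF.
    vaf_mu: float = math.log(0.02)
    vaf_sigma: float = 1.0
    #: variant-level log-VAF scatter around the patient location.
    vaf_within_sigma: float = 0.5
    #: artifact calls: low-VAF lognormal, treatment-independent drift at C2.
    artifact_vaf_mu: float = math.log(0.0015)
    artifact_vaf_sigma: float = 0.5
    artifact_lfc_sigma: float = 0.3

    # --- latent couplings (Gaussian copula correlations) ------------------
    rho_ttmb_vaf: float = 0.4
    rho_ttmb_cps: float = 0.3
    rho_ttmb_sens: float = 0.3

    # --- on-treatment dynamics -------------------------------------------
    dynamics: dict[str, ArmDynamics] = field(default_factory=_default_dynamics)
    #: per-variant log fold-change scatter around the patient draw.
    lfc_within_sigma: float = 0.2

    # --- response model ---------------------------------------------------
    responder_intercept: dict[str, float] = field(
        default_factory=_default_responder_intercepts
    )
    responder_slope: float = 1.0
    prop_cr_given_responder: float = 0.15
    prop_sd_given_nonresponder: float = 0.50

    # --- 9-week tumor-size change coupling --------------------------------
    tc_intercepts: dict[str, float] = field(default_factory=_default_tc_intercepts)
    #: percent change per unit of the patient's true log fold-change.
    tc_slope: float = 10.0
    tc_sigma: float = 12.0

    # --- outcome model (log-hazard scale) ---------------------------------
    #: per unit centered true log baseline maxVAF.
    beta_baseline: float = 0.30
    #: per unit centered true C2/C1 log fold-change.
    beta_ratio: float = 0.50
    #: arm B (chemo) vs arm A.  The default approximately offsets the hazard
    #: advantage the chemo arm would otherwise inherit from its much deeper
    #: fold-change distribution via beta_ratio, so the marginal arms have
    #: broadly similar OS (an overall-negative trial).
    beta_arm: float = 1.30
    #: per ECOG PS point (0/1/2, treated ordinally).
    beta_ecog: float = 0.30
    beta_subgroup: dict[str, float] = field(default_factory=_default_subgroup_betas)
    #: per percent 9-week tumor-size change (0 = no direct radiographic effect).
    beta_tumor_change: float = 0.0
    #: baseline hazards, events/month; the covariate terms inflate the
    #: marginal hazard, so default median OS lands near 8 months.
    base_hazard_os: float = 0.025
    base_hazard_progression: float = 0.10
    #: independent exponential censoring, events/month (0 = none).
    censor_rate: float = 0.02

    # --- baseline covariates ----------------------------------------------
    ecog_probs: tuple[float, float, float] = (0.40, 0.50, 0.10)
    tumor_size_mu: float = math.log(70.0)
    tumor_size_sigma: float = 0.5

    #: emit an opaque external change score (MR-score stand-in slot).
    emit_external_change_score: bool = True
    external_score_sigma: float = 0.5

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_per_arm, (int,)) or self.n_per_arm < 0:
            raise ConfigError(f"n_per_arm must be a nonnegative integer, got {self.n_per_arm!r}")
        positive = [
            "ttmb_sigma", "wes_per_ttmb", "cps_sigma", "panel_depth", "wes_depth",
            "vaf_sigma", "responder_slope",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        nonnegative = [
            "panel_fp_rate", "panel_fp_rate_new_c2", "vaf_within_sigma",
            "artifact_vaf_sigma", "artifact_lfc_sigma", "lfc_within_sigma",
            "tc_sigma", "base_hazard_os", "base_hazard_progression",
            "censor_rate", "external_score_sigma",
        ]
        for name in nonnegative:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 <= self.prop_pdl1_high <= 1.0:
            raise ConfigError(f"prop_pdl1_high must lie in [0, 1], got {self.prop_pdl1_high!r}")
        for name in ("panel_capture", "prop_cr_given_responder", "prop_sd_given_nonresponder"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {getattr(self, name)!r}")
        for name in ("rho_ttmb_vaf", "rho_ttmb_cps", "rho_ttmb_sens"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must lie in (-1, 1), got {getattr(self, name)!r}")
        if self.rho_ttmb_vaf**2 + self.rho_ttmb_cps**2 + self.rho_ttmb_sens**2 >= 1.0:
            raise ConfigError(
                "latent correlations rho_ttmb_* define a non-positive-definite copula"
            )
        if set(self.dynamics) != set(ARMS):
            raise ConfigError(f"dynamics must define arms {ARMS}, got {sorted(self.dynamics)}")
        for arm, dyn in self.dynamics.items():
            for cls in (dyn.responder, dyn.nonresponder):
                if cls.lfc_sigma < 0:
                    raise ConfigError(f"dynamics[{arm}] lfc_sigma must be >= 0")
        if set(self.responder_intercept) != set(ARMS):
            raise ConfigError("responder_intercept must define both arms")
        if set(self.beta_subgroup) != set(SUBGROUP_LEVELS):
            raise ConfigError(f"beta_subgroup must define levels {SUBGROUP_LEVELS}")
        if set(self.tc_intercepts) != set(BOR_CLASSES):
            raise ConfigError(f"tc_intercepts must define classes {BOR_CLASSES}")
        if abs(sum(self.ecog_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.ecog_probs):
            raise ConfigError(f"ecog_probs must be a probability vector, got {self.ecog_probs!r}")

    # ------------------------------------------------------------------
    @classmethod
    def null(cls, **overrides: Any) -> "CohortConfig":
        """A config in which every outcome association is switched off.

        All outcome betas are 0, latent couplings are 0 and the on-treatment
        dynamics are identical across arms and response classes, so every
        ctDNA metric is independent of BOR, PFS and OS by construction.
        """
        identical = ArmDynamics(
            responder=ResponseClassDynamics(math.log(0.5), 0.8),
            nonresponder=ResponseClassDynamics(math.log(0.5), 0.8),
        )
        base: dict[str, Any] = dict(
            beta_baseline=0.0,
            beta_ratio=0.0,
            beta_arm=0.0,
            beta_ecog=0.0,
            beta_subgroup={k: 0.0 for k in SUBGROUP_LEVELS},
            beta_tumor_change=0.0,
            rho_ttmb_vaf=0.0,
            rho_ttmb_cps=0.0,
            rho_ttmb_sens=0.0,
            dynamics={ARM_IMMUNO: identical, ARM_CHEMO: identical},
        )
        base.update(overrides)
        return cls(**base)

    # ------------------------------------------------------------------
    def replace(self, **changes: Any) -> "CohortConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            return obj

        return convert(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        kwargs = dict(raw)
        if "dynamics" in kwargs:
            kwargs["dynamics"] = {
                arm: ArmDynamics(
                    responder=ResponseClassDynamics(**d["responder"]),
                    nonresponder=ResponseClassDynamics(**d["nonresponder"]),
                )
                if isinstance(d, dict)
                else d
                for arm, d in kwargs["dynamics"].items()
            }
        if "ecog_probs" in kwargs:
            kwargs["ecog_probs"] = tuple(kwargs["ecog_probs"])
        try:
            return cls(**kwargs)
        except TypeError as exc:  # malformed nested structure
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    # ------------------------------------------------------------------
    # Theoretical centering constants for the hazard linear predictor.
    def expected_log_baseline(self) -> float:
        """Config-implied centering constant for log baseline maxVAF."""
        return self.vaf_mu

    def expected_log_ratio(self) -> float:
        """Config-implied mean log fold-change, pooled over arms and classes."""
        total = 0.0
        for arm in ARMS:
            p_resp = 1.0 / (1.0 + math.exp(-self.responder_intercept[arm]))
            dyn = self.dynamics[arm]
            total += p_resp * dyn.responder.lfc_mu + (1 - p_resp) * dyn.nonresponder.lfc_mu
        return total / len(ARMS)
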