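"""ctDNA and tissue biomarker metrics from harmonized variant calls.

Implements the monitoring metric set: tumor-informed maxVAF (plasma panel
calls confirmed in the patient's tissue WES), tumor-uninformed maxVAF, the
C1-anchored tumor-uninformed meanVAF (on-treatment variants absent at
baseline are ignored; baseline variants absent on treatment count as zeros),
C2/C1 change ratios with clearance and evaluability flags, blood TMB, tissue
TMB with its filter chain, the PD-L1 combined positive score and the
TMBxPD-L1 four-level subgroup factor.

Variant identity is an exact left-normalized ``(chrom, pos, ref, alt)`` key:
a "chr" prefix is stripped, shared allele suffixes then prefixes are trimmed
to the minimal representation, and the position is shifted accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import DataError

TTMB_CUTOFF = 175.0   # mut/exome
CPS_CUTOFF = 10.0

#: metrics evaluated at baseline and for C2/C1 monitoring
BASELINE_METRICS = ("maxvaf_informed", "maxvaf_uninformed")
MONITORING_METRICS = ("maxvaf_informed", "maxvaf_uninformed", "meanvaf_uninformed")

KEY_COLUMNS = ["key_chrom", "key_pos", "key_ref", "key_alt"]


class VariantKey(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ChangeResult:
    """C2/C1 change for one metric of one patient."""

    ratio: Optional[float]
    cleared: Optional[bool]
    evaluable: bool


def normalize_key(chrom, pos, ref, alt) -> VariantKey:
    """Canonical left-normalized variant key.

    Strips a leading ``chr``, uppercases alleles, trims any shared suffix and
    then any shared prefix (keeping at least one base on each side), and
    shifts ``pos`` right by the number of prefix bases removed.  Idempotent.
    """
    chrom = str(chrom)
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    ref = str(ref).upper()
    alt = str(alt).upper()
    if not ref or not alt:
        raise DataError(f"empty allele in variant {chrom}:{pos} {ref!r}>{alt!r}")
    if ref == alt:
        raise DataError(f"ref equals alt in variant {chrom}:{pos} {ref}>{alt}")
    pos = int(pos)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def add_keys(calls: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``calls`` with normalized key columns appended."""
    out = calls.copy()
    if len(out) == 0:
        for col in KEY_COLUMNS:
            out[col] = pd.Series(dtype=object)
        return out
    chrom = out["chrom"].astype(str).str.replace(r"(?i)^chr", "", regex=True)
    ref = out["ref"].astype(str).str.upper()
    alt = out["alt"].astype(str).str.upper()
    pos = out["pos"].astype(int)
    simple = (ref.str.len() == 1) & (alt.str.len() == 1)
    if bool(simple.all()):
        if (ref == alt).any():
            bad = out[ref == alt].iloc[0]
            raise DataError(f"ref equals alt in variant {bad['chrom']}:{bad['pos']}")
        out["key_chrom"], out["key_pos"] = chrom, pos
        out["key_ref"], out["key_alt"] = ref, alt
    else:
        keys = [
            normalize_key(c, p, r, a)
            for c, p, r, a in zip(chrom, pos, ref, alt)
        ]
        out["key_chrom"] = [k.chrom for k in keys]
        out["key_pos"] = [k.pos for k in keys]
        out["key_ref"] = [k.ref for k in keys]
        out["key_alt"] = [k.alt for k in keys]
    return out


def _single_patient(df: pd.DataFrame, what: str) -> None:
    ids = df["patient_id"].unique()
    if len(ids) > 1:
        raise DataError(f"{what} mixes patient_ids: {sorted(ids)}")


def tumor_informed_filter(panel_calls: pd.DataFrame, wes_calls: pd.DataFrame) -> pd.DataFrame:
    """Plasma panel calls confirmed in the patient's tissue WES set.

    Membership is by exact normalized key and is timepoint-agnostic on the
    WES side (tissue is pretreatment only).  Both inputs must belong to one
    and the same patient.
    """
    _single_patient(panel_calls, "panel_calls")
    _single_patient(wes_calls, "wes_calls")
    if len(panel_calls) and len(wes_calls):
        p, w = panel_calls["patient_id"].iloc[0], wes_calls["patient_id"].iloc[0]
        if p != w:
            raise DataError(f"panel patient {p!r} does not match WES patient {w!r}")
    if len(panel_calls) == 0 or len(wes_calls) == 0:
        return panel_calls.iloc[0:0]
    panel = add_keys(panel_calls)
    wes_keys = add_keys(wes_calls)[KEY_COLUMNS].drop_duplicates()
    merged = panel.merge(wes_keys, on=KEY_COLUMNS, how="inner")
    return merged[panel_calls.columns]


def max_vaf(calls: pd.DataFrame) -> float:
    """Maximum VAF over a call set; 0.0 for an empty set (ctDNA-negative)."""
    if len(calls) == 0:
        return 0.0
    return float(calls["vaf"].max())


def mean_vaf_c1_anchored(
    c1_calls: pd.DataFrame, c2_calls: pd.DataFrame
) -> tuple[float, float]:
    """C1-anchored mean VAF at both timepoints.

    The denominator at both timepoints is the number of distinct C1 variant
    keys.  At C2, a baseline variant without an on-treatment call contributes
    zero; on-treatment-only variants are ignored.  With no C1 variants the
    metric is undefined: returns ``(nan, nan)``.
    """
    if len(c1_calls) == 0:
        return (float("nan"), float("nan"))
    c1 = add_keys(c1_calls).groupby(KEY_COLUMNS, as_index=False)["vaf"].mean()
    m1 = float(c1["vaf"].mean())
    if len(c2_calls) == 0:
        return (m1, 0.0)
    c2 = add_keys(c2_calls).groupby(KEY_COLUMNS, as_index=False)["vaf"].mean()
    joined = c1.merge(c2, on=KEY_COLUMNS, how="left", suffixes=("_c1", "_c2"))
    m2 = float(joined["vaf_c2"].fillna(0.0).mean())
    return (m1, m2)


def c2c1_change(c1_value: float, c2_value: float) -> ChangeResult:
    """C2/C1 ratio with clearance and evaluability flags.

    Monitoring requires a detectable baseline level: with ``c1 == 0`` the
    ratio is undefined and the patient is not evaluable for this metric.
    """
    if c1_value < 0 or c2_value < 0:
        raise DataError(f"negative metric value: C1={c1_value}, C2={c2_value}")
    if c1_value == 0:
        return ChangeResult(ratio=None, cleared=None, evaluable=False)
    return ChangeResult(
        ratio=c2_value / c1_value, cleared=(c2_value == 0.0), evaluable=True
    )


def compute_ttmb(wes_calls: pd.DataFrame) -> int:
    """Tissue TMB: somatic nonsynonymous SNVs surviving the filter chain.

    Filters: single-nucleotide substitutions only; at least 4 mutant reads;
    calls in dbSNP but not in COSMIC removed; nonsynonymous only.  Missing
    annotation flags are a data error (fail loud, never silently skip).
    """
    if len(wes_calls) == 0:
        return 0
    for col in ("in_dbsnp", "in_cosmic", "nonsynonymous", "alt_reads"):
        if col not in wes_calls.columns:
            raise DataError(f"WES calls lack required column {col!r}")
        bad = wes_calls[wes_calls[col].isna()]
        if len(bad):
            row = bad.iloc[0]
            raise DataError(
                f"missing {col} annotation on call "
                f"{row.get('patient_id', '?')} {row['chrom']}:{row['pos']}"
            )
    ref_len = wes_calls["ref"].astype(str).str.len()
    alt_len = wes_calls["alt"].astype(str).str.len()
    is_snv = (ref_len == 1) & (alt_len == 1)
    dbsnp_only = wes_calls["in_dbsnp"].astype(bool) & ~wes_calls["in_cosmic"].astype(bool)
    keep = (
        is_snv
        & wes_calls["nonsynonymous"].astype(bool)
        & (wes_calls["alt_reads"] >= 4)
        & ~dbsnp_only
    )
    return int(keep.sum())


def compute_btmb(panel_c1_calls: pd.DataFrame) -> int:
    """Blood TMB: number of distinct somatic panel variant keys at C1."""
    if len(panel_c1_calls) == 0:
        return 0
    return int(len(add_keys(panel_c1_calls)[KEY_COLUMNS].drop_duplicates()))


def compute_cps(n_staining_cells: float, n_viable_tumor_cells: float) -> float:
    """PD-L1 combined positive score: staining cells per 100 viable tumor cells."""
    if n_viable_tumor_cells <= 0:
        raise DataError("CPS denominator (viable tumor cells) must be positive")
    if n_staining_cells < 0:
        raise DataError("CPS numerator must be nonnegative")
    return 100.0 * n_staining_cells / n_viable_tumor_cells


def subgroup_factor(ttmb: float, cps: float) -> str:
    """Four-level TMBxPD-L1 factor; boundary values belong to the high level."""
    tmb_high = ttmb >= TTMB_CUTOFF
    pdl1_high = cps >= CPS_CUTOFF
    return (
        f"tmb_{'high' if tmb_high else 'low'}_pdl1_{'high' if pdl1_high else 'low'}"
    )


# ---------------------------------------------------------------------------
# cohort-level profile table
# ---------------------------------------------------------------------------

def _agg_max(panel: pd.DataFrame, mask: np.ndarray, index: pd.Index) -> dict[str, pd.Series]:
    """Per-patient max VAF at each timepoint over the masked panel subset."""
    out = {}
    sub = panel[mask]
    for tp in ("C1", "C2"):
        g = sub[sub["timepoint"] == tp].groupby("patient_id")["vaf"].max()
        out[tp] = g.reindex(index).fillna(0.0)
    return out


def compute_profiles(
    variants: pd.DataFrame, patient_ids: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Per-patient ctDNA metric profile table.

    One row per patient with columns ``<metric>_c1``, ``<metric>_c2``,
    ``ratio_<metric>``, ``positive_c1_<metric>``, ``cleared_c2_<metric>`` and
    ``evaluable_<metric>`` for each metric in :data:`MONITORING_METRICS`,
    plus ``btmb`` and the WES-derived ``ttmb_wes``.  Metrics follow the
    emptiness conventions of the scalar operations (empty set -> maxVAF 0;
    no baseline variants -> meanVAF and all ratios undefined).
    """
    if patient_ids is None:
        index = pd.Index(sorted(variants["patient_id"].unique()), name="patient_id")
    else:
        index = pd.Index(list(patient_ids), name="patient_id")

    panel = add_keys(variants[variants["assay"] == "panel"])
    wes = add_keys(variants[variants["assay"] == "wes"])

    # tumor-informed membership: panel key present in the same patient's WES set
    wes_keys = wes[["patient_id", *KEY_COLUMNS]].drop_duplicates()
    informed = (
        panel.reset_index()
        .merge(wes_keys, on=["patient_id", *KEY_COLUMNS], how="left", indicator=True)
        .set_index("index")["_merge"]
        .eq("both")
        .reindex(panel.index)
        .to_numpy()
        if len(panel)
        else np.zeros(0, dtype=bool)
    )

    prof = pd.DataFrame(index=index)

    max_inf = _agg_max(panel, informed, index)
    max_uni = _agg_max(panel, np.ones(len(panel), dtype=bool), index)
    prof["maxvaf_informed_c1"], prof["maxvaf_informed_c2"] = max_inf["C1"], max_inf["C2"]
    prof["maxvaf_uninformed_c1"], prof["maxvaf_uninformed_c2"] = max_uni["C1"], max_uni["C2"]

    # C1-anchored uninformed mean VAF, vectorized over patients
    c1 = panel[panel["timepoint"] == "C1"]
    c2 = panel[panel["timepoint"] == "C2"]
    c1d = c1.groupby(["patient_id", *KEY_COLUMNS], as_index=False)["vaf"].mean()
    c2d = c2.groupby(["patient_id", *KEY_COLUMNS], as_index=False)["vaf"].mean()
    joined = c1d.merge(
        c2d, on=["patient_id", *KEY_COLUMNS], how="left", suffixes=("_c1", "_c2")
    )
    grp = joined.groupby("patient_id")
    prof["meanvaf_uninformed_c1"] = grp["vaf_c1"].mean().reindex(index)
    prof["meanvaf_uninformed_c2"] = (
        joined.assign(v2=joined["vaf_c2"].fillna(0.0)).groupby("patient_id")["v2"]
        .mean()
        .reindex(index)
    )

    for metric in MONITORING_METRICS:
        c1v = prof[f"{metric}_c1"]
        c2v = prof[f"{metric}_c2"]
        evaluable = c1v > 0
        prof[f"positive_c1_{metric}"] = evaluable.fillna(False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(evaluable, c2v / c1v, np.nan)
        prof[f"ratio_{metric}"] = ratio
        prof[f"cleared_c2_{metric}"] = np.where(
            evaluable, (c2v == 0) & evaluable, None
        )
        prof[f"evaluable_{metric}"] = evaluable.fillna(False)

    # vectorized equivalents of compute_btmb / compute_ttmb per patient
    c1_panel = panel[panel["timepoint"] == "C1"]
    btmb = (
        c1_panel[["patient_id", *KEY_COLUMNS]]
        .drop_duplicates()
        .groupby("patient_id")
        .size()
    )
    prof["btmb"] = btmb.reindex(index).fillna(0).astype(int)

    if len(wes):
        for col in ("in_dbsnp", "in_cosmic", "nonsynonymous"):
            if wes[col].isna().any():
                row = wes[wes[col].isna()].iloc[0]
                raise DataError(
                    f"missing {col} annotation on call "
                    f"{row['patient_id']} {row['chrom']}:{row['pos']}"
                )
        is_snv = (wes["ref"].astype(str).str.len() == 1) & (
            wes["alt"].astype(str).str.len() == 1
        )
        dbsnp_only = wes["in_dbsnp"].astype(bool) & ~wes["in_cosmic"].astype(bool)
        keep = (
            is_snv
            & wes["nonsynonymous"].astype(bool)
            & (wes["alt_reads"] >= 4)
            & ~dbsnp_only
        )
        ttmb = wes[keep].groupby("patient_id").size()
    else:
        ttmb = pd.Series(dtype=int)
    prof["ttmb_wes"] = ttmb.reindex(index).fillna(0).astype(int)
    return prof.reset_index()
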