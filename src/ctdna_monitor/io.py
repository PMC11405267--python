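"""File formats, pipeline orchestration and run manifests.

Two variant interchange dialects: a long-format TSV (one row per call,
columns as in :data:`ctdna_monitor.cohort.VARIANT_COLUMNS`) and VCF (one
file per patient x timepoint x assay, ``##SAMPLE``/``##TIMEPOINT``/
``##ASSAY`` header lines, FORMAT ``AD``/``DP``/``AF``, annotation flags in
INFO).  Both round-trip losslessly on canonical records; multi-allelic VCF
records are split into one call per alternate allele.

``run_pipeline`` ties the stages together (simulate -> metrics ->
associations -> reports) and writes a :class:`RunManifest` with the config
hash, seeds and data-file digests so identical configs can be shown to
produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .cohort import CLINICAL_COLUMNS, VARIANT_COLUMNS, SyntheticCohort, generate_cohort
from .config import CohortConfig
from .errors import DataError

log = logging.getLogger("ctdna_monitor")

_CONTIGS = [str(c) for c in range(1, 23)] + ["X", "Y"]
_BOOL_COLUMNS = ["in_dbsnp", "in_cosmic", "nonsynonymous"]


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def write_clinical(clinical: pd.DataFrame, path: Path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_clinical(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns and c != "external_change_score"]
    if missing:
        raise DataError(f"clinical table {path} lacks column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# variant calls
# ---------------------------------------------------------------------------

def write_variants_tsv(variants: pd.DataFrame, path: Path) -> None:
    out = variants[VARIANT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


def _read_variants_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed TSV {path}: {exc}") from exc
    if len(df) == 0 and list(df.columns) == []:
        raise DataError(f"{path} has no header")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"variant TSV {path} lacks column(s): {missing}")
    for i, row in df.iterrows():
        if not (0 <= row["alt_reads"] <= row["total_reads"]):
            raise DataError(f"{path} line {i + 2}: alt_reads outside [0, total_reads]")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    return df[VARIANT_COLUMNS]


def write_variants_vcf(variants: pd.DataFrame, directory: Path) -> list[Path]:
    """One VCF per patient x timepoint x assay under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (pid, tp, assay), group in variants.groupby(
        ["patient_id", "timepoint", "assay"], sort=True
    ):
        header = pysam.VariantHeader()
        header.add_line(f"##SAMPLE={pid}")
        header.add_line(f"##TIMEPOINT={tp}")
        header.add_line(f"##ASSAY={assay}")
        for contig in _CONTIGS:
            header.add_line(f"##contig=<ID={contig}>")
        header.add_line('##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="In dbSNP">')
        header.add_line('##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="In COSMIC">')
        header.add_line('##INFO=<ID=NONSYN,Number=0,Type=Flag,Description="Nonsynonymous">')
        header.add_line(
            '##INFO=<ID=TRUTH,Number=1,Type=String,Description="Generator truth label">'
        )
        header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
        header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
        header.add_line('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">')
        header.add_sample(str(pid))
        path = directory / f"{pid}_{tp}_{assay}.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for _, row in group.sort_values(["chrom", "pos", "ref", "alt"]).iterrows():
                rec = vcf.new_record(
                    contig=str(row["chrom"]),
                    start=int(row["pos"]) - 1,
                    stop=int(row["pos"]) - 1 + len(str(row["ref"])),
                    alleles=(str(row["ref"]), str(row["alt"])),
                )
                if bool(row["in_dbsnp"]):
                    rec.info["DBSNP"] = True
                if bool(row["in_cosmic"]):
                    rec.info["COSMIC"] = True
                if bool(row["nonsynonymous"]):
                    rec.info["NONSYN"] = True
                label = row.get("truth_label")
                if isinstance(label, str) and label:
                    rec.info["TRUTH"] = label
                alt_reads = int(row["alt_reads"])
                total = int(row["total_reads"])
                rec.samples[str(pid)]["AD"] = (total - alt_reads, alt_reads)
                rec.samples[str(pid)]["DP"] = total
                rec.samples[str(pid)]["AF"] = float(alt_reads / total)
                vcf.write(rec)
        paths.append(path)
    return paths


def _header_value(header: pysam.VariantHeader, key: str) -> Optional[str]:
    for rec in header.records:
        text = str(rec).strip()
        if text.startswith(f"##{key}="):
            return text.split("=", 1)[1]
    return None


def _read_variants_vcf(path: Path) -> pd.DataFrame:
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        pid = _header_value(vcf.header, "SAMPLE") or (
            list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        )
        tp = _header_value(vcf.header, "TIMEPOINT")
        assay = _header_value(vcf.header, "ASSAY")
        if pid is None:
            raise DataError(f"VCF {path} carries no sample")
        rows = []
        for line_no, rec in enumerate(vcf, start=1):
            sample = rec.samples[list(rec.samples)[0]]
            ad = sample.get("AD")
            dp = sample.get("DP")
            if rec.alts is None:
                continue
            for k, alt in enumerate(rec.alts):
                alt_reads = int(ad[k + 1]) if ad is not None and len(ad) > k + 1 else 0
                total = int(dp) if dp is not None else int(sum(a for a in ad if a is not None))
                if not 0 <= alt_reads <= total:
                    raise DataError(f"{path} record {line_no}: AD outside [0, DP]")
                rows.append(
                    {
                        "patient_id": pid,
                        "timepoint": tp,
                        "assay": assay,
                        "chrom": rec.contig,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "alt_reads": alt_reads,
                        "total_reads": total,
                        "vaf": alt_reads / total if total else float("nan"),
                        "in_dbsnp": "DBSNP" in rec.info,
                        "in_cosmic": "COSMIC" in rec.info,
                        "nonsynonymous": "NONSYN" in rec.info,
                        "truth_label": rec.info["TRUTH"] if "TRUTH" in rec.info else None,
                    }
                )
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.DataFrame(rows)[VARIANT_COLUMNS]


def read_variants(path: Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read variant calls from one file in the given dialect ('tsv' or 'vcf')."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise DataError(f"unknown variant dialect {dialect!r}")


# ---------------------------------------------------------------------------
# manifest and pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    version: str
    config_hash: str
    seed: int
    row_counts: dict
    digests: dict
    timestamp: str

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def config_hash(config: CohortConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()


def write_cohort(
    cohort: SyntheticCohort, out_dir: Path, variant_format: str = "tsv"
) -> dict[str, Path]:
    """Write clinical TSV, variant calls and the ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["clinical"] = out_dir / "clinical.tsv"
    write_clinical(cohort.clinical, paths["clinical"])
    if variant_format == "tsv":
        paths["variants"] = out_dir / "variants.tsv"
        write_variants_tsv(cohort.variants, paths["variants"])
    elif variant_format == "vcf":
        vcf_dir = out_dir / "vcf"
        write_variants_vcf(cohort.variants, vcf_dir)
        paths["variants"] = vcf_dir
    else:
        raise DataError(f"unknown variant format {variant_format!r}")
    truth_path = out_dir / "truth.json"
    payload = {
        "config": cohort.config.to_dict(),
        "per_patient": cohort.truth.to_dict(orient="records"),
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
    paths["truth"] = truth_path
    return paths


def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: Path,
    variant_format: str = "tsv",
    make_plots: bool = True,
) -> RunManifest:
    """Simulate, compute metrics, run the association plan and write reports.

    Outputs under ``out_dir``: ``clinical.tsv``, ``variants.tsv`` (or
    ``vcf/``), ``profiles.tsv``, ``results.tsv``, ``truth.json``, optional KM
    plots, and ``manifest.json``.  Raises on any stage error after removing
    partial outputs is *not* attempted; instead the manifest is only written
    on success, so its absence marks an invalid tree.
    """
    from .association import CtdnaAssociationModel
    from .metrics import MONITORING_METRICS, compute_profiles

    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(str(config))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("simulate: generating cohort (n_per_arm=%d)", config.n_per_arm)
    cohort = generate_cohort(config)
    paths = write_cohort(cohort, out_dir, variant_format=variant_format)
    log.info(
        "simulate: %d patients, %d variant calls",
        len(cohort.clinical), len(cohort.variants),
    )

    profiles = compute_profiles(cohort.variants, patient_ids=cohort.clinical["patient_id"])
    profiles_path = out_dir / "profiles.tsv"
    profiles.to_csv(profiles_path, sep="\t", index=False)
    for metric in MONITORING_METRICS:
        log.info(
            "metrics: %d/%d patients evaluable for %s monitoring",
            int(profiles[f"evaluable_{metric}"].sum()), len(profiles), metric,
        )

    model = CtdnaAssociationModel.from_cohort(cohort)
    results = model.fit()
    results_path = out_dir / "results.tsv"
    results.summary().to_csv(results_path, sep="\t", index=False, float_format="%.6g")
    log.info("associate: %d tests run", len(results.results))

    if make_plots and len(cohort.clinical):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric in MONITORING_METRICS:
            col = f"ratio_{metric}"
            try:
                ax = results.plot_km(col, "OS")
            except DataError:
                continue
            ax.figure.savefig(out_dir / f"km_os_{col}.png", dpi=100)
            plt.close(ax.figure)

    data_files = [paths["clinical"], profiles_path, results_path, paths["truth"]]
    if variant_format == "tsv":
        data_files.append(paths["variants"])
    manifest = RunManifest(
        version=__version__,
        config_hash=config_hash(config),
        seed=config.seed,
        row_counts={
            "patients": int(len(cohort.clinical)),
            "variant_calls": int(len(cohort.variants)),
            "tests": len(results.results),
        },
        digests={p.name: _sha256(p) for p in data_files},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
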