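"""Readers/writers for the pipeline's external formats.

Genotypes travel either as VCF v4.2 (GT fields, one sample per patient;
variants keyed by rsid, positions synthetic) or as a TSV matrix dialect:
tab-separated, UTF-8, mandatory header, rows = patient ids, columns = rsids,
cells = ``X/Y`` allele pairs with ``./.`` for missing. Covariates and
trajectories are plain CSV; association results are written as deterministic
TSV/JSON files.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .association import AssociationResult
from .errors import AlleleMismatchError, InvalidArgumentError, UnknownSNPError
from .genotypes import MISSING, GenotypeMatrix, call_to_dosage
from .manifest import SNPManifest

# --------------------------------------------------------------------------
# genotype TSV dialect
# --------------------------------------------------------------------------
def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = genotypes.to_frame()
    frame.to_csv(path, sep="\t", index=True)


def read_genotype_tsv(path: str | Path, manifest: SNPManifest) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="patient_id", dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in manifest]
    if unknown:
        raise UnknownSNPError(f"rsids not in manifest: {unknown}")
    sub = manifest.subset(list(frame.columns))
    dosage = np.empty((len(frame), len(sub)), dtype=np.int8)
    bad: list[str] = []
    for j, entry in enumerate(sub):
        for i, call in enumerate(frame[entry.rsid]):
            try:
                dosage[i, j] = call_to_dosage(call, entry.ref, entry.alt)
            except AlleleMismatchError:
                bad.append(f"{frame.index[i]}/{entry.rsid}: {call}")
    if bad:
        raise AlleleMismatchError(
            f"{len(bad)} genotype call(s) mismatch the manifest alleles", records=bad
        )
    return GenotypeMatrix(
        patient_ids=[str(i) for i in frame.index], manifest=sub, dosage=dosage
    )


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------
def write_genotype_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """VCF v4.2 with GT fields; positions are synthetic (panel order)."""
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line('##contig=<ID=1,length=1000000>')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for pid in genotypes.patient_ids:
        header.add_sample(pid)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, entry in enumerate(genotypes.manifest, start=1):
            rec = vcf.new_record(
                contig="1", start=pos - 1, stop=pos, id=entry.rsid,
                alleles=(entry.ref, entry.alt),
            )
            dosage = genotypes.dosage_of(entry.rsid)
            for i, pid in enumerate(genotypes.patient_ids):
                rec.samples[pid]["GT"] = gt_map[int(dosage[i])]
            vcf.write(rec)


def read_genotype_vcf(path: str | Path, manifest: SNPManifest) -> GenotypeMatrix:
    """Read GT dosages from a VCF, re-orienting to the manifest's ref allele.

    Records whose REF/ALT letters are swapped relative to the manifest have
    their dosages flipped; allele letters outside the manifest pair raise
    :class:`AlleleMismatchError`.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rsids: list[str] = []
        columns: list[np.ndarray] = []
        bad: list[str] = []
        for rec in vcf:
            rsid = rec.id
            if rsid is None or rsid not in manifest:
                raise UnknownSNPError(f"VCF record id {rsid!r} not in manifest")
            entry = manifest[rsid]
            alts = rec.alts or ()
            alleles = {rec.ref, *alts}
            if alleles == {entry.ref, entry.alt}:
                flipped = rec.ref == entry.alt
            elif alleles == {entry.ref}:  # monomorphic record
                flipped = False
            else:
                bad.append(f"{rsid}: VCF alleles {sorted(alleles)}")
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    d = int(sum(gt))
                    col[i] = 2 - d if flipped else d
            rsids.append(rsid)
            columns.append(col)
    if bad:
        raise AlleleMismatchError(
            f"{len(bad)} VCF record(s) mismatch the manifest alleles", records=bad
        )
    return GenotypeMatrix(
        patient_ids=samples, manifest=manifest.subset(rsids),
        dosage=np.column_stack(columns),
    )


def read_genotype_matrix(path: str | Path, manifest: SNPManifest) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` or the TSV matrix dialect."""
    p = Path(path)
    if p.suffix.lower() == ".vcf":
        return read_genotype_vcf(p, manifest)
    return read_genotype_tsv(p, manifest)


# --------------------------------------------------------------------------
# covariates & trajectories
# --------------------------------------------------------------------------
def write_covariates_csv(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, index=True)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="patient_id")
    for col in ("t2d", "htn"):
        frame[col] = frame[col].astype(bool)
    return frame


def write_trajectories_csv(trajectories, path: str | Path) -> None:
    from .simulate import trajectories_to_frame

    frame = (
        trajectories
        if isinstance(trajectories, pd.DataFrame)
        else trajectories_to_frame(trajectories)
    )
    frame.to_csv(path, index=False)


def read_trajectories_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"patient_id", "visit_year", "weight_kg"}
    if not required.issubset(frame.columns):
        raise InvalidArgumentError(f"trajectory CSV needs columns {sorted(required)}")
    frame["patient_id"] = frame["patient_id"].astype(str)
    return frame


# --------------------------------------------------------------------------
# association results
# --------------------------------------------------------------------------
def results_model_table(results: list[AssociationResult]) -> pd.DataFrame:
    """One row per SNP x phenotype x fitted model."""
    rows = []
    for r in results:
        for model, fit in r.fits.items():
            rows.append(
                {
                    "phenotype": r.phenotype,
                    "gene": r.gene,
                    "rsid": r.rsid,
                    "model": model.value,
                    "n_used": fit.n_used,
                    "aic": fit.aic,
                    "p_lrt": fit.p_value,
                    "contrasts": ",".join(c.name for c in fit.contrasts),
                    "estimates": ",".join(f"{c.estimate:.6g}" for c in fit.contrasts),
                    "ci_lows": ",".join(f"{c.ci_low:.6g}" for c in fit.contrasts),
                    "ci_highs": ",".join(f"{c.ci_high:.6g}" for c in fit.contrasts),
                    "is_best": model == r.best_model,
                }
            )
        for model, reason in r.skipped.items():
            rows.append(
                {
                    "phenotype": r.phenotype, "gene": r.gene, "rsid": r.rsid,
                    "model": model.value, "n_used": r.n_used,
                    "aic": np.nan, "p_lrt": np.nan,
                    "contrasts": "", "estimates": "", "ci_lows": "", "ci_highs": "",
                    "is_best": False,
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["phenotype", "gene", "rsid", "model"]).reset_index(drop=True)
    return frame


def results_best_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Best-model summary: one row per SNP x phenotype."""
    rows = []
    for r in results:
        best = r.best_fit
        rows.append(
            {
                "phenotype": r.phenotype,
                "gene": r.gene,
                "rsid": r.rsid,
                "best_model": r.best_model.value if r.best_model else "",
                "p_value": r.p_value,
                "p_adjusted": np.nan if r.p_adjusted is None else r.p_adjusted,
                "aic": best.aic if best else np.nan,
                "estimate": best.contrasts[-1].estimate if best else np.nan,
                "ci_low": best.contrasts[-1].ci_low if best else np.nan,
                "ci_high": best.contrasts[-1].ci_high if best else np.nan,
                "significant": r.significant,
                "risk_allele": r.risk_allele or "",
                "hwe_p": r.hwe_p,
                "call_rate": r.call_rate,
                "qc_pass": r.qc_pass,
                "n_used": r.n_used,
                "note": r.note or r.risk_rule_note,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["phenotype", "gene", "rsid"]).reset_index(drop=True)
    return frame


_BEST_COLUMNS = [
    "phenotype", "gene", "rsid", "best_model", "p_value", "p_adjusted", "aic",
    "estimate", "ci_low", "ci_high", "significant", "risk_allele", "hwe_p",
    "call_rate", "qc_pass", "n_used", "note",
]
_MODEL_COLUMNS = [
    "phenotype", "gene", "rsid", "model", "n_used", "aic", "p_lrt",
    "contrasts", "estimates", "ci_lows", "ci_highs", "is_best",
]


def write_results(
    results: list[AssociationResult],
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the association result tables and a JSON summary.

    Output is deterministic: fixed file names, tables sorted by
    (phenotype, gene, rsid), and a summary carrying the seed plus a hash of
    the configuration used.
    """
    from .association import significant_counts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_table = results_model_table(results)
    best_table = results_best_table(results)
    if model_table.empty:
        model_table = pd.DataFrame(columns=_MODEL_COLUMNS)
    if best_table.empty:
        best_table = pd.DataFrame(columns=_BEST_COLUMNS)
    paths = {
        "models": out / "association_models.tsv",
        "best": out / "association_best.tsv",
        "summary": out / "association_summary.json",
    }
    model_table.to_csv(paths["models"], sep="\t", index=False, float_format="%.10g")
    best_table.to_csv(paths["best"], sep="\t", index=False, float_format="%.10g")
    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    summary = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_results": len(results),
        **significant_counts(results),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=True)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------
@dataclass
class RunConfig:
    """End-to-end pipeline parameters, loadable from YAML."""

    n_patients: int = 375
    seed: int = 0
    alpha: float = 0.05
    call_rate_threshold: float = 0.95
    percentile: float = 75.0
    followup_year: int = 6
    window: float = 1.0
    missing_genotype_rate: float = 0.02
    phenotypes: list[str] = field(default_factory=lambda: ["twl_nadir", "twl_6y", "wr_mwl"])
    effect_spec: list[dict] = field(default_factory=list)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if not 0 <= self.call_rate_threshold <= 1:
            raise InvalidArgumentError("call_rate_threshold must be in [0, 1]")
        if not 0 < self.percentile < 100:
            raise InvalidArgumentError("percentile must be in (0, 100)")
        if self.window < 0:
            raise InvalidArgumentError("window must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
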