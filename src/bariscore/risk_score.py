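"""Unweighted phenotype-specific genetic risk scores.

A risk score definition collects, for one phenotype, the significant
QC-passing SNPs with their risk alleles. Each SNP contributes 2 points for
the risk-allele homozygote, 1 for the heterozygote and 0 otherwise
(over-dominant entries score the heterozygote 1 and both homozygotes 0).
Patient scores are integer sums; the cohort is split at the 75th percentile
of the empirical score distribution (linear-interpolation percentile), the
high category being scores strictly above the cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationResult
from .errors import EmptyRiskScoreError, InvalidArgumentError, UnknownSNPError
from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class RiskScoreEntry:
    rsid: str
    risk_allele: str | None  # None for over-dominant (genotype-level) rules
    points: dict[int, int]  # alt-allele dosage -> points
    model: str = ""
    p_value: float = float("nan")
    note: str = ""

    def __post_init__(self) -> None:
        if set(self.points) != {0, 1, 2}:
            raise InvalidArgumentError("points map must cover dosages 0, 1, 2")
        if any(p not in (0, 1, 2) for p in self.points.values()):
            raise InvalidArgumentError("points must be in {0, 1, 2}")

    @property
    def max_points(self) -> int:
        return max(self.points.values())


@dataclass
class RiskScoreDefinition:
    phenotype: str
    entries: list[RiskScoreEntry] = field(default_factory=list)

    @property
    def max_score(self) -> int:
        return sum(e.max_points for e in self.entries)

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    # --------------------------------------------------------------- JSON
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "phenotype": self.phenotype,
            "max_score": self.max_score,
            "entries": [
                {
                    "rsid": e.rsid,
                    "risk_allele": e.risk_allele,
                    "points": {str(k): v for k, v in e.points.items()},
                    "model": e.model,
                    "p_value": None if np.isnan(e.p_value) else e.p_value,
                    "note": e.note,
                }
                for e in self.entries
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RiskScoreDefinition":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        entries = [
            RiskScoreEntry(
                rsid=e["rsid"],
                risk_allele=e.get("risk_allele"),
                points={int(k): int(v) for k, v in e["points"].items()},
                model=e.get("model", ""),
                p_value=float("nan") if e.get("p_value") is None else float(e["p_value"]),
                note=e.get("note", ""),
            )
            for e in payload["entries"]
        ]
        return cls(phenotype=payload["phenotype"], entries=entries)


def build_rs_definition(
    results: list[AssociationResult], phenotype: str
) -> RiskScoreDefinition:
    """Collect the significant, QC-passing SNPs for one phenotype.

    Raises :class:`EmptyRiskScoreError` when the scan produced no usable
    entry, in which case scoring is refused.
    """
    entries = []
    for r in results:
        if r.phenotype != phenotype or not (r.significant and r.qc_pass):
            continue
        if r.risk_points is None:
            continue  # risk rule was never callable (e.g. QC change after scan)
        entries.append(
            RiskScoreEntry(
                rsid=r.rsid,
                risk_allele=r.risk_allele,
                points=dict(r.risk_points),
                model=str(r.best_model.value) if r.best_model else "",
                p_value=r.p_value,
                note=r.risk_rule_note,
            )
        )
    if not entries:
        raise EmptyRiskScoreError(
            f"no significant QC-passing SNP associated with {phenotype!r}; "
            "risk score cannot be built"
        )
    return RiskScoreDefinition(phenotype=phenotype, entries=entries)


def score_patients(
    genotypes: GenotypeMatrix,
    rs_def: RiskScoreDefinition,
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Integer risk score per patient.

    ``missing_policy='zero'`` lets a missing genotype contribute 0 points
    (counted in ``n_missing``); ``'exclude'`` drops patients missing any
    score SNP (their score is NA).
    """
    if missing_policy not in ("zero", "exclude"):
        raise InvalidArgumentError("missing_policy must be 'zero' or 'exclude'")
    if not rs_def.entries:
        raise EmptyRiskScoreError("risk score definition has no entries")
    scores = np.zeros(genotypes.n_patients, dtype=int)
    n_missing = np.zeros(genotypes.n_patients, dtype=int)
    for entry in rs_def.entries:
        if entry.rsid not in genotypes.manifest:
            raise UnknownSNPError(f"score SNP {entry.rsid!r} absent from genotype matrix")
        dosage = genotypes.dosage_of(entry.rsid)
        lut = np.array(
            [entry.points[0], entry.points[1], entry.points[2], 0], dtype=int
        )
        scores += lut[np.where(dosage == MISSING, 3, dosage)]
        n_missing += (dosage == MISSING).astype(int)
    out = pd.DataFrame(
        {"score": scores, "n_missing": n_missing},
        index=pd.Index(genotypes.patient_ids, name="patient_id"),
    )
    if missing_policy == "exclude":
        out["score"] = out["score"].astype("Int64").mask(out["n_missing"] > 0)
    return out


@dataclass(frozen=True)
class ScoreCategories:
    categories: pd.Series  # 'high' / 'low' per patient (or per score position)
    cutoff: float  # linear-interpolation percentile of the score distribution
    realized_threshold: int | None  # smallest integer score in the high class

    @property
    def n_high(self) -> int:
        return int((self.categories == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.categories == "low").sum())


def categorize_scores(
    scores: pd.Series | np.ndarray | list[int], percentile: float = 75.0
) -> ScoreCategories:
    """Split scores at the given empirical percentile (high = strictly above).

    With fewer than two distinct scores the split is degenerate: everyone is
    'low' and a warning is issued.
    """
    s = pd.Series(scores).astype(float)
    valid = s.dropna()
    if valid.empty:
        raise InvalidArgumentError("no scores to categorize")
    if valid.nunique() < 2:
        warnings.warn(
            "fewer than two distinct scores; the high category is empty",
            stacklevel=2,
        )
    cutoff = float(np.percentile(valid.to_numpy(), percentile))
    cats = pd.Series(
        np.where(s.to_numpy() > cutoff, "high", "low"), index=s.index, name="category"
    )
    cats[s.isna().to_numpy()] = pd.NA
    high_scores = valid[valid > cutoff]
    realized = int(high_scores.min()) if not high_scores.empty else None
    return ScoreCategories(categories=cats, cutoff=cutoff, realized_threshold=realized)
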