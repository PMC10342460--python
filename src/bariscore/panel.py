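"""Packaged candidate panel and its published risk-allele assignments.

Besides the 48-variant manifest, the package ships the published summary of
which panel SNPs were associated with which weight-response phenotype and
their risk alleles. From that summary, reference risk-score definitions can
be rebuilt without rerunning an association scan.
"""

from __future__ import annotations

import csv
from importlib import resources

import pandas as pd

from .errors import InvalidArgumentError
from .manifest import SNPManifest
from .risk_score import RiskScoreDefinition, RiskScoreEntry

PANEL_PHENOTYPES = ("twl_nadir", "twl_6y", "wr_mwl")


def panel_risk_alleles() -> pd.DataFrame:
    """Published per-SNP risk alleles with their associated phenotypes."""
    with resources.as_file(
        resources.files("bariscore.data").joinpath("panel_risk_alleles.tsv")
    ) as p:
        with open(p, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    frame = pd.DataFrame(rows)
    frame["phenotypes"] = frame["phenotypes"].str.split(",")
    return frame


def reference_risk_definition(
    phenotype: str, manifest: SNPManifest | None = None
) -> RiskScoreDefinition:
    """Risk-score definition for ``phenotype`` from the published assignments.

    Points follow the unweighted 2/1/0 rule: 2 for the risk-allele
    homozygote, 1 for the heterozygote, 0 otherwise, with the risk allele
    oriented against the manifest's ref/alt letters.
    """
    if phenotype not in PANEL_PHENOTYPES:
        raise InvalidArgumentError(
            f"phenotype must be one of {PANEL_PHENOTYPES}, got {phenotype!r}"
        )
    manifest = manifest or SNPManifest.default()
    entries = []
    for _, row in panel_risk_alleles().iterrows():
        if phenotype not in row["phenotypes"]:
            continue
        variant = manifest[row["rsid"]]
        risk = row["risk_allele"]
        if risk == variant.alt:
            points = {0: 0, 1: 1, 2: 2}
        elif risk == variant.ref:
            points = {0: 2, 1: 1, 2: 0}
        else:
            raise InvalidArgumentError(
                f"{row['rsid']}: risk allele {risk} not in manifest pair "
                f"{variant.ref}/{variant.alt}"
            )
        entries.append(
            RiskScoreEntry(rsid=row["rsid"], risk_allele=risk, points=points)
        )
    return RiskScoreDefinition(phenotype=phenotype, entries=entries)
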