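"""In-memory genotype matrix keyed by patient id and rsid.

Genotypes are stored as alternate-allele dosage (0/1/2) with ``-1`` marking a
missing call, alongside the manifest that fixes each SNP's allele letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlleleMismatchError, InvalidArgumentError, UnknownSNPError
from .manifest import SNPManifest

MISSING = -1
MISSING_CALL = "./."


def call_to_dosage(call: str, ref: str, alt: str) -> int:
    """Parse a single ``X/Y`` call into an alt-allele dosage.

    Blank cells and ``./.`` are treated as missing. Allele order within the
    call is irrelevant.
    """
    call = call.strip()
    if call in ("", MISSING_CALL, ".", "NA"):
        return MISSING
    alleles = call.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise AlleleMismatchError(f"malformed genotype call {call!r}")
    dosage = 0
    for a in alleles:
        if a == alt:
            dosage += 1
        elif a != ref:
            raise AlleleMismatchError(
                f"allele {a!r} in call {call!r} not in manifest pair {ref}/{alt}",
                records=[call],
            )
    return dosage


def dosage_to_call(dosage: int, ref: str, alt: str) -> str:
    if dosage == MISSING:
        return MISSING_CALL
    if dosage == 0:
        return f"{ref}/{ref}"
    if dosage == 1:
        return f"{ref}/{alt}"
    if dosage == 2:
        return f"{alt}/{alt}"
    raise InvalidArgumentError(f"dosage must be in {{-1,0,1,2}}, got {dosage}")


@dataclass
class GenotypeMatrix:
    """Patients x SNPs alt-allele dosage matrix with missingness."""

    patient_ids: list[str]
    manifest: SNPManifest
    dosage: np.ndarray  # shape (n_patients, n_snps), int8, -1 = missing
    _col: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.patient_ids):
            raise InvalidArgumentError("dosage rows must match patient_ids")
        if m != len(self.manifest):
            raise InvalidArgumentError("dosage columns must match manifest entries")
        if len(set(self.patient_ids)) != n:
            raise InvalidArgumentError("patient ids must be unique")
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise InvalidArgumentError("dosage values must be in {-1, 0, 1, 2}")
        self._col = {r: i for i, r in enumerate(self.manifest.rsids)}

    @property
    def rsids(self) -> list[str]:
        return self.manifest.rsids

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def dosage_of(self, rsid: str) -> np.ndarray:
        if rsid not in self._col:
            raise UnknownSNPError(f"rsid {rsid!r} not in genotype matrix")
        return self.dosage[:, self._col[rsid]]

    def call_rate(self, rsid: str) -> float:
        d = self.dosage_of(rsid)
        return float(np.mean(d != MISSING))

    def call_rates(self) -> pd.Series:
        rates = np.mean(self.dosage != MISSING, axis=0)
        return pd.Series(rates, index=self.rsids, name="call_rate")

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(ref-hom, het, alt-hom) counts among non-missing calls."""
        d = self.dosage_of(rsid)
        return (int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2)))

    def to_frame(self) -> pd.DataFrame:
        """String-call DataFrame (rows = patients, columns = rsids)."""
        cols = {}
        for e in self.manifest:
            d = self.dosage_of(e.rsid)
            lut = np.array(
                [f"{e.ref}/{e.ref}", f"{e.ref}/{e.alt}", f"{e.alt}/{e.alt}", MISSING_CALL]
            )
            cols[e.rsid] = lut[np.where(d == MISSING, 3, d)]
        return pd.DataFrame(cols, index=pd.Index(self.patient_ids, name="patient_id"))

    def subset_snps(self, rsids: list[str]) -> "GenotypeMatrix":
        idx = [self._col[r] if r in self._col else self._missing(r) for r in rsids]
        return GenotypeMatrix(
            patient_ids=list(self.patient_ids),
            manifest=self.manifest.subset(rsids),
            dosage=self.dosage[:, idx].copy(),
        )

    def _missing(self, rsid: str):
        raise UnknownSNPError(f"rsid {rsid!r} not in genotype matrix")
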