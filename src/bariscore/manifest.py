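"""SNP panel manifest: rsids, allele letters and (optional) minor allele frequencies.

Variants are keyed by rsid plus allele letters; no genomic coordinates are
used anywhere in the pipeline. The packaged default panel covers 48 variants
in 13 candidate genes (the three NPY-receptor subtypes count as one gene
family).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import InvalidArgumentError, UnknownSNPError

VALID_ALLELES = frozenset("ACGT")

#: Minimum/maximum of the uniform distribution used to fill in missing MAFs.
DEFAULT_MAF_RANGE = (0.10, 0.45)


@dataclass(frozen=True)
class SNPVariant:
    """A biallelic variant with its gene symbol and allele orientation."""

    gene: str
    rsid: str
    ref: str
    alt: str
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_ALLELES or self.alt not in VALID_ALLELES:
            raise InvalidArgumentError(
                f"{self.rsid}: alleles must be one of A/C/G/T, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise InvalidArgumentError(f"{self.rsid}: ref and alt alleles must differ")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise InvalidArgumentError(f"{self.rsid}: maf must be in [0, 0.5], got {self.maf}")


class SNPManifest:
    """Ordered collection of :class:`SNPVariant` with unique rsids."""

    def __init__(self, entries: list[SNPVariant]):
        rsids = [e.rsid for e in entries]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise InvalidArgumentError(f"duplicate rsids in manifest: {dupes}")
        self.entries: list[SNPVariant] = list(entries)
        self._by_rsid = {e.rsid: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SNPVariant]:
        return iter(self.entries)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def __getitem__(self, rsid: str) -> SNPVariant:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise UnknownSNPError(f"rsid {rsid!r} not in manifest") from None

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols, in panel order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.gene, None)
        return list(seen)

    @property
    def n_gene_families(self) -> int:
        """Gene count with the NPY-receptor subtypes collapsed into one family."""
        families = {("NPYR" if g.startswith("NPY") and g.endswith("R") else g) for g in self.genes}
        return len(families)

    def subset(self, rsids: list[str]) -> "SNPManifest":
        return SNPManifest([self[r] for r in rsids])

    def with_default_mafs(self, seed: int | np.random.Generator = 0) -> "SNPManifest":
        """Return a copy where entries lacking a MAF get one drawn uniformly.

        The draw is reproducible for a given seed; entries that already carry
        a MAF are left untouched.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lo, hi = DEFAULT_MAF_RANGE
        out = []
        for e in self.entries:
            if e.maf is None:
                out.append(replace(e, maf=float(rng.uniform(lo, hi))))
            else:
                out.append(e)
        return SNPManifest(out)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path: str | Path) -> "SNPManifest":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"gene", "rsid", "ref", "alt"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise InvalidArgumentError(
                    f"manifest TSV must have header columns {sorted(required)} (+ optional maf)"
                )
            for row in reader:
                maf_raw = (row.get("maf") or "").strip()
                entries.append(
                    SNPVariant(
                        gene=row["gene"].strip(),
                        rsid=row["rsid"].strip(),
                        ref=row["ref"].strip().upper(),
                        alt=row["alt"].strip().upper(),
                        maf=float(maf_raw) if maf_raw else None,
                    )
                )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene", "rsid", "ref", "alt", "maf"])
            for e in self.entries:
                writer.writerow(
                    [e.gene, e.rsid, e.ref, e.alt, "" if e.maf is None else repr(e.maf)]
                )

    @classmethod
    def default(cls) -> "SNPManifest":
        """The packaged 48-variant candidate panel."""
        with resources.as_file(
            resources.files("bariscore.data").joinpath("snp_manifest.tsv")
        ) as p:
            return cls.from_tsv(p)
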