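"""Per-SNP association testing under five inheritance models.

Each SNP x phenotype pair is fitted under the codominant, dominant,
recessive, over-dominant and log-additive encodings, every fit adjusted for
sex, age, initial BMI, T2D, HTN and surgery type (two indicator contrasts
against a restrictive baseline). The genetic-term p-value is a likelihood-
ratio test against the covariate-only model fitted on the same complete-case
rows; the best model is the one with the lowest AIC (``2k - 2 log L`` with
``k`` counting every fitted coefficient), ties broken toward fewer genetic
parameters and then a fixed model order. Risk alleles are called for
significant, QC-passing SNPs: for loss phenotypes the allele on the side of
lower adjusted weight loss, for regain phenotypes the side of higher
regain.

Linear-family fits use a lean least-squares path (cross-checked against
statsmodels in the test suite); binary phenotypes use statsmodels Logit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AllModelsSkippedError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .genotypes import MISSING, GenotypeMatrix
from .hwe import hwe_exact_test
from .models import ALL_MODELS, TIE_BREAK_ORDER, InheritanceModel, encode_inheritance

#: Default per-SNP call-rate QC threshold.
CALL_RATE_THRESHOLD = 0.95

#: Minimum complete-case rows per estimated parameter.
MIN_ROWS_PER_PARAM = 10

#: Phenotypes fitted by default (linear family), and the supported binaries.
DEFAULT_PHENOTYPES = ("twl_nadir", "twl_6y", "wr_mwl")
BINARY_PHENOTYPES = ("ewl6y_gt50", "wr_gt20")
LINEAR_PHENOTYPES = ("twl_nadir", "twl_6y", "wr_mwl", "ewl_nadir", "ewl_6y")

COVARIATE_COLUMNS = (
    "sex_male",
    "age",
    "bmi0",
    "t2d",
    "htn",
    "surgery_mixed",
    "surgery_malabsorptive",
)


def phenotype_direction(phenotype: str) -> str:
    """'loss' for weight-loss phenotypes, 'regain' for weight-regain ones."""
    return "regain" if phenotype.startswith("wr") else "loss"


def phenotype_family(phenotype: str) -> str:
    if phenotype in BINARY_PHENOTYPES:
        return "logistic"
    if phenotype in LINEAR_PHENOTYPES:
        return "linear"
    raise InvalidArgumentError(f"unknown phenotype {phenotype!r}")


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Contrast:
    """One genetic coefficient with its 95% CI (phenotype units or log-odds)."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if math.isfinite(self.estimate) and not (
            self.ci_low <= self.estimate <= self.ci_high
        ):
            raise InvalidArgumentError("CI must contain the point estimate")


@dataclass(frozen=True)
class ModelFit:
    model: InheritanceModel
    contrasts: tuple[Contrast, ...]
    p_value: float  # LRT p of the genetic term vs the covariate-only model
    aic: float
    n_used: int


@dataclass
class AssociationResult:
    rsid: str
    gene: str
    phenotype: str
    fits: dict[InheritanceModel, ModelFit] = field(default_factory=dict)
    skipped: dict[InheritanceModel, str] = field(default_factory=dict)
    best_model: InheritanceModel | None = None
    significant: bool = False
    p_value: float = float("nan")  # best model's genetic-term p
    p_adjusted: float | None = None
    risk_allele: str | None = None
    risk_points: dict[int, int] | None = None  # dosage -> points
    risk_rule_note: str = ""
    hwe_p: float = float("nan")
    call_rate: float = float("nan")
    qc_pass: bool = True
    n_used: int = 0
    note: str = ""

    @property
    def best_fit(self) -> ModelFit | None:
        return self.fits.get(self.best_model) if self.best_model else None


# --------------------------------------------------------------------------
# covariate design
# --------------------------------------------------------------------------
def covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric adjustment design (no intercept column) from the covariate table."""
    X = np.column_stack(
        [
            (covariates["sex"] == "male").to_numpy(float),
            covariates["age"].to_numpy(float),
            covariates["bmi0"].to_numpy(float),
            covariates["t2d"].to_numpy(float),
            covariates["htn"].to_numpy(float),
            (covariates["surgery"] == "mixed").to_numpy(float),
            (covariates["surgery"] == "malabsorptive").to_numpy(float),
        ]
    )
    return X, list(COVARIATE_COLUMNS)


# --------------------------------------------------------------------------
# model fitting primitives
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class _Fit:
    params: np.ndarray
    bse: np.ndarray
    llf: float
    df_resid: int
    k: int


def _ols(X: np.ndarray, y: np.ndarray) -> _Fit:
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"{n} rows for {k} parameters")
    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise DegenerateDesignError("rank-deficient design matrix")
    resid = y - X @ params
    rss = float(resid @ resid)
    if rss <= 0:
        raise DegenerateDesignError("zero residual variance")
    llf = -0.5 * n * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)
    sigma2 = rss / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(xtx_inv) * sigma2)
    return _Fit(params=params, bse=bse, llf=llf, df_resid=n - k, k=k)


def _logit(X: np.ndarray, y: np.ndarray) -> _Fit:
    import statsmodels.api as sm

    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"{n} rows for {k} parameters")
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError("binary outcome is constant")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # separation / singular matrix
        raise DegenerateDesignError(f"logistic fit failed: {err}") from err
    if not res.mle_retvals.get("converged", True):
        raise DegenerateDesignError("logistic fit did not converge")
    return _Fit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        llf=float(res.llf),
        df_resid=n - k,
        k=k,
    )


def _fit(X: np.ndarray, y: np.ndarray, family: str) -> _Fit:
    return _ols(X, y) if family == "linear" else _logit(X, y)


def _ci_halfwidth(fit: _Fit, family: str) -> np.ndarray:
    if family == "linear":
        return stats.t.ppf(0.975, fit.df_resid) * fit.bse
    return stats.norm.ppf(0.975) * fit.bse


_CONTRAST_NAMES = {
    InheritanceModel.DOMINANT: ("alt-carrier vs ref-hom",),
    InheritanceModel.RECESSIVE: ("alt-hom vs ref-carrier",),
    InheritanceModel.OVERDOMINANT: ("het vs homozygotes",),
    InheritanceModel.LOG_ADDITIVE: ("per alt allele",),
    InheritanceModel.CODOMINANT: ("het vs ref-hom", "alt-hom vs ref-hom"),
}


def select_best_model(aics: dict[InheritanceModel, float]) -> InheritanceModel:
    """Lowest AIC; ties toward fewer genetic parameters, then fixed order."""
    if not aics:
        raise InvalidArgumentError("no candidate models")
    rank = {m: i for i, m in enumerate(TIE_BREAK_ORDER)}
    return min(
        aics, key=lambda m: (aics[m], InheritanceModel(m).n_genetic_params, rank[m])
    )


# --------------------------------------------------------------------------
# per-SNP fitting
# --------------------------------------------------------------------------
def fit_inheritance_models(
    rsid: str,
    dosage: np.ndarray,
    phenotype: np.ndarray,
    family: str,
    covariates: pd.DataFrame | None,
    alpha: float = 0.05,
    phenotype_name: str = "",
    gene: str = "",
) -> AssociationResult:
    """Fit all five inheritance models for one SNP-phenotype pair.

    ``dosage`` uses -1 for missing calls; rows with missing genotype,
    phenotype or covariates are dropped (complete-case). Raises
    :class:`InsufficientDataError` when fewer than 10 rows per parameter
    remain and :class:`AllModelsSkippedError` when no model is estimable.
    """
    if family not in ("linear", "logistic"):
        raise InvalidArgumentError(f"family must be linear or logistic, got {family!r}")
    dosage = np.asarray(dosage)
    y_all = np.asarray(phenotype, dtype=float)
    if len(dosage) != len(y_all):
        raise InvalidArgumentError("genotype and phenotype vectors must align")

    result = AssociationResult(rsid=rsid, gene=gene, phenotype=phenotype_name)
    result.call_rate = float(np.mean(dosage != MISSING))
    called = dosage[dosage != MISSING]
    if called.size:
        result.hwe_p = hwe_exact_test(
            int(np.sum(called == 0)), int(np.sum(called == 1)), int(np.sum(called == 2))
        )

    if covariates is not None:
        Xc, _ = covariate_design(covariates)
        if len(covariates) != len(y_all):
            raise InvalidArgumentError("covariates must align with phenotype vector")
    else:
        Xc = np.empty((len(y_all), 0))
    mask = (dosage != MISSING) & np.isfinite(y_all) & np.all(np.isfinite(Xc), axis=1)
    n_used = int(mask.sum())
    result.n_used = n_used
    max_params = 1 + Xc.shape[1] + 2  # intercept + covariates + codominant term
    if n_used < MIN_ROWS_PER_PARAM * (1 + Xc.shape[1] + 1):
        raise InsufficientDataError(
            f"{rsid}/{phenotype_name}: {n_used} complete cases for ~{max_params} parameters"
        )

    d = dosage[mask]
    y = y_all[mask]
    X0 = np.column_stack([np.ones(n_used), Xc[mask]])
    reduced = _fit(X0, y, family)

    for model in ALL_MODELS:
        enc = encode_inheritance(d, model)
        if any(np.ptp(enc[:, j]) == 0.0 for j in range(enc.shape[1])):
            result.skipped[model] = "degenerate encoding (constant genetic column)"
            continue
        X1 = np.column_stack([X0, enc])
        try:
            full = _fit(X1, y, family)
        except (DegenerateDesignError, InsufficientDataError) as err:
            result.skipped[model] = str(err)
            continue
        lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
        p = float(stats.chi2.sf(lrt, enc.shape[1]))
        aic = 2.0 * full.k - 2.0 * full.llf
        half = _ci_halfwidth(full, family)
        genetic = slice(X0.shape[1], X1.shape[1])
        contrasts = tuple(
            Contrast(
                name=name,
                estimate=float(est),
                ci_low=float(est - hw),
                ci_high=float(est + hw),
            )
            for name, est, hw in zip(
                _CONTRAST_NAMES[model], full.params[genetic], half[genetic]
            )
        )
        result.fits[model] = ModelFit(
            model=model, contrasts=contrasts, p_value=p, aic=aic, n_used=n_used
        )

    if not result.fits:
        raise AllModelsSkippedError(
            f"{rsid}/{phenotype_name}: no estimable inheritance model "
            f"({'; '.join(result.skipped.values())})"
        )
    result.best_model = select_best_model({m: f.aic for m, f in result.fits.items()})
    best = result.fits[result.best_model]
    result.p_value = best.p_value
    result.significant = bool(best.p_value < alpha)
    return result


# --------------------------------------------------------------------------
# risk-allele calling
# --------------------------------------------------------------------------
def call_risk_allele(
    result: AssociationResult, direction: str, ref: str, alt: str
) -> AssociationResult:
    """Attach the risk allele and genotype->points rule to a significant fit.

    For loss phenotypes the risk side is the genotype group with the lower
    adjusted mean (negative contrast vs baseline => alternate allele);
    for regain phenotypes the direction is reversed. Over-dominant winners
    have no allele-level risk direction, so the heterozygote is recorded as
    the risk genotype (scoring 1; no genotype can score 2).
    """
    if direction not in ("loss", "regain"):
        raise InvalidArgumentError("direction must be 'loss' or 'regain'")
    result.risk_allele = None
    result.risk_points = None
    result.risk_rule_note = ""
    if not result.significant or result.best_fit is None:
        return result
    fit = result.best_fit
    if fit.model is InheritanceModel.OVERDOMINANT:
        result.risk_points = {0: 0, 1: 1, 2: 0}
        result.risk_rule_note = (
            "over-dominant: heterozygote is the risk genotype; no allele-level direction"
        )
        return result
    # For codominant use the alt-homozygote contrast (dose-consistent side).
    effect = fit.contrasts[-1].estimate
    alt_is_risk = (effect < 0) if direction == "loss" else (effect > 0)
    result.risk_allele = alt if alt_is_risk else ref
    result.risk_points = {0: 0, 1: 1, 2: 2} if alt_is_risk else {0: 2, 1: 1, 2: 0}
    return result


# --------------------------------------------------------------------------
# full scan
# --------------------------------------------------------------------------
@dataclass
class ScanConfig:
    alpha: float = 0.05
    call_rate_threshold: float = CALL_RATE_THRESHOLD
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    fdr: bool = False  # Benjamini-Hochberg across SNPs within each phenotype

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if not 0.0 <= self.call_rate_threshold <= 1.0:
            raise InvalidArgumentError("call_rate_threshold must be in [0, 1]")
        for ph in self.phenotypes:
            phenotype_family(ph)


def run_association_scan(
    genotypes: GenotypeMatrix,
    phenotype_table: pd.DataFrame,
    covariates: pd.DataFrame | None,
    config: ScanConfig | None = None,
) -> list[AssociationResult]:
    """Fit every SNP x phenotype pair and call risk alleles.

    Call-rate QC (default 0.95) marks failing SNPs ``qc_pass=False``; they
    are still fitted and reported but excluded from risk-allele calling.
    The HWE test is reported, never exclusionary. Per-SNP failures are
    recorded in the result's ``note`` instead of aborting the scan.
    """
    config = config or ScanConfig()
    config.validate()
    ids = list(genotypes.patient_ids)
    if list(phenotype_table.index) != ids:
        phenotype_table = phenotype_table.reindex(ids)
    if covariates is not None and list(covariates.index) != ids:
        covariates = covariates.reindex(ids)

    results: list[AssociationResult] = []
    for entry in genotypes.manifest:
        dosage = genotypes.dosage_of(entry.rsid)
        for ph in config.phenotypes:
            y = pd.to_numeric(phenotype_table[ph], errors="coerce").to_numpy(dtype=float)
            try:
                res = fit_inheritance_models(
                    rsid=entry.rsid,
                    dosage=dosage,
                    phenotype=y,
                    family=phenotype_family(ph),
                    covariates=covariates,
                    alpha=config.alpha,
                    phenotype_name=ph,
                    gene=entry.gene,
                )
            except (InsufficientDataError, AllModelsSkippedError) as err:
                res = AssociationResult(
                    rsid=entry.rsid, gene=entry.gene, phenotype=ph, note=str(err)
                )
                res.call_rate = float(np.mean(dosage != MISSING))
            res.qc_pass = bool(res.call_rate >= config.call_rate_threshold)
            results.append(res)

    if config.fdr:
        _apply_bh(results, config.alpha)
    for res in results:
        if res.qc_pass and res.best_fit is not None:
            entry = genotypes.manifest[res.rsid]
            call_risk_allele(
                res, phenotype_direction(res.phenotype), entry.ref, entry.alt
            )
    return results


def _apply_bh(results: list[AssociationResult], alpha: float) -> None:
    """Benjamini-Hochberg within each phenotype; re-gates ``significant``."""
    from statsmodels.stats.multitest import multipletests

    by_ph: dict[str, list[AssociationResult]] = {}
    for r in results:
        if math.isfinite(r.p_value):
            by_ph.setdefault(r.phenotype, []).append(r)
    for group in by_ph.values():
        pvals = [r.p_value for r in group]
        reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for r, rej, a in zip(group, reject, adj):
            r.p_adjusted = float(a)
            r.significant = bool(rej)


def significant_counts(results: list[AssociationResult]) -> dict[str, object]:
    """Per-phenotype and unique-SNP counts of significant associations."""
    per_ph: dict[str, int] = {}
    unique: set[str] = set()
    loss_snps: set[str] = set()
    regain_snps: set[str] = set()
    for r in results:
        if r.significant and r.qc_pass:
            per_ph[r.phenotype] = per_ph.get(r.phenotype, 0) + 1
            unique.add(r.rsid)
            if phenotype_direction(r.phenotype) == "loss":
                loss_snps.add(r.rsid)
            else:
                regain_snps.add(r.rsid)
    return {
        "per_phenotype": per_ph,
        "n_unique_snps": len(unique),
        "n_loss_snps": len(loss_snps),
        "n_regain_snps": len(regain_snps),
    }
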