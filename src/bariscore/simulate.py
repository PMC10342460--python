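"""Synthetic cohort generator: genotypes, covariates and weight trajectories.

The generator emulates the statistical structure the downstream analysis
assumes: genotypes in Hardy-Weinberg proportions at configurable MAFs,
covariates with configurable marginals, and per-patient weight trajectories
that decline to a nadir in year 1-2 and then partially regain. Genetic
effects can be planted on the latent weight-response phenotypes for
parameter-recovery and calibration experiments.

Latent phenotype construction (all in percent units):

    twl_nadir = mean + covariate effects + planted effects + noise
    wr_mwl    = mean + covariate effects + planted effects + noise
    twl_6y    = twl_nadir * (1 - wr_mwl/100) + planted effects + noise

so a planted effect shifts its target phenotype by exactly its stated size
before noise. Trajectories are then drawn through the implied year-0, nadir
and year-6 weights (exponential decline to the nadir, linear regain after).
SNPs are simulated independently; no linkage structure is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UnknownSNPError
from .genotypes import MISSING, GenotypeMatrix
from .manifest import SNPManifest
from .models import InheritanceModel, encode_inheritance

PHENOTYPE_TARGETS = ("twl_nadir", "twl_6y", "wr_mwl")
SURGERY_TYPES = ("restrictive", "mixed", "malabsorptive")


@dataclass(frozen=True)
class EffectSpec:
    """A genetic effect planted on a latent phenotype.

    ``beta`` is in phenotype units (percentage points) per unit of the model
    encoding; codominant is not supported as a planting model because it has
    no single effect size.
    """

    rsid: str
    target: str
    model: InheritanceModel
    beta: float

    def __post_init__(self) -> None:
        if self.target not in PHENOTYPE_TARGETS:
            raise InvalidArgumentError(
                f"effect target must be one of {PHENOTYPE_TARGETS}, got {self.target!r}"
            )
        if InheritanceModel(self.model) is InheritanceModel.CODOMINANT:
            raise InvalidArgumentError("codominant has no single effect size; plant per-genotype effects via two specs")


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions for the simulated pre-surgery profile."""

    female_fraction: float = 0.69
    age_mean: float = 44.79
    age_sd: float = 11.99
    age_range: tuple[float, float] = (18.0, 65.0)
    bmi_mean: float = 44.87
    bmi_sd: float = 6.59
    bmi_range: tuple[float, float] = (30.0, 75.0)
    t2d_fraction: float = 0.357
    htn_fraction: float = 0.49
    # restrictive / mixed / malabsorptive; published rounded fractions
    # (16 / 54.66 / 29.3) are closed to sum to one.
    surgery_fractions: tuple[float, float, float] = (0.16, 0.5466, 0.2934)
    height_mean: float = 1.65
    height_sd: float = 0.09
    height_range: tuple[float, float] = (1.40, 2.10)

    def validate(self) -> None:
        for name, frac in (
            ("female_fraction", self.female_fraction),
            ("t2d_fraction", self.t2d_fraction),
            ("htn_fraction", self.htn_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1], got {frac}")
        if any(f < 0 for f in self.surgery_fractions):
            raise InvalidArgumentError("surgery fractions must be non-negative")
        if abs(sum(self.surgery_fractions) - 1.0) > 1e-9:
            raise InvalidArgumentError("surgery fractions must sum to 1 within 1e-9")


def _default_noise_sd() -> dict[str, float]:
    return {"twl_nadir": 8.0, "twl_6y": 4.0, "wr_mwl": 9.0}


def _default_covariate_effects() -> dict[str, dict[str, float]]:
    # Modest, fixed pre-surgery-profile effects so that covariate adjustment
    # in the association module is exercised on non-null covariates.
    return {
        "twl_nadir": {
            "malabsorptive": 3.0,
            "restrictive": -3.0,
            "age_c": -0.08,
            "bmi_c": -0.10,
            "t2d": -1.5,
            "htn": -0.5,
            "male": 1.0,
        },
        "wr_mwl": {"malabsorptive": -1.5, "restrictive": 1.5, "age_c": 0.05, "t2d": 1.0},
        "twl_6y": {},
    }


@dataclass
class SimulationConfig:
    """Full configuration of a synthetic cohort."""

    n_patients: int = 375
    seed: int = 0
    marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    effect_spec: list[EffectSpec] = field(default_factory=list)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    visit_years: list[int] = field(default_factory=lambda: list(range(9)))
    missing_genotype_rate: float = 0.02
    visit_noise_sd: float = 0.0  # kg, applied to postoperative visits
    twl_nadir_mean: float = 38.79
    wr_mean: float = 16.0
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_covariate_effects
    )

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InvalidArgumentError("n_patients must be >= 1")
        if not 0.0 <= self.missing_genotype_rate <= 1.0:
            raise InvalidArgumentError("missing_genotype_rate must be in [0, 1]")
        if 0 not in self.visit_years or not any(y >= 1 for y in self.visit_years):
            raise InvalidArgumentError("visit_years must include year 0 and a postoperative year")
        if len(set(self.visit_years)) != len(self.visit_years):
            raise InvalidArgumentError("visit_years must be unique")
        for k, v in self.noise_sd.items():
            if k not in PHENOTYPE_TARGETS:
                raise InvalidArgumentError(f"unknown noise_sd key {k!r}")
            if v < 0:
                raise InvalidArgumentError("noise sd must be non-negative")
        self.marginals.validate()


@dataclass
class WeightTrajectory:
    """Annual weight records for one patient; year 0 is the pre-surgery weight."""

    patient_id: str
    years: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.years.shape != self.weights.shape:
            raise InvalidArgumentError("years and weights must have equal length")
        if len(set(self.years.tolist())) != len(self.years):
            raise InvalidArgumentError(f"{self.patient_id}: visit years must be unique")
        if 0 not in self.years:
            raise InvalidArgumentError(f"{self.patient_id}: trajectory must contain year 0")
        if not np.any(self.years >= 1):
            raise InvalidArgumentError(f"{self.patient_id}: needs a postoperative record")
        if np.any(self.weights <= 0):
            raise InvalidArgumentError(f"{self.patient_id}: weights must be positive")


def trajectories_to_frame(trajectories: list[WeightTrajectory]) -> pd.DataFrame:
    """Long-format (`patient_id`, `visit_year`, `weight_kg`) frame."""
    return pd.DataFrame(
        {
            "patient_id": np.repeat(
                [t.patient_id for t in trajectories], [len(t.years) for t in trajectories]
            ),
            "visit_year": np.concatenate([t.years for t in trajectories]),
            "weight_kg": np.concatenate([t.weights for t in trajectories]),
        }
    )


def frame_to_trajectories(frame: pd.DataFrame) -> list[WeightTrajectory]:
    out = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        out.append(
            WeightTrajectory(
                patient_id=str(pid),
                years=grp["visit_year"].to_numpy(),
                weights=grp["weight_kg"].to_numpy(),
            )
        )
    return out


def patient_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------
def simulate_genotypes(
    manifest: SNPManifest, n: int, seed: int, missing_rate: float = 0.0
) -> GenotypeMatrix:
    """Draw genotypes independently per SNP under Hardy-Weinberg proportions.

    Each SNP column is i.i.d. with genotype probabilities
    ``(1-q)^2, 2q(1-q), q^2`` for alternate-allele frequency ``q`` equal to
    the manifest MAF; missing calls are then inserted at ``missing_rate``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not 0.0 <= missing_rate <= 1.0:
        raise InvalidArgumentError("missing_rate must be in [0, 1]")
    mafs = []
    for e in manifest:
        if e.maf is None:
            raise InvalidArgumentError(
                f"{e.rsid}: manifest has no MAF; call manifest.with_default_mafs() first"
            )
        mafs.append(e.maf)
    q = np.asarray(mafs)
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(q)))
    p_rr = (1.0 - q) ** 2
    p_het = 2.0 * q * (1.0 - q)
    dosage = (u >= p_rr).astype(np.int8) + (u >= p_rr + p_het).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, len(q))) < missing_rate
        dosage[mask] = MISSING
    return GenotypeMatrix(patient_ids=patient_ids(n), manifest=manifest, dosage=dosage)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw the pre-surgery covariate table with the configured marginals."""
    config.validate()
    m = config.marginals
    n = config.n_patients
    rng = np.random.default_rng((config.seed, 2))
    sex = np.where(rng.random(n) < m.female_fraction, "female", "male")
    age = np.clip(rng.normal(m.age_mean, m.age_sd, n), *m.age_range)
    bmi0 = np.clip(rng.normal(m.bmi_mean, m.bmi_sd, n), *m.bmi_range)
    height = np.clip(rng.normal(m.height_mean, m.height_sd, n), *m.height_range)
    t2d = rng.random(n) < m.t2d_fraction
    htn = rng.random(n) < m.htn_fraction
    surgery = rng.choice(SURGERY_TYPES, size=n, p=m.surgery_fractions)
    return pd.DataFrame(
        {
            "age": np.round(age, 2),
            "sex": sex,
            "bmi0": np.round(bmi0, 2),
            "height": np.round(height, 3),
            "t2d": t2d,
            "htn": htn,
            "surgery": surgery,
        },
        index=pd.Index(patient_ids(n), name="patient_id"),
    )


def _covariate_contribution(
    covariates: pd.DataFrame, effects: dict[str, float]
) -> np.ndarray:
    out = np.zeros(len(covariates))
    if not effects:
        return out
    terms = {
        "malabsorptive": (covariates["surgery"] == "malabsorptive").to_numpy(float),
        "restrictive": (covariates["surgery"] == "restrictive").to_numpy(float),
        "age_c": covariates["age"].to_numpy(float) - 45.0,
        "bmi_c": covariates["bmi0"].to_numpy(float) - 44.87,
        "t2d": covariates["t2d"].to_numpy(float),
        "htn": covariates["htn"].to_numpy(float),
        "male": (covariates["sex"] == "male").to_numpy(float),
    }
    for name, coef in effects.items():
        if name not in terms:
            raise InvalidArgumentError(f"unknown covariate-effect term {name!r}")
        out += coef * terms[name]
    return out


def _planted_contribution(
    genotypes: GenotypeMatrix, specs: list[EffectSpec], target: str
) -> np.ndarray:
    out = np.zeros(genotypes.n_patients)
    for spec in specs:
        if spec.target != target:
            continue
        if spec.rsid not in genotypes.manifest:
            raise UnknownSNPError(f"effect_spec rsid {spec.rsid!r} not in genotype matrix")
        dosage = genotypes.dosage_of(spec.rsid).copy()
        dosage[dosage == MISSING] = 0  # a missing call carries no planted effect
        enc = encode_inheritance(dosage, spec.model)[:, 0]
        out += spec.beta * enc
    return out


def latent_phenotypes(
    genotypes: GenotypeMatrix, covariates: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Latent (pre-trajectory) weight-response phenotypes per patient."""
    rng = np.random.default_rng((config.seed, 1))
    n = len(covariates)
    sd = {**_default_noise_sd(), **config.noise_sd}
    fx = {**_default_covariate_effects(), **config.covariate_effects}

    twl_nadir = (
        config.twl_nadir_mean
        + _covariate_contribution(covariates, fx["twl_nadir"])
        + _planted_contribution(genotypes, config.effect_spec, "twl_nadir")
        + rng.normal(0.0, sd["twl_nadir"], n)
    )
    wr = (
        config.wr_mean
        + _covariate_contribution(covariates, fx["wr_mwl"])
        + _planted_contribution(genotypes, config.effect_spec, "wr_mwl")
        + rng.normal(0.0, sd["wr_mwl"], n)
    )
    twl_nadir = np.clip(twl_nadir, 2.0, 80.0)
    wr = np.clip(wr, 0.0, 95.0)
    twl_6y = (
        twl_nadir * (1.0 - wr / 100.0)
        + _covariate_contribution(covariates, fx["twl_6y"])
        + _planted_contribution(genotypes, config.effect_spec, "twl_6y")
        + rng.normal(0.0, sd["twl_6y"], n)
    )
    twl_6y = np.clip(twl_6y, -30.0, 95.0)
    nadir_year = rng.choice([1, 2], size=n)
    return pd.DataFrame(
        {"twl_nadir": twl_nadir, "twl_6y": twl_6y, "nadir_year": nadir_year},
        index=covariates.index,
    )


def simulate_trajectories(
    genotypes: GenotypeMatrix, covariates: pd.DataFrame, config: SimulationConfig
) -> list[WeightTrajectory]:
    """Build annual weight trajectories from the latent phenotypes.

    Year 0 weight is ``bmi0 * height^2`` exactly; weight declines
    exponentially to the nadir (reached in year 1 or 2) and then changes
    linearly so that the year-6 weight realizes the latent ``twl_6y``.
    """
    if list(genotypes.patient_ids) != list(covariates.index):
        raise InvalidArgumentError("genotype and covariate patient ids must match")
    config.validate()
    latent = latent_phenotypes(genotypes, covariates, config)
    rng = np.random.default_rng((config.seed, 4))  # visit-level measurement noise
    years = np.asarray(sorted(config.visit_years))

    w0 = covariates["bmi0"].to_numpy(float) * covariates["height"].to_numpy(float) ** 2
    w_nadir = w0 * (1.0 - latent["twl_nadir"].to_numpy() / 100.0)
    w6 = w0 * (1.0 - latent["twl_6y"].to_numpy() / 100.0)
    t_nadir = latent["nadir_year"].to_numpy()

    out: list[WeightTrajectory] = []
    for i, pid in enumerate(covariates.index):
        slope = (w6[i] - w_nadir[i]) / (6.0 - t_nadir[i])
        w = np.where(
            years <= t_nadir[i],
            w_nadir[i] + (w0[i] - w_nadir[i]) * 0.25 ** years,
            w_nadir[i] + (years - t_nadir[i]) * slope,
        )
        w[years == t_nadir[i]] = w_nadir[i]
        if config.visit_noise_sd > 0:
            noise = rng.normal(0.0, config.visit_noise_sd, len(years))
            noise[years == 0] = 0.0  # year-0 weight stays exact
            w = w + noise
        w = np.maximum(w, 1.0)
        out.append(WeightTrajectory(patient_id=str(pid), years=years.copy(), weights=w))
    return out


def simulate_cohort(
    config: SimulationConfig, manifest: SNPManifest | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, list[WeightTrajectory]]:
    """Generate a full synthetic cohort (genotypes, covariates, trajectories)."""
    config.validate()
    if manifest is None:
        manifest = SNPManifest.default()
    manifest = manifest.with_default_mafs(np.random.default_rng((config.seed, 3)))
    genotypes = simulate_genotypes(
        manifest, config.n_patients, config.seed, config.missing_genotype_rate
    )
    covariates = simulate_covariates(config)
    trajectories = simulate_trajectories(genotypes, covariates, config)
    return genotypes, covariates, trajectories


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)
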