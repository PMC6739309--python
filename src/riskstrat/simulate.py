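"""Seeded synthetic sepsis-cohort generator.

Emulates the statistical structure the downstream pipeline assumes: a
log-normal plasma biomarker (eNAPRT) whose sepsis marginal is calibrated so
the median sits at 27.1 ng/ml and 71% of subjects fall at or above the
15 ng/ml cut-off; a step change-point mortality model (44% deaths above the
cut-off, 10% below); CRP linked to eNAPRT through a Gaussian copula tuned so
the raw-scale Pearson correlation is ~0.31; creatinine and LDH drawn
group-conditionally so the direction of the group contrasts matches clinical
expectation; and uniform death times within a 28-day follow-up for the
survival stage. All randomness derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "LogNormalMarginal",
    "MortalityModel",
    "SurvivalModel",
    "GeneratorConfig",
    "calibrate_sigma_from_split",
    "sample_correlated_covariate",
    "assign_outcome_and_time",
    "generate_cohort",
    "tune_rho_for_pearson",
    "sepsis_default_config",
]

#: log-scale sigma of the sepsis eNAPRT marginal, from inverting the
#: log-normal CDF so that P(X >= 15) = 0.71 when the median is 27.1 ng/ml
SEPSIS_ENAPRT_SIGMA = float(np.log(27.1 / 15.0) / stats.norm.ppf(0.71))

#: latent Gaussian-copula correlation between eNAPRT and CRP, calibrated by
#: bisection (tune_rho_for_pearson) so the raw-scale Pearson r is 0.31 under
#: the default marginals and the group-conditional CRP medians
DEFAULT_CRP_RHO = 0.325


@dataclass(frozen=True)
class LogNormalMarginal:
    """Log-normal marginal parameterized by its median (mu = ln median)."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))


@dataclass(frozen=True)
class MortalityModel:
    """Death-probability model.

    ``step`` mode: P(death) = ``p_high`` if biomarker >= ``tau`` else
    ``p_low`` — the change-point structure the threshold scan is designed to
    recover. ``logistic`` mode: P(death) = expit(intercept + slope * ln x),
    provided for power studies.
    """

    mode: str = "step"
    tau: float = 15.0
    p_high: float = 0.44
    p_low: float = 0.10
    intercept: float = -3.0
    slope: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("step", "logistic"):
            raise ValueError(f"unknown mortality mode: {self.mode!r}")
        if not (0 <= self.p_low <= self.p_high <= 1):
            raise ValueError("need 0 <= p_low <= p_high <= 1")

    def death_probability(self, values: np.ndarray) -> np.ndarray:
        if self.mode == "step":
            return np.where(values >= self.tau, self.p_high, self.p_low)
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.log(values))


@dataclass(frozen=True)
class SurvivalModel:
    """Death times uniform in (0, followup]; survivors censored at followup."""

    followup_days: float = 28.0

    def __post_init__(self) -> None:
        if self.followup_days <= 0:
            raise ValueError("followup_days must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``primary`` names the biomarker that drives mortality and the copula;
    ``conditional_medians`` optionally overrides a covariate's median per
    mortality-model group (high/low around ``mortality.tau``).
    """

    n: int = 100
    primary: str = "eNAPRT"
    marginals: dict = field(default_factory=dict)
    conditional_medians: dict = field(default_factory=dict)
    copula_rho: dict = field(default_factory=dict)
    mortality: MortalityModel = field(default_factory=MortalityModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.primary not in self.marginals:
            raise ValueError(f"primary biomarker {self.primary!r} lacks a marginal")
        for name, rho in self.copula_rho.items():
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1 for {name!r}")
            if name not in self.marginals:
                raise ValueError(f"copula names unknown biomarker {name!r}")
        for name in self.conditional_medians:
            if name not in self.marginals:
                raise ValueError(
                    f"conditional_medians names unknown biomarker {name!r}"
                )


def sepsis_default_config(n: int = 100) -> GeneratorConfig:
    """The default sepsis cohort: calibrated eNAPRT, routine covariates.

    eNAPRT: median 27.1 ng/ml, sigma from the 71/29 split at 15 ng/ml.
    CRP/creatinine/LDH medians are group-conditional (>= / < 15 ng/ml):
    209/130 mg/l, 1.8/1.1 mg/dl, 488/392 U/l. Other covariates (eNAMPT, PCT,
    WBC, Plts, INR) are independent log-normals at typical sepsis medians.
    Dispersion defaults to sigma = 0.6 on the log scale where no calibration
    constraint applies.
    """
    marginals = {
        "eNAPRT": LogNormalMarginal(27.1, SEPSIS_ENAPRT_SIGMA),
        "CRP": LogNormalMarginal(185.0, 0.6),
        "creatinine": LogNormalMarginal(1.6, 0.6),
        "LDH": LogNormalMarginal(460.0, 0.6),
        "eNAMPT": LogNormalMarginal(5.05, 0.6),
        "PCT": LogNormalMarginal(2.0, 0.8),
        "WBC": LogNormalMarginal(12.0, 0.4),
        "Plts": LogNormalMarginal(200.0, 0.4),
        "INR": LogNormalMarginal(1.3, 0.2),
    }
    conditional = {
        "CRP": {"high": 209.0, "low": 130.0},
        "creatinine": {"high": 1.8, "low": 1.1},
        "LDH": {"high": 488.0, "low": 392.0},
    }
    return GeneratorConfig(
        n=n,
        primary="eNAPRT",
        marginals=marginals,
        conditional_medians=conditional,
        copula_rho={"CRP": DEFAULT_CRP_RHO},
    )


def calibrate_sigma_from_split(
    median: float, tau: float, frac_high: float
) -> float:
    """Log-scale sigma such that P(X >= tau) = frac_high for a log-normal
    with ln-median mu = ln(median).

    Closed form: sigma = (ln median - ln tau) / Phi^-1(frac_high). When
    tau == median any sigma satisfies frac_high = 0.5; returns 1.0.
    """
    if median <= 0 or tau <= 0:
        raise ValueError("median and tau must be > 0")
    if not 0 < frac_high < 1:
        raise ValueError("frac_high must be in (0, 1)")
    if np.isclose(tau, median):
        if not np.isclose(frac_high, 0.5):
            raise ValueError("tau == median forces frac_high = 0.5")
        return 1.0
    if np.isclose(frac_high, 0.5):
        raise ValueError("frac_high = 0.5 requires tau == median")
    sigma = (np.log(median) - np.log(tau)) / stats.norm.ppf(frac_high)
    if sigma <= 0:
        raise ValueError(
            "infeasible split: tau on the wrong side of the median for frac_high"
        )
    return float(sigma)


def sample_correlated_covariate(
    primary_latents: np.ndarray,
    rho: float,
    marginal: LogNormalMarginal,
    seed: int,
    mu_override: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-copula draw: exp(mu2 + sigma2 * (rho z1 + sqrt(1-rho^2) z2)).

    ``mu_override`` replaces the marginal's ln-median per subject (used for
    group-conditional medians).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    z1 = np.asarray(primary_latents, dtype=float)
    rng = np.random.default_rng(seed)
    z2 = rng.standard_normal(z1.shape[0])
    mu = marginal.mu if mu_override is None else np.asarray(mu_override, float)
    if mu_override is not None and len(mu_override) != len(z1):
        raise ValueError("mu_override length mismatch")
    latent = rho * z1 + np.sqrt(1 - rho**2) * z2
    return np.exp(mu + marginal.sigma * latent)


def assign_outcome_and_time(
    values: np.ndarray,
    mortality: MortalityModel,
    survival: SurvivalModel,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (outcome, time, event) per subject from the mortality model.

    Deaths get a time uniform in (0, followup] with event = 1; survivors are
    censored at followup with event = 0. Outcome and event coincide here
    because every death occurs within follow-up.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    p = mortality.death_probability(values)
    outcome = (rng.random(values.shape[0]) < p).astype(int)
    t_death = survival.followup_days * (1.0 - rng.random(values.shape[0]))
    time = np.where(outcome == 1, t_death, survival.followup_days)
    event = outcome.copy()
    return outcome, time, event


def _label_seed(seed: int, index: int) -> int:
    """Deterministic per-stream seed derived from the global seed."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1)[0])


def generate_cohort(config: GeneratorConfig, seed: int) -> CohortTable:
    """Generate a fully populated cohort; bit-identical for equal inputs.

    The primary biomarker is drawn first from its log-normal marginal; each
    other biomarker is drawn via the Gaussian copula against the primary's
    latent z-scores (rho = 0 for covariates not named in ``copula_rho``),
    with group-conditional ln-medians where configured. Outcomes and survival
    follow from the mortality and survival models.
    """
    cfg = config
    n = cfg.n
    primary_marg = cfg.marginals[cfg.primary]

    rng = np.random.default_rng(_label_seed(seed, 0))
    z1 = rng.standard_normal(n)
    primary_vals = np.exp(primary_marg.mu + primary_marg.sigma * z1)
    high_mask = primary_vals >= cfg.mortality.tau

    data = {"subject_id": [f"S{i:06d}" for i in range(n)]}
    biomarkers = [cfg.primary]
    data[cfg.primary] = primary_vals

    for idx, (name, marg) in enumerate(sorted(cfg.marginals.items()), start=1):
        if name == cfg.primary:
            continue
        rho = cfg.copula_rho.get(name, 0.0)
        mu_override = None
        if name in cfg.conditional_medians:
            med = cfg.conditional_medians[name]
            mu_override = np.where(
                high_mask, np.log(med["high"]), np.log(med["low"])
            )
        data[name] = sample_correlated_covariate(
            z1, rho, marg, _label_seed(seed, idx), mu_override=mu_override
        )
        biomarkers.append(name)

    outcome, time, event = assign_outcome_and_time(
        primary_vals, cfg.mortality, cfg.survival, _label_seed(seed, 10_000)
    )
    data["outcome"] = outcome
    data["time"] = time
    data["event"] = event

    df = pd.DataFrame(data)
    cols = ["subject_id", "outcome", "time", "event"] + biomarkers
    return CohortTable(data=df[cols], biomarkers=biomarkers)


def tune_rho_for_pearson(
    target_r: float,
    config: GeneratorConfig,
    covariate: str = "CRP",
    n: int = 100_000,
    seed: int = 0,
    tol: float = 0.005,
    max_iter: int = 40,
) -> float:
    """Bisect the latent copula rho so the raw-scale Pearson r between the
    primary biomarker and ``covariate`` hits ``target_r`` at Monte-Carlo
    scale ``n`` (common random numbers across iterations)."""

    def sample_r(rho: float) -> float:
        cfg = replace(
            config, n=n, copula_rho={**config.copula_rho, covariate: rho}
        )
        cohort = generate_cohort(cfg, seed)
        x = cohort.data[config.primary].to_numpy()
        y = cohort.data[covariate].to_numpy()
        return float(np.corrcoef(x, y)[0, 1])

    lo, hi = -0.99, 0.99
    if not sample_r(lo) <= target_r <= sample_r(hi):
        raise ValueError("target correlation unreachable under these marginals")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = sample_r(mid)
        if abs(r - target_r) < tol:
            return mid
        if r < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
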