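"""Binomial GLM fitting, BIC ranking, and genetic-algorithm subset search.

The question the search answers: which routine clinical covariates (CRP,
PCT, WBC, platelets, INR, eNAMPT) combine with the primary biomarker to
improve prediction of death? Candidate models are subsets of main effects
and pairwise interactions under the marginality (hierarchy) constraint — an
interaction enters only alongside both its main effects. Models are scored
by BIC = -2 loglik + k ln n (natural log, k counting the intercept) and the
GA is validated against an exhaustive enumeration oracle.

Logistic fits delegate to statsmodels (IRLS); concentration covariates are
log-transformed before entering the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cohort import CohortTable

__all__ = [
    "EffectSet",
    "GlmFit",
    "GAConfig",
    "ModelSearchResult",
    "CorrelationResult",
    "build_design",
    "fit_logistic_glm",
    "anova_deviance",
    "ga_search",
    "exhaustive_oracle",
    "pearson_correlation",
    "default_candidate_effects",
]

_SEPARATION_BOUND = 15.0  # |beta| beyond this on standardized predictors


def _interaction_parts(effect: str) -> tuple[str, str] | None:
    if ":" in effect:
        a, b = effect.split(":", 1)
        return a, b
    return None


@dataclass(frozen=True)
class EffectSet:
    """A subset of candidate effects as an inclusion vector.

    ``candidates`` is the ordered universe (mains like ``"CRP"``,
    interactions like ``"eNAPRT:CRP"``); ``inclusion`` is the 0/1 vector
    over it. Marginality is enforced at construction.
    """

    candidates: tuple[str, ...]
    inclusion: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.inclusion):
            raise ValueError("inclusion length mismatch")
        included = set(self.effects)
        for eff in self.effects:
            parts = _interaction_parts(eff)
            if parts and not all(p in included for p in parts):
                raise ValueError(
                    f"marginality violated: {eff!r} without both main effects"
                )

    @property
    def effects(self) -> tuple[str, ...]:
        return tuple(
            c for c, inc in zip(self.candidates, self.inclusion) if inc
        )

    @staticmethod
    def repair(candidates, bits) -> "EffectSet":
        """Drop orphan interactions so the vector satisfies marginality."""
        bits = list(bits)
        included = {c for c, b in zip(candidates, bits) if b}
        for i, (c, b) in enumerate(zip(candidates, bits)):
            parts = _interaction_parts(c)
            if b and parts and not all(p in included for p in parts):
                bits[i] = 0
        return EffectSet(tuple(candidates), tuple(bits))


@dataclass
class GlmFit:
    """A fitted binomial GLM with the pieces BIC ranking needs."""

    effects: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    loglik: float
    deviance: float
    n: int
    k: int  # parameter count including the intercept
    bic: float
    converged: bool
    separation: bool


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 100
    tournament_k: int = 3
    crossover_p: float = 0.9
    elitism: int = 2
    top_k: int = 10
    mutation_rate: float | None = None  # default 1/L


@dataclass
class ModelSearchResult:
    ranked: list[tuple[EffectSet, GlmFit]]  # ascending BIC
    trace: list[float] = field(default_factory=list)  # best BIC per generation
    seed: int | None = None
    config: GAConfig | None = None

    @property
    def best(self) -> tuple[EffectSet, GlmFit]:
        return self.ranked[0]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float


def default_candidate_effects(
    primary: str = "eNAPRT",
    covariates: tuple[str, ...] = ("CRP", "PCT", "WBC", "Plts", "INR", "eNAMPT"),
    all_pairs: bool = False,
) -> list[str]:
    """Main effects plus pairwise interactions involving the primary
    biomarker (or all pairs when ``all_pairs``)."""
    mains = [primary, *covariates]
    inter = []
    if all_pairs:
        for i, x in enumerate(mains):
            inter.extend(f"{x}:{y}" for y in mains[i + 1 :])
    else:
        inter = [f"{primary}:{c}" for c in covariates]
    return mains + inter


def build_design(
    cohort: CohortTable,
    effects: tuple[str, ...],
    outcome: str = "outcome",
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Complete-case design matrix (with intercept) and outcome vector.

    Main-effect columns are ln-transformed concentrations (zeros clipped to
    half the smallest positive value); interactions are products of the
    transformed mains.
    """
    mains = sorted({p for e in effects for p in (_interaction_parts(e) or (e,))})
    cols = cohort.data[list(mains) + [outcome]].dropna()
    transformed = {}
    for name in mains:
        v = cols[name].to_numpy(dtype=float)
        if log_transform:
            pos = v[v > 0]
            floor = pos.min() / 2 if pos.size else 1.0
            v = np.log(np.maximum(v, floor))
        transformed[name] = v
    X = pd.DataFrame({"Intercept": np.ones(len(cols))}, index=cols.index)
    for eff in effects:
        parts = _interaction_parts(eff)
        if parts:
            X[eff] = transformed[parts[0]] * transformed[parts[1]]
        else:
            X[eff] = transformed[eff]
    y = cols[outcome].astype(int)
    return X, y


def fit_logistic_glm(design: pd.DataFrame, outcome) -> GlmFit:
    """Maximum-likelihood logistic fit (IRLS via statsmodels).

    The design must already contain the intercept column. Raises on a
    rank-deficient design, naming the dependent columns; flags separation
    when a coefficient diverges on the standardized scale.
    """
    X = pd.DataFrame(design)
    y = np.asarray(outcome, dtype=float)
    if len(X) <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # identify offending columns by QR pivoting on the column order
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = arr[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient design; dependent columns: {bad}")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    n = len(y)
    k = X.shape[1]
    bic = -2.0 * res.llf + k * np.log(n)

    scale = np.where(arr.std(axis=0) > 0, arr.std(axis=0), 1.0)
    separation = bool(np.any(np.abs(res.params.to_numpy() * scale) > _SEPARATION_BOUND))
    return GlmFit(
        effects=tuple(c for c in X.columns if c != "Intercept"),
        params=res.params,
        bse=res.bse,
        loglik=float(res.llf),
        deviance=float(res.deviance),
        n=n,
        k=k,
        bic=float(bic),
        converged=bool(res.converged),
        separation=separation,
    )


def anova_deviance(nested: GlmFit, full: GlmFit) -> float:
    """Likelihood-ratio (analysis of deviance) p-value for nested GLMs.

    p from the chi-square upper tail on the deviance difference with
    df = difference in parameter count.
    """
    if not set(nested.effects) <= set(full.effects):
        raise ValueError("models are not nested")
    if nested.n != full.n:
        raise ValueError("models were fitted to different data")
    d_dev = nested.deviance - full.deviance
    d_df = full.k - nested.k
    if d_df == 0:
        return 1.0
    if d_dev < -1e-6:
        raise ValueError("full model has higher deviance than nested model")
    return float(stats.chi2.sf(max(d_dev, 0.0), df=d_df))


class _FitnessCache:
    """Memoized BIC per inclusion vector (the GA revisits chromosomes)."""

    def __init__(self, cohort, candidates, outcome="outcome"):
        self.cohort = cohort
        self.candidates = tuple(candidates)
        self.outcome = outcome
        self._cache: dict[tuple[int, ...], GlmFit] = {}

    def fit(self, effect_set: EffectSet) -> GlmFit:
        key = effect_set.inclusion
        if key not in self._cache:
            X, y = build_design(
                self.cohort, effect_set.effects, outcome=self.outcome
            )
            self._cache[key] = fit_logistic_glm(X, y)
        return self._cache[key]


def _enumerate_valid(candidates: tuple[str, ...]):
    """All marginality-valid inclusion vectors (lexicographic order)."""
    L = len(candidates)
    for mask in range(2**L):
        bits = tuple((mask >> (L - 1 - i)) & 1 for i in range(L))
        try:
            yield EffectSet(candidates, bits)
        except ValueError:
            continue


def exhaustive_oracle(
    cohort: CohortTable,
    candidates,
    outcome: str = "outcome",
    top_k: int = 10,
) -> ModelSearchResult:
    """Fit every marginality-valid subset; exact BIC ranking.

    Ground truth for GA validation; limited to <= 15 candidate effects.
    """
    candidates = tuple(candidates)
    if len(candidates) > 15:
        raise ValueError("exhaustive search limited to <= 15 candidate effects")
    cache = _FitnessCache(cohort, candidates, outcome)
    fitted = [(es, cache.fit(es)) for es in _enumerate_valid(candidates)]
    fitted.sort(key=lambda t: (t[1].bic, t[0].inclusion))
    return ModelSearchResult(ranked=fitted[: max(top_k, 1)])


def ga_search(
    cohort: CohortTable,
    candidates,
    seed: int,
    config: GAConfig | None = None,
    outcome: str = "outcome",
) -> ModelSearchResult:
    """Genetic-algorithm search over marginality-respecting effect subsets.

    Fitness is -BIC. Tournament selection (k), uniform crossover, per-bit
    mutation, elitism, and a repair operator that drops orphan interactions
    after every variation step. The initial population always contains the
    intercept-only and the (repaired) full chromosome. Deterministic given
    (cohort, candidates, config, seed).
    """
    cfg = config or GAConfig()
    candidates = tuple(candidates)
    L = len(candidates)
    cache = _FitnessCache(cohort, candidates, outcome)
    rng = np.random.default_rng(seed)

    if L == 0:
        es = EffectSet((), ())
        return ModelSearchResult(
            ranked=[(es, cache.fit(es))], trace=[], seed=seed, config=cfg
        )

    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / L

    def make(bits) -> EffectSet:
        return EffectSet.repair(candidates, bits)

    pop = [make([0] * L), make([1] * L)]
    while len(pop) < cfg.population:
        pop.append(make(rng.integers(0, 2, size=L)))

    seen: dict[tuple[int, ...], float] = {}

    def fitness(es: EffectSet) -> float:
        bic = cache.fit(es).bic
        seen[es.inclusion] = bic
        return bic

    scores = [fitness(es) for es in pop]
    trace = [min(scores)]

    for _ in range(cfg.generations):
        order = sorted(
            range(len(pop)), key=lambda i: (scores[i], pop[i].inclusion)
        )
        elites = [pop[i] for i in order[: cfg.elitism]]

        def tournament() -> EffectSet:
            picks = rng.integers(0, len(pop), size=cfg.tournament_k)
            best = min(picks, key=lambda i: (scores[i], pop[i].inclusion))
            return pop[best]

        children = list(elites)
        while len(children) < cfg.population:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_p:
                mask = rng.integers(0, 2, size=L)
                bits = [
                    b1 if m else b2
                    for b1, b2, m in zip(p1.inclusion, p2.inclusion, mask)
                ]
            else:
                bits = list(p1.inclusion)
            flip = rng.random(L) < mut
            bits = [b ^ int(f) for b, f in zip(bits, flip)]
            children.append(make(bits))
        pop = children
        scores = [fitness(es) for es in pop]
        trace.append(min(min(scores), trace[-1]))

    ranked_keys = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
    ranked = [
        (EffectSet(candidates, key), cache.fit(EffectSet(candidates, key)))
        for key, _ in ranked_keys[: max(cfg.top_k, 1)]
    ]
    return ModelSearchResult(ranked=ranked, trace=trace, seed=seed, config=cfg)


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with the two-sided t-transform p and the least-squares line.

    Pairwise-complete cases only; requires >= 3 pairs and non-degenerate
    variance in both variables.
    """
    x = np.asarray(pd.Series(x), dtype=float)
    y = np.asarray(pd.Series(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    lr = stats.linregress(x, y)
    r = float(lr.rvalue)
    return CorrelationResult(
        r=r,
        p=float(max(lr.pvalue, np.finfo(float).tiny)),
        n=int(x.size),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
    )
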