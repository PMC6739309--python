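"""End-to-end orchestration: simulate/load -> scan -> survival -> models.

A :class:`PipelineConfig` names exactly one input source (a cohort CSV or a
generator spec), the analysis columns, and per-stage settings; one integer
seed drives every stochastic stage through derived sub-streams. The report
is a plain JSON-serializable dict plus a human-readable summary; logging
goes to stderr and never into data outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .cohort import CohortTable, read_cohort_table, write_cohort_table
from .models import GAConfig, default_candidate_effects, ga_search
from .scan import ScanConfig, scan_thresholds
from .simulate import generate_cohort, sepsis_default_config
from .survival import logrank_test

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger("riskstrat")

_KNOWN_KEYS = {
    "input_path",
    "generator",
    "schema",
    "biomarker",
    "outcome",
    "time",
    "event",
    "scan",
    "model_search",
    "seed",
    "output_dir",
}


@dataclass
class PipelineConfig:
    input_path: str | None = None
    generator: dict | None = None  # {"n": ..} for the default sepsis cohort
    schema: dict | None = None
    biomarker: str = "eNAPRT"
    outcome: str = "outcome"
    time: str = "time"
    event: str = "event"
    scan: ScanConfig = field(default_factory=ScanConfig)
    model_search: dict = field(default_factory=dict)
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError(
                "config must name exactly one input source "
                "(input_path or generator)"
            )
        if self.generator is not None and self.seed is None:
            raise ValueError("a seed is mandatory when the generator is used")


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON/YAML pipeline config (strict keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "scan" in raw:
        raw["scan"] = ScanConfig(**raw["scan"])
    return PipelineConfig(**raw)


def _get_cohort(config: PipelineConfig) -> CohortTable:
    if config.input_path is not None:
        return read_cohort_table(config.input_path, schema=config.schema)
    gen = dict(config.generator or {})
    n = int(gen.pop("n", 100))
    if gen:
        raise ValueError(f"unknown generator keys: {sorted(gen)}")
    return generate_cohort(sepsis_default_config(n=n), seed=config.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the machine-readable report dict.

    Stages: cohort acquisition, threshold scan with best-cut-off report,
    log-rank survival comparison of the dichotomized groups (when survival
    columns exist), and GA model selection. Any stage error is re-raised
    with the stage name after being logged.
    """
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
    }

    stage = "cohort"
    try:
        t0 = time.perf_counter()
        cohort = _get_cohort(config)
        log.info("stage %s: n=%d (%.2fs)", stage, cohort.n, time.perf_counter() - t0)
        report["cohort"] = {
            "n": cohort.n,
            "biomarkers": cohort.biomarkers,
            "n_events": int(cohort.outcomes().sum()),
        }

        stage = "scan"
        t0 = time.perf_counter()
        ledger = scan_thresholds(cohort, config.biomarker, config.scan)
        best = ledger.best
        m = best.matrix
        report["scan"] = {
            "n_candidates": len(ledger.records),
            "best": best.to_dict(),
            "mortality_high_pct": round(100 * m.risk_exposed, 1),
            "mortality_low_pct": round(100 * m.risk_unexposed, 1),
        }
        log.info(
            "stage %s: %d candidates, best tau=%.3g (%.2fs)",
            stage, len(ledger.records), best.tau, time.perf_counter() - t0,
        )

        stage = "survival"
        if cohort.has_survival:
            t0 = time.perf_counter()
            vals = cohort.biomarker_values(config.biomarker)
            keep = vals.notna()
            df = cohort.data[keep]
            grp = (vals[keep] >= best.tau).astype(int)
            lr = logrank_test(df["time"], df["event"], grp)
            report["survival"] = {
                "threshold": best.tau,
                "logrank_statistic": lr.statistic,
                "logrank_p": lr.p,
                "observed": lr.observed,
                "expected": lr.expected,
            }
            log.info("stage %s: logrank p=%.3g (%.2fs)",
                     stage, lr.p, time.perf_counter() - t0)

        stage = "model_search"
        t0 = time.perf_counter()
        ms = dict(config.model_search)
        covs = tuple(
            ms.get("covariates")
            or [b for b in cohort.biomarkers
                if b != config.biomarker
                and b in ("CRP", "PCT", "WBC", "Plts", "INR", "eNAMPT")]
        )
        candidates = default_candidate_effects(config.biomarker, covs)
        ga_cfg = GAConfig(**ms.get("ga", {}))
        result = ga_search(cohort, candidates, seed=int(config.seed or 0),
                           config=ga_cfg)
        report["model_search"] = {
            "candidates": candidates,
            "ranked": [
                {"effects": list(es.effects), "bic": fit.bic, "k": fit.k}
                for es, fit in result.ranked
            ],
            "best_effects": list(result.best[0].effects),
            "best_bic": result.best[1].bic,
        }
        log.info("stage %s: best BIC %.2f (%.2fs)",
                 stage, result.best[1].bic, time.perf_counter() - t0)
    except Exception as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.output_dir:
        import pathlib

        out = pathlib.Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_table(cohort, out / "cohort.csv")
        ledger.to_json(out / "ledger.json")
        ledger.to_tsv(out / "ledger.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def summarize_report(report: dict) -> str:
    """Human-readable one-screen summary of a pipeline report."""
    lines = [f"riskstrat v{report['version']} (seed={report['seed']})"]
    c = report["cohort"]
    lines.append(f"cohort: n={c['n']}, events={c['n_events']}")
    s = report["scan"]
    b = s["best"]
    lines.append(
        f"best cut-off: tau={b['tau']:.3g}  matrix=({b['a']},{b['b']},"
        f"{b['c']},{b['d']})  fisher_p={b['fisher_p']:.3g}"
    )
    lines.append(
        f"  mortality >= tau: {s['mortality_high_pct']}%   "
        f"< tau: {s['mortality_low_pct']}%   "
        f"RR={b['rr']:.3g} [{b['ci_low']:.3g}, {b['ci_high']:.3g}]"
    )
    if "survival" in report:
        lr = report["survival"]
        lines.append(
            f"log-rank: chi2={lr['logrank_statistic']:.3g} p={lr['logrank_p']:.3g}"
        )
    if "model_search" in report:
        m = report["model_search"]
        lines.append(
            f"best model: {' + '.join(m['best_effects']) or 'intercept only'}"
            f"  BIC={m['best_bic']:.2f}"
        )
    return "\n".join(lines)


def _config_echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
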