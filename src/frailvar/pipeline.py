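"""End-to-end analysis pipeline over collections of cohort tables.

For each mortality table and each starting age: fit the GGM parameters by
Poisson maximum likelihood, discretize the fitted frailty distribution
(collapsing to a single class when the estimated variance is below the
degeneracy threshold), build the age x frailty projection matrix, and
decompose the variance of remaining longevity.  Period (single calendar
year) tables run through the identical pipeline -- the cohort/period
distinction is only a labelling concern.  Per-cohort fit failures are
recorded with a flag and skipped, never fatal to a sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import MortalityData
from .decomposition import LongevityDecomposition, matrix_decomposition
from .estimation import GGMFit, fit_ggm
from .ggm import (
    DEFAULT_G,
    DEFAULT_OMEGA,
    DEFAULT_Q_MAX,
    DEFAULT_Q_MIN,
    GAMMA_DEGENERACY_THRESHOLD,
    discretize_frailty,
)

__all__ = [
    "AnalysisConfig",
    "DecompositionResult",
    "run_decomposition_analysis",
    "summarize_periods",
    "results_to_frame",
    "DEFAULT_PERIOD_BINS",
]

logger = logging.getLogger("frailvar")

#: Historical periods used to average the heterogeneity fraction over
#: cohorts; the third period runs to 1903 for France in published analyses
#: (override per country via AnalysisConfig.period_bins).
DEFAULT_PERIOD_BINS = [
    ("1751-1815", 1751, 1815),
    ("1816-1871", 1816, 1871),
    ("1872-1899", 1872, 1899),
]


@dataclass
class AnalysisConfig:
    """Settings for a decomposition sweep; defaults are the study conditions."""

    starting_ages: Sequence[int] = (40, 50, 60, 70)
    g: int = DEFAULT_G
    omega: int = DEFAULT_OMEGA
    q_min: float = DEFAULT_Q_MIN
    q_max: float = DEFAULT_Q_MAX
    gamma_degeneracy_threshold: float = GAMMA_DEGENERACY_THRESHOLD
    optimizer: dict = field(default_factory=dict)
    seed: int | None = None
    period_bins: Sequence[tuple[str, int, int]] = tuple(DEFAULT_PERIOD_BINS)

    def __post_init__(self) -> None:
        bins = sorted(self.period_bins, key=lambda b: b[1])
        for (_, _, hi), (label, lo, _) in zip(bins[:-1], bins[1:]):
            if lo <= hi:
                raise ValueError(f"period bins overlap at {label}")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "period_bins" in d:
            d = dict(d)
            d["period_bins"] = [tuple(b) for b in d["period_bins"]]
        return cls(**d)


@dataclass
class DecompositionResult:
    """One (cohort, sex, starting age) row of a sweep."""

    cohort_label: str
    sex: str
    start_age: int
    fit: GGMFit | None
    decomposition: LongevityDecomposition | None
    failed: bool = False
    failure_reason: str = ""
    degenerate: bool = False  # gamma-hat below threshold: single frailty class


def _analyze_one(
    table: MortalityData, start_age: int, config: AnalysisConfig
) -> DecompositionResult:
    fit = fit_ggm(
        table, start_age,
        optimizer_config=config.optimizer or None,
        seed=config.seed,
    )
    p = fit.params
    degenerate = p.gamma < config.gamma_degeneracy_threshold
    frailty = discretize_frailty(
        0.0 if degenerate else p.gamma, config.g, config.q_min, config.q_max
    )
    decomp = matrix_decomposition(p, frailty, config.omega)
    logger.info(
        "cohort=%s sex=%s start_age=%d a=%.4g b=%.4g c=%.4g gamma=%.4g "
        "degenerate=%s fraction=%.4f",
        table.cohort_label, table.sex, start_age,
        p.a, p.b, p.c, p.gamma, degenerate, decomp.fraction_heterogeneity,
    )
    return DecompositionResult(
        cohort_label=table.cohort_label,
        sex=table.sex,
        start_age=start_age,
        fit=fit,
        decomposition=decomp,
        degenerate=degenerate,
    )


def run_decomposition_analysis(
    tables: Iterable[MortalityData],
    config: AnalysisConfig | None = None,
) -> list[DecompositionResult]:
    """Run fit -> discretize -> build -> decompose for every table x starting age.

    Deterministic given the config seed.  Individual failures are logged
    and returned as flagged rows.
    """
    config = config or AnalysisConfig()
    tables = list(tables)
    if not tables:
        raise ValueError("no mortality tables provided")

    results = []
    for table in tables:
        for start_age in config.starting_ages:
            try:
                results.append(_analyze_one(table, start_age, config))
            except Exception as exc:
                logger.warning(
                    "cohort=%s sex=%s start_age=%d failed: %s",
                    table.cohort_label, table.sex, start_age, exc,
                )
                results.append(
                    DecompositionResult(
                        cohort_label=table.cohort_label,
                        sex=table.sex,
                        start_age=start_age,
                        fit=None,
                        decomposition=None,
                        failed=True,
                        failure_reason=str(exc),
                    )
                )
    return results


def results_to_frame(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """One TSV-ready row per (cohort, sex, start_age): parameters and variances."""
    rows = []
    for r in results:
        row = {
            "cohort": r.cohort_label,
            "sex": r.sex,
            "start_age": r.start_age,
            "failed": r.failed,
            "degenerate": r.degenerate,
        }
        if r.fit is not None:
            p = r.fit.params
            row.update(a=p.a, b=p.b, c=p.c, gamma=p.gamma,
                       log_likelihood=r.fit.log_likelihood,
                       converged=r.fit.converged)
        if r.decomposition is not None:
            d = r.decomposition
            row.update(
                mean_longevity=d.mixture_mean,
                mean_after_start=d.mean_after_start,
                v_total=d.v_total,
                v_within=d.v_within,
                v_between=d.v_between,
                fraction_heterogeneity=d.fraction_heterogeneity,
            )
        if r.failed:
            row["failure_reason"] = r.failure_reason
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_periods(
    results: Sequence[DecompositionResult],
    period_bins: Sequence[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Mean heterogeneity fraction per (sex, start_age, period).

    Cohort labels must parse as birth years to be binned.  Bins with no
    cohorts are reported with NaN mean and count 0, never as zero.
    """
    if not results:
        raise ValueError("no results to summarize")
    bins = period_bins or DEFAULT_PERIOD_BINS

    usable = [r for r in results if not r.failed and r.decomposition is not None]
    rows = []
    sexes = sorted({r.sex for r in usable})
    ages = sorted({r.start_age for r in usable})
    for label, lo, hi in bins:
        for sex in sexes:
            for start_age in ages:
                fracs = [
                    r.decomposition.fraction_heterogeneity
                    for r in usable
                    if r.sex == sex and r.start_age == start_age
                    and _cohort_year(r.cohort_label) is not None
                    and lo <= _cohort_year(r.cohort_label) <= hi
                ]
                rows.append({
                    "period": label,
                    "sex": sex,
                    "start_age": start_age,
                    "n_cohorts": len(fracs),
                    "mean_fraction_heterogeneity":
                        float(np.mean(fracs)) if fracs else float("nan"),
                })
    return pd.DataFrame(rows)


def _cohort_year(label: str) -> int | None:
    try:
        return int(label)
    except (TypeError, ValueError):
        return None
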