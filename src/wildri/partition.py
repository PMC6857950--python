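"""Demographic partition analyses: summaries, tests, model selection.

Analytes are summarised and compared across age class, sex, month, year
and site. Test dispatch is normality-gated: when every group passes the
Shapiro-Wilk screen the parametric branch runs (t-test for two groups,
one-way ANOVA for more), otherwise the rank-based branch (Mann-Whitney
U, Kruskal-Wallis). Significant omnibus tests are followed by pairwise
two-sample tests. A general-linear-model stage fits candidate OLS models
over the demographic factors and ranks them by AICc with Akaike weights;
the default candidate set is every subset of the five main effects plus
the global model with all two-way interactions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .datamodel import DEMOGRAPHIC_FACTORS, Dataset
from .screening import assess_normality

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "LinearFit",
    "ModelCandidate",
    "analysis_frame",
    "summarize_groups",
    "compare_groups",
    "fit_linear_model",
    "select_model",
    "default_candidate_set",
]

MIN_LEVEL_N = 2


@dataclass(frozen=True)
class GroupSummary:
    analyte: str
    factor: str
    level: str
    n: int
    center: float          # mean (normal) or median (non-normal)
    spread_low: float      # 95% CI of the mean, or 10th percentile
    spread_high: float     # 95% CI of the mean, or 90th percentile
    min: float
    max: float
    normal: bool

    def __post_init__(self) -> None:
        if self.spread_low > self.spread_high + 1e-12 or self.min > self.max:
            raise ValueError(f"{self.analyte}/{self.level}: inverted spread")


@dataclass(frozen=True)
class ComparisonResult:
    analyte: str
    factor: str
    test: str              # t, anova, mann_whitney, kruskal_wallis
    statistic: float
    p: float
    pairwise: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"p={self.p} outside [0, 1]")


@dataclass(frozen=True)
class LinearFit:
    analyte: str
    terms: tuple[tuple[str, ...], ...]
    coefficients: dict[str, float]
    rss: float
    k: int                 # estimated coefficients + 1 (residual variance)
    n: int


@dataclass(frozen=True)
class ModelCandidate:
    analyte: str
    terms: tuple[tuple[str, ...], ...]
    k: int
    aicc: float
    delta_aicc: float
    weight: float


def analysis_frame(
    data: Dataset, analyte: str, dedup: str = "first"
) -> pd.DataFrame:
    """Per-sample frame for one analyte, demographics as categoricals.

    ``dedup="first"`` keeps each animal's first capture (by date) so
    repeated measures do not masquerade as independent observations;
    ``dedup="all"`` keeps every sample.
    """
    if dedup not in ("first", "all"):
        raise ValueError(f"unknown dedup strategy {dedup!r}")
    rows = [
        {
            "animal_id": s.animal_id,
            "date": s.date,
            "value": s.values[analyte],
            "age_class": s.age_class,
            "sex": s.sex,
            "month": s.month,
            "year": str(s.year),
            "site": s.site,
        }
        for s in data.samples
        if analyte in s.values
    ]
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError(f"{analyte}: no values available")
    if dedup == "first":
        frame = (
            frame.sort_values(["animal_id", "date"], kind="stable")
            .groupby("animal_id", as_index=False)
            .first()
        )
    return frame.reset_index(drop=True)


def _levels(frame: pd.DataFrame, factor: str) -> dict[str, np.ndarray]:
    if factor not in DEMOGRAPHIC_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    out: dict[str, np.ndarray] = {}
    for level, sub in frame.groupby(factor, sort=True, observed=True):
        vals = sub["value"].to_numpy(dtype=float)
        if vals.size < MIN_LEVEL_N:
            warnings.warn(
                f"{factor}={level}: n={vals.size} < {MIN_LEVEL_N}; level dropped"
            )
            continue
        out[str(level)] = vals
    return out


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if values.size < 3 or np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assess_normality(values, alpha=alpha).normal


def summarize_groups(
    data: Dataset, analyte: str, factor: str, alpha: float = 0.05,
    dedup: str = "all",
) -> list[GroupSummary]:
    """Descriptive summary per factor level.

    Normally distributed levels report the mean with its t-based 95%
    confidence interval; other levels report the median with the
    10th-90th percentile range. Minimum and maximum always reported.
    """
    frame = analysis_frame(data, analyte, dedup=dedup)
    out = []
    for level, vals in _levels(frame, factor).items():
        normal = _is_normal(vals, alpha)
        if normal:
            m = vals.mean()
            sem = vals.std(ddof=1) / math.sqrt(vals.size)
            if sem == 0:
                lo = hi = m
            else:
                lo, hi = stats.t.interval(0.95, vals.size - 1, loc=m, scale=sem)
            center, s_lo, s_hi = m, lo, hi
        else:
            center = float(np.median(vals))
            s_lo, s_hi = np.percentile(vals, [10, 90])
        out.append(
            GroupSummary(
                analyte=analyte,
                factor=factor,
                level=level,
                n=int(vals.size),
                center=float(center),
                spread_low=float(s_lo),
                spread_high=float(s_hi),
                min=float(vals.min()),
                max=float(vals.max()),
                normal=normal,
            )
        )
    return out


def _two_sample(a: np.ndarray, b: np.ndarray, parametric: bool) -> tuple[float, float]:
    if parametric:
        r = stats.ttest_ind(a, b)
    else:
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(r.statistic), float(r.pvalue)


def compare_groups(
    data: Dataset,
    analyte: str,
    factor: str,
    alpha: float = 0.05,
    dedup: str = "all",
) -> ComparisonResult:
    """Normality-gated omnibus comparison across factor levels.

    The parametric branch (t-test / one-way ANOVA) is taken only when
    every usable level passes the Shapiro-Wilk screen; otherwise the
    rank branch (Mann-Whitney U / Kruskal-Wallis). With more than two
    levels and omnibus p < alpha, pairwise two-sample tests follow using
    the same gate per pair. For the sex factor, pairwise reporting is
    restricted to female vs male (the unknown-sex level stays in the
    omnibus test and in modeling).
    """
    frame = analysis_frame(data, analyte, dedup=dedup)
    levels = _levels(frame, factor)
    if len(levels) < 2:
        raise ValueError(f"{analyte}/{factor}: fewer than 2 usable levels")
    flags = {lvl: _is_normal(v, alpha) for lvl, v in levels.items()}
    parametric = all(flags.values())
    names = list(levels)
    arrays = [levels[n] for n in names]

    if len(names) == 2:
        test = "t" if parametric else "mann_whitney"
        statistic, p = _two_sample(arrays[0], arrays[1], parametric)
        pairwise: tuple[tuple[str, str, float], ...] = ()
    else:
        if parametric:
            test = "anova"
            r = stats.f_oneway(*arrays)
        else:
            test = "kruskal_wallis"
            r = stats.kruskal(*arrays)
        statistic, p = float(r.statistic), float(r.pvalue)
        pairwise = ()
        if p < alpha:
            pairs = []
            for la, lb in itertools.combinations(names, 2):
                if factor == "sex" and {la, lb} != {"female", "male"}:
                    continue
                _, pp = _two_sample(
                    levels[la], levels[lb], flags[la] and flags[lb]
                )
                pairs.append((la, lb, pp))
            pairwise = tuple(pairs)
    return ComparisonResult(
        analyte=analyte,
        factor=factor,
        test=test,
        statistic=statistic,
        p=p,
        pairwise=pairwise,
    )


def _formula(terms: tuple[tuple[str, ...], ...]) -> str:
    if not terms:
        return "value ~ 1"
    parts = []
    for term in terms:
        parts.append(":".join(f"C({f})" for f in term))
    return "value ~ " + " + ".join(parts)


def fit_linear_model(
    data: Dataset,
    analyte: str,
    terms: tuple[tuple[str, ...], ...],
    dedup: str = "first",
    frame: pd.DataFrame | None = None,
) -> LinearFit:
    """Ordinary least squares with dummy-coded factors.

    ``terms`` is a tuple of main effects ``("site",)`` and two-way
    interactions ``("site", "year")``. Aliased (rank-deficient) columns
    are dropped with a warning; ``k`` counts estimated coefficients plus
    one for the residual variance.
    """
    if frame is None:
        frame = analysis_frame(data, analyte, dedup=dedup)
    model = smf.ols(_formula(terms), data=frame)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        warnings.warn(
            f"{analyte}: design matrix rank {rank} < {model.exog.shape[1]} "
            "columns; aliased columns dropped"
        )
    fit = model.fit()
    return LinearFit(
        analyte=analyte,
        terms=terms,
        coefficients=dict(fit.params),
        rss=float(fit.ssr),
        k=int(rank) + 1,
        n=int(fit.nobs),
    )


def default_candidate_set(
    factors: tuple[str, ...] = DEMOGRAPHIC_FACTORS,
) -> list[tuple[tuple[str, ...], ...]]:
    """All main-effect subsets plus the global two-way-interaction model."""
    mains = [(f,) for f in factors]
    candidates: list[tuple[tuple[str, ...], ...]] = []
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            candidates.append(tuple(combo))
    global_model = tuple(mains) + tuple(
        (a, b) for (a,), (b,) in itertools.combinations(mains, 2)
    )
    candidates.append(global_model)
    return candidates


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike information criterion for a Gaussian fit."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    if rss <= 0:
        rss = 1e-300  # perfect fit; keep the criterion finite and dominant
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def select_model(
    data: Dataset,
    analyte: str,
    candidates: list[tuple[tuple[str, ...], ...]] | None = None,
    dedup: str = "first",
    criterion: str = "aicc",
) -> list[ModelCandidate]:
    """Rank candidate OLS models by AICc (or plain AIC) with weights.

    Candidates whose sample size cannot support the parameter count are
    skipped with a warning. Akaike weights are normalised over the
    candidates actually fitted and sum to one.
    """
    if criterion not in ("aicc", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if candidates is None:
        candidates = default_candidate_set()
    frame = analysis_frame(data, analyte, dedup=dedup)
    fitted: list[tuple[tuple[tuple[str, ...], ...], int, float]] = []
    for terms in candidates:
        fit = fit_linear_model(data, analyte, terms, frame=frame)
        if criterion == "aicc" and fit.n - fit.k - 1 <= 0:
            warnings.warn(
                f"{analyte}: candidate {terms} skipped (n={fit.n}, k={fit.k})"
            )
            continue
        if criterion == "aicc":
            score = aicc(fit.rss, fit.n, fit.k)
        else:
            score = fit.n * math.log(max(fit.rss, 1e-300) / fit.n) + 2 * fit.k
        fitted.append((terms, fit.k, score))
    if not fitted:
        raise ValueError(f"{analyte}: no candidate model could be scored")
    best = min(score for _, _, score in fitted)
    deltas = [score - best for _, _, score in fitted]
    raw = np.exp(-0.5 * np.asarray(deltas))
    weights = raw / raw.sum()
    ranked = sorted(
        zip(fitted, deltas, weights), key=lambda t: t[0][2]
    )
    return [
        ModelCandidate(
            analyte=analyte,
            terms=terms,
            k=k,
            aicc=score,
            delta_aicc=delta,
            weight=float(w),
        )
        for (terms, k, score), delta, w in ranked
    ]
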