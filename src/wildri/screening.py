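"""Pre-analytical gatekeeping: inclusion rules, outlier flags, normality.

Whole samples are excluded on clinical-exam or sample-quality grounds;
statistical outliers are then flagged per analyte, so each analyte keeps
its own retained subset. The default outlier screen is Horn's method:
a maximum-likelihood Box-Cox transform followed by Tukey fences at
1.5 interquartile ranges, the de-facto standard for reference-interval
outlier detection. Distribution shape is called by the Shapiro-Wilk test
at alpha 0.05, with skewness and excess kurtosis reported as diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import Dataset

__all__ = [
    "ScreeningReport",
    "NormalityResult",
    "apply_inclusion",
    "detect_outliers",
    "assess_normality",
    "screen_analyte",
]

MIN_OUTLIER_N = 20


@dataclass(frozen=True)
class NormalityResult:
    normal: bool
    shapiro_p: float
    skewness: float
    excess_kurtosis: float

    @property
    def label(self) -> str:
        return "normal" if self.normal else "non-normal"


@dataclass(frozen=True)
class ScreeningReport:
    """Per-analyte accounting of exclusions and the distribution call.

    Counts are disjoint and sequential: exam exclusions first, quality
    exclusions among the remainder, missing values among included
    samples, then outliers among present values, so that
    ``n_retained = n_input - n_excluded_exam - n_excluded_quality -
    n_missing - len(outlier_sample_ids)``.
    """

    analyte: str
    n_input: int
    n_excluded_exam: int
    n_excluded_quality: int
    n_missing: int
    outlier_sample_ids: tuple[int, ...]
    n_retained: int
    normality: str
    shapiro_p: float
    skewness: float
    excess_kurtosis: float

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_excluded_exam
            - self.n_excluded_quality
            - self.n_missing
            - len(self.outlier_sample_ids)
        )
        if self.n_retained != expected:
            raise ValueError(
                f"{self.analyte}: inconsistent counts "
                f"(retained {self.n_retained}, expected {expected})"
            )


def apply_inclusion(data: Dataset) -> Dataset:
    """Drop samples with an abnormal exam or poor sample quality."""
    kept = [
        s for s in data.samples
        if not s.exam_abnormal and not s.sample_quality_poor
    ]
    return Dataset(samples=kept, analytes=data.analytes)


def detect_outliers(values: np.ndarray, method: str = "horn") -> np.ndarray:
    """Indexes of values outside Tukey fences, optionally after Box-Cox.

    ``horn`` transforms by maximum-likelihood Box-Cox (values shifted to
    be strictly positive first) and applies the fences on the
    transformed scale; ``tukey_raw`` fences the raw values; ``none``
    flags nothing. Fewer than 20 values, or a constant vector, returns
    an empty set (with a warning in the former case). A single pass only
    — flagging is not iterated.
    """
    values = np.asarray(values, dtype=float)
    if method == "none":
        return np.array([], dtype=int)
    if method not in ("horn", "tukey_raw"):
        raise ValueError(f"unknown outlier method {method!r}")
    if values.size < MIN_OUTLIER_N:
        warnings.warn(
            f"only {values.size} values (< {MIN_OUTLIER_N}); skipping outlier "
            "detection"
        )
        return np.array([], dtype=int)
    if np.ptp(values) == 0:
        return np.array([], dtype=int)

    work = values
    if method == "horn":
        shifted = values
        lo = values.min()
        if lo <= 0:
            shifted = values - lo + 1e-6 * max(np.ptp(values), 1.0)
        work, _ = stats.boxcox(shifted)
    q1, q3 = np.percentile(work, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return np.nonzero((work < lower) | (work > upper))[0]


def assess_normality(values: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality call with shape diagnostics.

    ``normal`` iff the Shapiro-Wilk p-value exceeds ``alpha``. Constant
    vectors are classified non-normal with a warning (the test statistic
    is undefined for them). Valid for 3 <= n <= 5000.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={values.size}")
    if np.ptp(values) == 0:
        warnings.warn("constant vector: classifying as non-normal")
        return NormalityResult(False, 0.0, 0.0, 0.0)
    p = float(stats.shapiro(values).pvalue)
    return NormalityResult(
        normal=p > alpha,
        shapiro_p=p,
        skewness=float(stats.skew(values)),
        excess_kurtosis=float(stats.kurtosis(values)),
    )


def screen_analyte(
    data: Dataset,
    analyte: str,
    method: str = "horn",
    alpha: float = 0.05,
) -> tuple[ScreeningReport, np.ndarray]:
    """Full screening pass for one analyte.

    Returns the report and the retained value vector (inclusion-passing,
    non-missing, non-outlier), in sample order. Outlier sample ids index
    into ``data.samples``.
    """
    n_input = len(data.samples)
    exam_idx = [i for i, s in enumerate(data.samples) if s.exam_abnormal]
    quality_idx = [
        i for i, s in enumerate(data.samples)
        if not s.exam_abnormal and s.sample_quality_poor
    ]
    included = [
        i for i, s in enumerate(data.samples)
        if not s.exam_abnormal and not s.sample_quality_poor
    ]
    present = [i for i in included if analyte in data.samples[i].values]
    n_missing = len(included) - len(present)
    values = np.array([data.samples[i].values[analyte] for i in present])

    out_local = detect_outliers(values, method=method)
    outlier_ids = tuple(present[j] for j in out_local)
    keep_mask = np.ones(values.size, dtype=bool)
    keep_mask[out_local] = False
    retained = values[keep_mask]

    if retained.size >= 3:
        norm = assess_normality(retained, alpha=alpha)
    else:
        warnings.warn(f"{analyte}: fewer than 3 retained values; calling non-normal")
        norm = NormalityResult(False, 0.0, 0.0, 0.0)

    report = ScreeningReport(
        analyte=analyte,
        n_input=n_input,
        n_excluded_exam=len(exam_idx),
        n_excluded_quality=len(quality_idx),
        n_missing=n_missing,
        outlier_sample_ids=outlier_ids,
        n_retained=int(retained.size),
        normality=norm.label,
        shapiro_p=norm.shapiro_p,
        skewness=norm.skewness,
        excess_kurtosis=norm.excess_kurtosis,
    )
    return report, retained
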