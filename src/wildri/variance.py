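"""Within/between-animal variance decomposition, individuality, RCV.

Longitudinally sampled animals let an analyte's variation be split into
a within-animal component (CVi) and a between-animal component (CVg) by
a one-way random-effects analysis of variance, estimated by the method
of moments on the unbalanced design. Two derived quantities drive
interpretation:

* the index of individuality, the ratio of within-animal (optionally
  plus analytical) variation to between-animal variation — below 0.6 an
  individual's results drift so little relative to the population that
  a population-based reference interval is insensitive, and a
  subject-based reference (the animal as its own baseline) is preferred;
* the reference change value (RCV), the smallest relative difference
  between two serial results in one animal that exceeds expected
  within-animal plus analytical noise at 95% confidence.

Two index variants and two RCV variants are reported because published
usage varies in whether the analytical CV enters the formula; the
variant used for the reference-type decision is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import AnalyteDefinition, Dataset

__all__ = [
    "VarianceComponents",
    "estimate_cvs",
    "index_of_individuality",
    "reference_change_value",
    "decide_ri_type",
    "compute_components",
]

Z_TWO_SIDED_95 = 1.96
INDEX_THRESHOLD = 0.6


@dataclass(frozen=True)
class VarianceComponents:
    analyte: str
    cv_i: float
    cv_g: float
    cv_a: float | None
    n_animals: int
    n_samples: int
    index_with_cva: float
    index_without_cva: float
    rcv_stated: float
    rcv_combined: float
    ri_type: str

    def __post_init__(self) -> None:
        if self.cv_i < 0 or self.cv_g < 0:
            raise ValueError(f"{self.analyte}: CVs must be >= 0")
        if self.rcv_combined < self.rcv_stated - 1e-12:
            raise ValueError(f"{self.analyte}: combined RCV below stated RCV")
        if self.ri_type not in ("subject", "population"):
            raise ValueError(f"{self.analyte}: bad ri_type {self.ri_type!r}")


def estimate_cvs(data: Dataset, analyte: str) -> tuple[float, float, int, int]:
    """Method-of-moments one-way random-effects CV estimates.

    Only animals with at least two non-missing values of the analyte
    enter. With per-animal counts n_a (total N over k animals):

    * pooled within-animal variance
      ``s_w^2 = sum_a sum_j (x_aj - xbar_a)^2 / sum_a (n_a - 1)``,
    * between-animal mean square
      ``MS_b = sum_a n_a (xbar_a - xbar)^2 / (k - 1)``,
    * effective group size ``n0 = (N - sum_a n_a^2 / N) / (k - 1)``,
    * between-animal variance ``s_b^2 = max(0, (MS_b - s_w^2) / n0)``
      (negative moment estimates truncate to zero).

    Returns ``(cv_i, cv_g, k, N)`` with CVs relative to the grand mean
    of the repeat-sampled subset. On a balanced design this is exactly
    the classical one-way ANOVA decomposition.
    """
    groups = {}
    for s in data.samples:
        if analyte in s.values:
            groups.setdefault(s.animal_id, []).append(s.values[analyte])
    groups = {a: np.asarray(v, float) for a, v in groups.items() if len(v) >= 2}
    k = len(groups)
    if k < 2:
        raise ValueError(
            f"{analyte}: need >= 2 animals with repeat samples, found {k}"
        )
    counts = np.array([len(v) for v in groups.values()])
    N = int(counts.sum())
    allvals = np.concatenate(list(groups.values()))
    grand = allvals.mean()
    if grand <= 0:
        raise ValueError(f"{analyte}: grand mean {grand} <= 0, CVs undefined")

    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    s_w2 = ss_within / (N - k)
    means = np.array([v.mean() for v in groups.values()])
    ms_between = float((counts * (means - grand) ** 2).sum() / (k - 1))
    n0 = (N - (counts**2).sum() / N) / (k - 1)
    s_b2 = max(0.0, (ms_between - s_w2) / n0)

    return math.sqrt(s_w2) / grand, math.sqrt(s_b2) / grand, k, N


def index_of_individuality(
    cv_i: float, cv_g: float, cv_a: float | None = None
) -> tuple[float, float]:
    """Both index variants: ``((cv_i + cv_a) / cv_g, cv_i / cv_g)``.

    Without an analytical CV the two coincide. Undefined when the
    between-animal CV is zero.
    """
    if cv_g <= 0:
        raise ValueError("index of individuality undefined for cv_g <= 0")
    without = cv_i / cv_g
    with_cva = (cv_i + cv_a) / cv_g if cv_a is not None else without
    return with_cva, without


def reference_change_value(
    cv_i: float, cv_a: float | None = None
) -> tuple[float, float]:
    """RCV as a proportion: ``(1.96 sqrt2 CVi, 1.96 sqrt2 sqrt(CVa^2+CVi^2))``.

    The first (stated) variant ignores analytical noise; the second
    (combined) folds it in and reduces to the first when CVa is absent.
    """
    if cv_i < 0:
        raise ValueError("cv_i must be >= 0")
    base = Z_TWO_SIDED_95 * math.sqrt(2.0)
    stated = base * cv_i
    a = cv_a if cv_a is not None else 0.0
    combined = base * math.hypot(a, cv_i)
    return stated, combined


def decide_ri_type(index: float, threshold: float = INDEX_THRESHOLD) -> str:
    """``subject`` iff the index is strictly below the threshold.

    An index exactly at the threshold yields ``population`` — the more
    general interval type.
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    return "subject" if index < threshold else "population"


def compute_components(
    data: Dataset,
    analyte: AnalyteDefinition,
    index_variant: str = "without_cva",
    threshold: float = INDEX_THRESHOLD,
) -> VarianceComponents:
    """Assemble the full variance-component record for one analyte.

    ``index_variant`` selects which index drives the reference-type
    decision: ``"without_cva"`` (default) or ``"with_cva"``.
    """
    if index_variant not in ("without_cva", "with_cva"):
        raise ValueError(f"unknown index variant {index_variant!r}")
    cv_i, cv_g, k, n = estimate_cvs(data, analyte.name)
    idx_with, idx_without = index_of_individuality(cv_i, cv_g, analyte.analytical_cv)
    rcv_stated, rcv_combined = reference_change_value(cv_i, analyte.analytical_cv)
    deciding = idx_without if index_variant == "without_cva" else idx_with
    return VarianceComponents(
        analyte=analyte.name,
        cv_i=cv_i,
        cv_g=cv_g,
        cv_a=analyte.analytical_cv,
        n_animals=k,
        n_samples=n,
        index_with_cva=idx_with,
        index_without_cva=idx_without,
        rcv_stated=rcv_stated,
        rcv_combined=rcv_combined,
        ri_type=decide_ri_type(deciding, threshold),
    )
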