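"""Method-comparison statistics: Passing-Bablok, Kendall tau-b, weighted kappa.

Passing-Bablok regression is implemented from the original 1983 procedure:
the slope is the shifted median of all pairwise slopes S_ij, with slopes
equal to -1 excluded and the median offset by K = #{S_ij < -1} so the
estimator is invariant under swapping the axes; confidence bounds come
from rank positions around the median using the normal approximation of
the Kendall statistic.  Kendall's tau-b (tie-corrected) is delegated to
scipy.  The weighted Cohen's kappa uses LINEAR disagreement weights
w_ij = |i - j| / (k - 1), the convention appropriate for ordered
therapeutic categories a single band apart being a milder error than two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from vancoauc.pk_core import DomainError

__all__ = [
    "AUC_CATEGORIES",
    "AgreementTable",
    "KappaResult",
    "KendallResult",
    "PBRegression",
    "classify_auc",
    "kendall_tau_b",
    "passing_bablok",
    "weighted_kappa",
]

#: Ordered therapeutic categories for AUC24 (mg*h/L), low to high.
AUC_CATEGORIES = ("<400", "400-600", ">600")


def classify_auc(auc: float) -> str:
    """Three-way therapeutic classification with a *closed* band [400, 600]."""
    if not auc >= 0:
        raise DomainError(f"auc must be >= 0, got {auc!r}")
    if auc < 400.0:
        return AUC_CATEGORIES[0]
    if auc <= 600.0:
        return AUC_CATEGORIES[1]
    return AUC_CATEGORIES[2]


def classify_index(auc: float) -> int:
    """Ordinal index (0, 1, 2) of :func:`classify_auc`."""
    return AUC_CATEGORIES.index(classify_auc(auc))


@dataclass(frozen=True)
class PBRegression:
    """Passing-Bablok slope/intercept with 95% confidence intervals."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n: int


def passing_bablok(x, y, conf: float = 0.95) -> PBRegression:
    """Passing-Bablok method-comparison regression of y on x.

    Pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i) over all i < j; pairs
    with dx = dy = 0 are uninformative and dropped, dx = 0 alone yields an
    infinite slope with the sign of dy.  Slopes exactly equal to -1 are
    excluded and K = #{S_ij < -1} shifts the median, making the estimate
    equivariant under exchanging the two methods.  Confidence bounds use
    rank positions M1/M2 around the shifted median with
    C_gamma = z_{1-gamma/2} * sqrt(n(n-1)(2n+5)/18).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise DomainError("need at least 3 points")
    if np.all(x == x[0]):
        raise DomainError("all x identical; slopes undefined")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    s = np.full(dx.shape, np.inf)
    np.multiply(s, np.sign(dy), out=s, where=dx == 0)
    np.divide(dy, dx, out=s, where=dx != 0)
    s = s[s != -1.0]
    if len(s) == 0:
        raise DomainError("no valid pairwise slopes")
    s = np.sort(s)
    big_n = len(s)
    k_off = int(np.sum(s < -1.0))

    def shifted_median(offset: int) -> float:
        # 1-indexed rank positions per the original procedure
        if big_n % 2 == 1:
            pos = (big_n + 1) // 2 + offset
            return float(s[np.clip(pos - 1, 0, big_n - 1)])
        p1 = big_n // 2 + offset
        p2 = big_n // 2 + 1 + offset
        v1 = s[np.clip(p1 - 1, 0, big_n - 1)]
        v2 = s[np.clip(p2 - 1, 0, big_n - 1)]
        return float(0.5 * (v1 + v2))

    slope = shifted_median(k_off)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    c_gamma = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - c_gamma) / 2.0))
    m2 = big_n - m1 + 1
    lo = float(s[np.clip(m1 + k_off - 1, 0, big_n - 1)])
    hi = float(s[np.clip(m2 + k_off - 1, 0, big_n - 1)])

    intercept = float(np.median(y - slope * x))
    # intercept bounds pair with the opposite slope bounds
    int_lo = float(np.median(y - hi * x))
    int_hi = float(np.median(y - lo * x))
    return PBRegression(
        slope=slope,
        slope_ci=(lo, hi),
        intercept=intercept,
        intercept_ci=(min(int_lo, int_hi), max(int_lo, int_hi)),
        n=n,
    )


class KendallResult(NamedTuple):
    tau: float
    p_value: float


def kendall_tau_b(x, y) -> KendallResult:
    """Tie-corrected Kendall rank correlation tau-b."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise DomainError("x and y must be equal-length 1-D vectors, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("tau-b undefined for a zero-variance vector")
    res = stats.kendalltau(x, y)
    return KendallResult(tau=float(res.statistic), p_value=float(res.pvalue))


@dataclass(frozen=True)
class AgreementTable:
    """Square contingency table of ordered categories (rows: method,
    columns: reference)."""

    counts: np.ndarray
    categories: tuple[str, ...] = AUC_CATEGORIES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise DomainError("counts must be a square matrix")
        if np.any(c < 0):
            raise DomainError("counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_labels(cls, method, reference, categories=AUC_CATEGORIES):
        k = len(categories)
        counts = np.zeros((k, k))
        for m, r in zip(method, reference, strict=True):
            counts[categories.index(m), categories.index(r)] += 1
        return cls(counts=counts, categories=tuple(categories))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]
    n: int


def weighted_kappa(table: AgreementTable | np.ndarray, conf: float = 0.95) -> KappaResult:
    """Linearly weighted Cohen's kappa with an asymptotic confidence interval.

    Agreement weights w_ij = 1 - |i - j|/(k - 1) (equivalently linear
    disagreement weights):

        kappa_w = (p_o - p_e) / (1 - p_e),
        p_o = sum w_ij p_ij,  p_e = sum w_ij p_i. p_.j

    The standard error is the large-sample formula of Fleiss, Cohen and
    Everitt (1969); the interval is kappa +/- z * SE and is reported for
    orientation only — different software computes kappa CIs differently.
    """
    if not isinstance(table, AgreementTable):
        table = AgreementTable(counts=np.asarray(table))
    n = table.n
    if n < 1:
        raise DomainError("empty agreement table")
    k = table.counts.shape[0]
    p = table.counts / n
    idx = np.arange(k)
    w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    p_o = float(np.sum(w * p))
    p_e = float(np.sum(w * np.outer(p_row, p_col)))
    if p_e >= 1.0:
        raise DomainError("degenerate marginals: chance agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)

    w_row = w @ p_col  # E_j[w_ij] over the column marginal
    w_col = p_row @ w
    term = w - np.add.outer(w_row, w_col) * (1.0 - kappa)
    var = (
        float(np.sum(p * term**2)) - (kappa - p_e * (1.0 - kappa)) ** 2
    ) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci=(float(kappa - z * se), float(kappa + z * se)),
        n=int(round(n)),
    )
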