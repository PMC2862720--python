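"""Inter-method agreement and comparison statistics.

The central question these statistics answer: do two scoring routes (a
conventional whole-section read and a microchannel-based read of the same
tissue, or repeated slides from one patient) assign the same ordinal
biomarker categories to the same cases?

* Kendall's coefficient of concordance W (tie-corrected, mid-ranks) over
  m raters x n items, with the large-sample chi-square test
  chi2 = m (n - 1) W on n - 1 degrees of freedom.
* Cohen's kappa (two raters, unweighted) and Fleiss' kappa (m raters).
* Percent concordance with an exact binomial (Clopper-Pearson) 95% CI.
* Pearson correlation, classic Levene equal-variance test (mean-centered),
  and the two-sample t test, for comparing quantitative expression levels.
* A Latin-square design of biomarker orderings for reproducibility runs,
  both the cyclic construction and the specific order-4 pairwise-swap
  square used for 4-biomarker slides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .errors import ConfigurationError, DegenerateInputError

BIOMARKERS = ("ER", "HER2", "PR", "Ki-67")


# ---------------------------------------------------------------------
# Kendall's W
# ---------------------------------------------------------------------

def kendalls_w(ratings: np.ndarray) -> float:
    """Tie-corrected Kendall's coefficient of concordance.

    ``ratings`` is m raters x n items of ordinal values. Each rater's row
    is converted to mid-ranks; with S the sum of squared deviations of
    item rank sums from their mean and T_i = sum(t^3 - t) over each
    rater's tie groups,

        W = 12 S / (m^2 (n^3 - n) - m sum_i T_i).
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ConfigurationError("ratings must be an m x n matrix with m, n >= 2")
    m, n = R.shape
    ranks = np.vstack([rankdata(row) for row in R])
    T = 0.0
    for row in R:
        _, counts = np.unique(row, return_counts=True)
        T += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        raise DegenerateInputError(
            "every rater assigned a constant rating; W is undefined"
        )
    col_sums = ranks.sum(axis=0)
    S = float(np.sum((col_sums - col_sums.mean()) ** 2))
    return 12.0 * S / denom


def kcc_chisq(W: float, m: int, n: int) -> tuple[float, int, float]:
    """Large-sample chi-square test for W: chi2 = m(n-1)W on n-1 df."""
    if not 0.0 <= W <= 1.0 + 1e-12:
        raise ConfigurationError("W must lie in [0, 1]")
    if m < 2 or n < 2:
        raise ConfigurationError("need m >= 2 raters and n >= 2 items")
    chi2 = m * (n - 1) * W
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------
# Kappa statistics
# ---------------------------------------------------------------------

def contingency_table(a, b, n_categories: int = 4) -> np.ndarray:
    """Square contingency counts for two aligned categorical vectors."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ConfigurationError("rating vectors must have equal length")
    table = np.zeros((n_categories, n_categories), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def cohens_kappa(table: np.ndarray) -> tuple[float, float]:
    """Unweighted Cohen's kappa and its two-sided large-sample p-value."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ConfigurationError("contingency table must be square")
    total = table.sum()
    if total < 1:
        raise ConfigurationError("contingency table is empty")
    p_e = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / total**2)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateInputError(
            "both raters constant in the same category; kappa undefined"
        )
    res = _sm_cohens_kappa(table)
    return float(res.kappa), float(res.pvalue_two_sided)


def fleiss_kappa(ratings: np.ndarray, n_categories: int = 4) -> float:
    """Fleiss' kappa for an n items x k raters categorical matrix."""
    R = np.asarray(ratings, dtype=int)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ConfigurationError("ratings must be n items x k (>=2) raters")
    counts, _ = aggregate_raters(R, n_cat=n_categories)
    totals = counts.sum(axis=0)
    if np.count_nonzero(totals) < 2:
        raise DegenerateInputError("all ratings in one category; kappa undefined")
    return float(_sm_fleiss_kappa(counts))


def percent_concordance_ci(
    matches: int, n: int, method: str = "clopper-pearson"
) -> tuple[float, float, float]:
    """Percent agreement with an exact binomial 95% CI, on the 0-100 scale."""
    if n < 1:
        raise ConfigurationError("need at least one case")
    if not 0 <= matches <= n:
        raise ConfigurationError("matches must lie in [0, n]")
    if method != "clopper-pearson":
        raise ConfigurationError(f"unsupported CI method {method!r}")
    ci = stats.binomtest(matches, n).proportion_ci(confidence_level=0.95, method="exact")
    return 100.0 * matches / n, 100.0 * ci.low, 100.0 * ci.high


# ---------------------------------------------------------------------
# Quantitative comparisons
# ---------------------------------------------------------------------

def pearson_correlation(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ConfigurationError("need two equal-length vectors of length >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Classic Levene W statistic (deviations from group means) and p-value."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigurationError("need >= 2 groups with >= 2 values each")
    res = stats.levene(*[np.asarray(g, dtype=float) for g in groups], center=center)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t test (pooled variance; Welch if equal_var=False)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("each sample needs length >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateInputError("zero pooled variance; t undefined")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------
# Latin-square reproducibility design
# ---------------------------------------------------------------------

# Order-4 square used for 4-biomarker slides: each subsequent slide swaps
# adjacent biomarker pairs so that every biomarker visits every channel
# position exactly once. 0=ER, 1=HER2, 2=PR, 3=Ki-67.
_SWAP4 = np.array(
    [
        [0, 1, 2, 3],
        [1, 0, 3, 2],
        [2, 3, 0, 1],
        [3, 2, 1, 0],
    ]
)


@dataclass
class LatinDesign:
    order: int
    square: np.ndarray  # rows: slides; values: biomarker indices
    labels: tuple[str, ...] | None = None

    def is_valid(self) -> bool:
        want = set(range(self.order))
        rows_ok = all(set(r) == want for r in self.square)
        cols_ok = all(set(c) == want for c in self.square.T)
        return rows_ok and cols_ok

    def row_labels(self, i: int) -> tuple[str, ...]:
        labels = self.labels or tuple(str(j) for j in range(self.order))
        return tuple(labels[j] for j in self.square[i])


def latin_design(k: int, style: str = "cyclic") -> LatinDesign:
    """Latin square of biomarker orderings over repeated slides.

    ``style="cyclic"`` gives row i = left rotation by i. ``style="swap4"``
    (k = 4 only) gives the pairwise-swap square whose slide orders are
    (ER, HER2, PR, Ki-67), (HER2, ER, Ki-67, PR), (PR, Ki-67, ER, HER2),
    (Ki-67, PR, HER2, ER).
    """
    if k < 2:
        raise ConfigurationError("Latin square order must be >= 2")
    if style == "swap4":
        if k != 4:
            raise ConfigurationError("the 4-biomarker square requires k = 4")
        return LatinDesign(order=4, square=_SWAP4.copy(), labels=BIOMARKERS)
    if style == "cyclic":
        square = np.array([[(i + j) % k for j in range(k)] for i in range(k)])
        labels = BIOMARKERS if k == 4 else None
        return LatinDesign(order=k, square=square, labels=labels)
    raise ConfigurationError(f"unknown design style {style!r}")


def reproducibility_kcc(ratings_by_biomarker: dict[str, np.ndarray]) -> dict[str, float]:
    """Kendall's W per biomarker, treating repeated slides as raters.

    Each value is a slides x cases ordinal matrix from one biomarker's
    repeated measurements.
    """
    return {name: kendalls_w(mat) for name, mat in ratings_by_biomarker.items()}


# ---------------------------------------------------------------------
# Full two-method agreement report
# ---------------------------------------------------------------------

@dataclass
class AgreementReport:
    W: float
    chi2: float
    df: int
    p_w: float
    kappa: float
    p_kappa: float
    fleiss: float
    concordance_pct: float
    ci95: tuple[float, float]
    m_raters: int
    n_cases: int


def format_p(p: float) -> str:
    """Report p to 4 decimals, values below 1e-4 as '<0.0001'."""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def agreement_report(method_a, method_b, n_categories: int = 4) -> AgreementReport:
    """All two-method agreement statistics for one biomarker.

    The two scoring methods are treated as m = 2 raters of the same n
    cases: Kendall's W on mid-ranked ordinal codes with tie correction,
    its chi-square test, unweighted Cohen's kappa, Fleiss' kappa, and
    exact-binomial percent concordance.
    """
    a = np.asarray(method_a, dtype=int)
    b = np.asarray(method_b, dtype=int)
    if a.shape != b.shape or a.size < 2:
        raise ConfigurationError("need two aligned score vectors with n >= 2")
    n = a.size
    W = kendalls_w(np.vstack([a, b]))
    chi2, df, p_w = kcc_chisq(W, 2, n)
    table = contingency_table(a, b, n_categories)
    kappa, p_kappa = cohens_kappa(table)
    fk = fleiss_kappa(np.column_stack([a, b]), n_categories)
    matches = int((a == b).sum())
    pct, lo, hi = percent_concordance_ci(matches, n)
    return AgreementReport(
        W=W, chi2=chi2, df=df, p_w=p_w,
        kappa=kappa, p_kappa=p_kappa, fleiss=fk,
        concordance_pct=pct, ci95=(lo, hi), m_raters=2, n_cases=n,
    )


def concordance_table(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-biomarker agreement table from {biomarker: df(method_a, method_b)}."""
    rows = []
    for name, df in frames.items():
        rep = agreement_report(df["method_a"], df["method_b"])
        rows.append(
            {
                "biomarker": name,
                "KCC": rep.W,
                "chi2": rep.chi2,
                "p_KCC": format_p(rep.p_w),
                "kappa": rep.kappa,
                "p_kappa": format_p(rep.p_kappa),
                "fleiss_kappa": rep.fleiss,
                "concordance_pct": rep.concordance_pct,
                "ci95_lo": rep.ci95[0],
                "ci95_hi": rep.ci95[1],
                "n": rep.n_cases,
            }
        )
    return pd.DataFrame(rows)
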