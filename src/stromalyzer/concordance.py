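"""Agreement statistics between raters and methods.

Two observers (or an observer consensus and the automated method) score the
same patients; after dichotomization into stroma-low/stroma-high their
agreement is summarised by a 2×2 cross-tabulation and unweighted Cohen's
kappa. Continuous scores are compared with the intraclass correlation
coefficient (two-way random effects; absolute-agreement single-measure by
default, so a systematic offset between observer and machine counts as
disagreement). Associations between TSR and clinicopathological variables
use rank tests (Mann–Whitney U for two groups, Kruskal–Wallis beyond).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import DegenerateICCError, DegenerateKappaError, ParameterError
from .hotspot import STROMA_HIGH, STROMA_LOW

_LABEL_ORDER = (STROMA_LOW, STROMA_HIGH)


@dataclass(frozen=True)
class CrossTab2x2:
    """2×2 agreement table; rows = rater A, columns = rater B (low, high)."""

    counts: np.ndarray
    row_labels: tuple = _LABEL_ORDER
    col_labels: tuple = _LABEL_ORDER

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or (c < 0).any():
            raise ParameterError("counts must be a non-negative 2x2 table")
        if c.sum() == 0:
            raise ParameterError("empty table")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def concordant(self) -> int:
        """Number of cases on which the two raters agree (diagonal sum)."""
        return int(np.trace(self.counts))


@dataclass(frozen=True)
class AgreementResult:
    statistic: float
    ci_low: float
    ci_high: float
    n: int
    method: str


def crosstab(labels_a, labels_b) -> CrossTab2x2:
    """Cross-tabulate two sequences of stroma-low/high labels."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ParameterError("label sequences differ in length")
    if not a:
        raise ParameterError("label sequences are empty")
    idx = {lab: i for i, lab in enumerate(_LABEL_ORDER)}
    counts = np.zeros((2, 2), np.int64)
    for x, y in zip(a, b):
        try:
            counts[idx[x], idx[y]] += 1
        except KeyError as e:
            raise ParameterError(f"unknown dichotomy label {e.args[0]!r}") from None
    return CrossTab2x2(counts=counts)


def expand_crosstab(table: CrossTab2x2):
    """Inverse of :func:`crosstab`: emit per-case label pairs."""
    a, b = [], []
    for i, ra in enumerate(_LABEL_ORDER):
        for j, rb in enumerate(_LABEL_ORDER):
            a += [ra] * int(table.counts[i, j])
            b += [rb] * int(table.counts[i, j])
    return a, b


def cohens_kappa(table: CrossTab2x2) -> AgreementResult:
    """Unweighted Cohen's kappa with its asymptotic 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o the
    diagonal fraction and chance agreement p_e the margin-product sum.
    """
    c = table.counts.astype(float)
    n = c.sum()
    p_o = np.trace(c) / n
    p_e = float(table.row_margins @ table.col_margins) / n ** 2
    if math.isclose(p_e, 1.0):
        raise DegenerateKappaError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # large-sample standard error (simple form, adequate for reporting)
    se = math.sqrt(p_o * (1 - p_o) / n) / (1 - p_e)
    return AgreementResult(statistic=float(kappa),
                           ci_low=float(kappa - 1.96 * se),
                           ci_high=float(kappa + 1.96 * se),
                           n=int(n), method="kappa")


def icc(scores_a, scores_b, variant: str = "ICC2") -> AgreementResult:
    """Intraclass correlation between two continuous raters.

    ``variant`` is ``"ICC2"`` (two-way random effects, absolute agreement,
    single measure — the default, which penalizes systematic offsets) or
    ``"ICC3"`` (consistency).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ParameterError("need two equal-length score vectors, n >= 3")
    if variant not in ("ICC2", "ICC3"):
        raise ParameterError("variant must be 'ICC2' or 'ICC3'")
    if np.var(np.concatenate([a, b])) == 0:
        raise DegenerateICCError("zero total variance; ICC undefined")
    n = a.size
    long = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["A", "B"], n),
        "ratings": np.concatenate([a, b]),
    })
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        tab = pg.intraclass_corr(data=long, targets="targets",
                                 raters="raters", ratings="ratings")
    # pingouin labels the variants ICC2/ICC3 or ICC(A,1)/ICC(C,1) by version
    aliases = {"ICC2": ("ICC2", "ICC(A,1)"), "ICC3": ("ICC3", "ICC(C,1)")}
    row = tab[tab["Type"].isin(aliases[variant])].iloc[0]
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    lo, hi = row[ci_col]
    value = float(row["ICC"])
    if not np.isfinite(value):  # degenerate within-pair variance: exact match
        value, lo, hi = 1.0, 1.0, 1.0
    return AgreementResult(statistic=value, ci_low=float(lo),
                           ci_high=float(hi), n=int(n), method=variant)


def association_tests(cohort: pd.DataFrame, variable: str,
                      tsr_scores: str):
    """Rank test of TSR against a categorical clinicopathological variable.

    Two levels → Mann–Whitney U; more → Kruskal–Wallis. Levels with zero
    cases are dropped with a warning. Returns ``(statistic, p_value,
    test_name)``; the p-value is two-sided.
    """
    import warnings

    groups = []
    for level, sub in cohort.groupby(variable, observed=False):
        vals = sub[tsr_scores].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"level {level!r} of {variable!r} has no cases; dropped")
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ParameterError(f"{variable!r} has fewer than 2 populated levels")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue), "mann-whitney-u"
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue), "kruskal-wallis"
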