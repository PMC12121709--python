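"""Nonparametric group inference with exact small-sample behaviour.

The Wilcoxon signed-rank and Mann-Whitney U tests are implemented from
first principles: exact two-sided p-values by full enumeration in the
small-sample range (all sign patterns / all group assignments), with a
tie-corrected normal approximation beyond it.  A linear mixed-effects
contrast (participant random intercept) is provided at contract level on
top of statsmodels for the factorial accuracy comparisons.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

EXACT_WILCOXON_N = 15     # exact enumeration up to 2^15 sign patterns
EXACT_MWU_N = 12          # exact enumeration up to C(12, n) assignments


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    return spstats.rankdata(values, method="average")


def _two_sided_from_distribution(observed: float, dist: np.ndarray) -> float:
    """Exact two-sided p: doubled smaller tail of a discrete distribution, capped at 1."""
    eps = 1e-12
    lo = np.mean(dist <= observed + eps)
    hi = np.mean(dist >= observed - eps)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(a, b=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    W is the sum of ranks of positive differences (zeros dropped, ties
    average-ranked).  For n <= 15 the p-value is exact, enumerating all
    2^n sign patterns; above that a tie-corrected normal approximation
    with continuity correction is used.
    """
    a = np.asarray(a, float)
    d = a - np.asarray(b, float) if b is not None else a
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    ranks = _rank_with_ties(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_N:
        # distribution of W over all sign assignments of the observed ranks
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        dist = signs @ ranks
        p = _two_sided_from_distribution(w, dist)
        return TestResult(w, p, "exact", n)
    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    p = float(2 * spstats.norm.sf(abs(z)))
    return TestResult(w, min(1.0, p), "normal", n)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U (rank-sum) test for two independent samples.

    U counts pairs with a_i > b_j, plus half-ties.  For combined n <= 12
    the p-value is exact by enumerating every assignment of the pooled
    values to the two groups; otherwise a tie-corrected normal
    approximation with continuity correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    u = float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())
    pooled = np.concatenate([a, b])
    if n + m <= EXACT_MWU_N:
        dist = []
        idx = np.arange(n + m)
        for comb in itertools.combinations(idx, n):
            mask = np.zeros(n + m, bool)
            mask[list(comb)] = True
            aa, bb = pooled[mask], pooled[~mask]
            dist.append((aa[:, None] > bb[None, :]).sum()
                        + 0.5 * (aa[:, None] == bb[None, :]).sum())
        p = _two_sided_from_distribution(u, np.array(dist, float))
        return TestResult(u, p, "exact", n + m)
    mean = n * m / 2.0
    nm = n + m
    tie_counts = np.unique(pooled, return_counts=True)[1]
    tie_term = (tie_counts**3 - tie_counts).sum() / (nm * (nm - 1))
    var = n * m / 12.0 * (nm + 1 - tie_term)
    z = (u - mean - 0.5 * np.sign(u - mean)) / math.sqrt(var)
    p = float(2 * spstats.norm.sf(abs(z)))
    return TestResult(u, min(1.0, p), "normal", nm)


def mixed_model_contrast(
    data: pd.DataFrame,
    value: str = "accuracy",
    cue: str = "cue",
    roi: str = "roi",
    participant: str = "participant",
    term: str = "interaction",
) -> TestResult:
    """Mixed-effects test of ``value ~ cue * roi`` with participant random intercept.

    ``term`` selects the reported fixed effect: ``"interaction"``,
    ``"cue"`` or ``"roi"``.  Requires >= 2 participants and a balanced
    (complete) cue x roi design; missing cells raise with the offending
    combinations listed.
    """
    from statsmodels.formula.api import mixedlm

    for col in (value, cue, roi, participant):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if data[participant].nunique() < 2:
        raise ValueError("mixed model requires at least 2 participants")
    cells = data.groupby([cue, roi], observed=True).size()
    expected = [(c, r) for c in data[cue].unique() for r in data[roi].unique()]
    missing = [cr for cr in expected if cr not in cells.index]
    if missing:
        raise ValueError(f"missing cue x roi cells: {missing}")
    model = mixedlm(f"{value} ~ C({cue}) * C({roi})", data, groups=data[participant])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    names = list(fit.fe_params.index)
    if term == "interaction":
        keys = [nm for nm in names if ":" in nm]
    else:
        col = cue if term == "cue" else roi
        keys = [nm for nm in names if nm.startswith(f"C({col})") and ":" not in nm]
    if not keys:
        raise ValueError(f"no fixed-effect term found for {term!r}")
    key = keys[0]
    t = float(fit.tvalues[key])
    p = float(fit.pvalues[key])
    return TestResult(t, p, "mixedlm", int(data[participant].nunique()))


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f^2 for a nested-model comparison of variance explained."""
    if not 0 <= r2_reduced <= r2_full <= 1:
        raise ValueError("require 0 <= r2_reduced <= r2_full <= 1")
    if r2_full >= 1.0:
        return math.inf
    return (r2_full - r2_reduced) / (1.0 - r2_full)
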