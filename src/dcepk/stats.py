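"""Treatment-outcome statistics: logistic regression, ROC, diagnostic tables.

Covers the statistical layer of a per-site treatment-response analysis:
univariate logistic regression with Wald odds-ratio CIs, forward-stepwise
multivariate selection with likelihood-ratio tests, paired t-tests, empirical
ROC analysis with Youden-index threshold selection and a DeLong AUC
confidence interval, diagnostic-performance tables and Fisher's exact test.

Sites are treated as independent observations (no within-patient clustering
correction), and no multiple-testing correction is applied across
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LogisticResult",
    "StepwiseResult",
    "PairedTResult",
    "ROCResult",
    "DiagnosticTable",
    "univariate_logistic",
    "stepwise_multivariate",
    "paired_t_test",
    "roc_analysis",
    "diagnostic_performance",
    "confusion_counts",
    "fisher_exact_2x2",
]


@dataclass
class LogisticResult:
    """One predictor's logistic-regression summary (Wald inference)."""

    term: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    separated: bool = False


@dataclass
class StepwiseResult:
    """Outcome of forward-stepwise selection plus a confounder-adjusted refit."""

    selected: list
    results: dict               # term -> LogisticResult from the selected model
    adjusted: dict              # term -> LogisticResult with confounders included


@dataclass
class PairedTResult:
    t: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    optimal_threshold: float
    positive_direction: str     # "higher" | "lower"
    thresholds: np.ndarray = field(repr=False, default=None)
    sensitivities: np.ndarray = field(repr=False, default=None)
    specificities: np.ndarray = field(repr=False, default=None)


@dataclass
class DiagnosticTable:
    """Confusion counts and the five diagnostic metrics (percent).

    Undefined ratios (zero denominator) are reported as NaN, never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: Optional[float] = None
    direction: str = ">"

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return self._pct(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def ppv(self) -> float:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._pct(self.tn, self.tn + self.fn)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        raise ValueError("labels must be numeric 0/1; encode outcome first")
    y = y.astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    return y


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Logit MLE; returns (result, separated flag)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return None, True
    separated = (
        not np.all(np.isfinite(res.bse))
        or np.any(np.abs(res.params) > 15)
        or not res.mle_retvals.get("converged", True)
    )
    return res, separated


def univariate_logistic(x, y, term: str = "x") -> LogisticResult:
    """Univariate logistic regression logit P(y=1) = β0 + β1·x.

    Returns the slope's coefficient, odds ratio per unit of x with a Wald
    95% CI, and Wald p-value. A constant predictor gives OR = 1 with an
    unbounded CI; complete separation is flagged with an unbounded CI
    rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = _as_binary(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")

    if np.ptp(x) == 0:
        return LogisticResult(term, 0.0, 1.0, 0.0, np.inf, 1.0, n)

    X = sm.add_constant(x)
    res, separated = _fit_logit(X, y)
    if res is None or separated:
        beta = np.nan if res is None else float(res.params[1])
        return LogisticResult(
            term, beta, np.exp(beta) if np.isfinite(beta) else np.nan,
            0.0, np.inf, np.nan, n, separated=True,
        )
    beta = float(res.params[1])
    lo, hi = res.conf_int()[1]
    return LogisticResult(
        term, beta, float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)),
        float(res.pvalues[1]), n,
    )


def _lr_pvalue(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    stat = max(2.0 * (llf_full - llf_reduced), 0.0)
    return float(sps.chi2.sf(stat, df))


def stepwise_multivariate(
    data: pd.DataFrame,
    candidates: Sequence[str],
    y_col: str,
    confounders: Sequence[str] = (),
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseResult:
    """Forward-stepwise logistic selection with likelihood-ratio tests.

    Candidates enter one at a time when their LR-test p-value against the
    current model is below ``entry_p``; after each entry, included terms
    whose removal LR p-value is at or above ``removal_p`` are dropped.
    Selected terms are then refit with the confounders added to give
    adjusted odds ratios. An empty selection is a valid result.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate predictor is required")
    y = _as_binary(data[y_col].to_numpy())

    def fit_terms(terms):
        X = sm.add_constant(data[list(terms)].to_numpy(dtype=float)) \
            if terms else np.ones((len(y), 1))
        return _fit_logit(X, y)[0]

    selected: list[str] = []
    current = fit_terms(selected)
    while True:
        # entry step
        best, best_p = None, entry_p
        for cand in candidates:
            if cand in selected:
                continue
            trial = fit_terms(selected + [cand])
            if trial is None:
                continue
            p = _lr_pvalue(trial.llf, current.llf)
            if p < best_p:
                best, best_p = cand, p
        if best is None:
            break
        selected.append(best)
        current = fit_terms(selected)
        # removal step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            for term in list(selected):
                reduced = fit_terms([s for s in selected if s != term])
                if _lr_pvalue(current.llf, reduced.llf) >= removal_p:
                    selected.remove(term)
                    current = fit_terms(selected)
                    removed = True
                    break

    def summarize(terms, focus):
        if not terms:
            return {}
        X = sm.add_constant(data[list(terms)].to_numpy(dtype=float))
        res, separated = _fit_logit(X, y)
        out = {}
        if res is None:
            return {
                t: LogisticResult(t, np.nan, np.nan, 0.0, np.inf, np.nan,
                                  len(y), separated=True)
                for t in focus
            }
        ci = res.conf_int()
        for j, t in enumerate(terms, start=1):
            if t not in focus:
                continue
            out[t] = LogisticResult(
                t, float(res.params[j]), float(np.exp(res.params[j])),
                float(np.exp(ci[j][0])), float(np.exp(ci[j][1])),
                float(res.pvalues[j]), len(y), separated=separated,
            )
        return out

    results = summarize(selected, set(selected))
    adjusted = summarize(selected + [c for c in confounders if c not in selected],
                         set(selected))
    return StepwiseResult(selected=selected, results=results, adjusted=adjusted)


def paired_t_test(pre, post) -> PairedTResult:
    """Two-sided paired t-test on post − pre differences."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    if np.ptp(d) == 0:
        # zero variance of differences: t is 0 (no shift) or unbounded
        if d[0] == 0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, degenerate=True)
        return PairedTResult(float(np.sign(d[0]) * np.inf), n - 1, 0.0,
                             float(d[0]), degenerate=True)
    t, p = sps.ttest_rel(post, pre)
    return PairedTResult(float(t), n - 1, float(p), float(d.mean()))


def _oriented(scores, positive_direction):
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    s = np.asarray(scores, dtype=float)
    return s if positive_direction == "higher" else -s


def _auc_rank(s: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann–Whitney probability via midranks (tie-aware)."""
    n1 = int(y.sum())
    n0 = y.size - n1
    r = sps.rankdata(s)
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _delong_variance(s: np.ndarray, y: np.ndarray, auc: float) -> float:
    pos = s[y == 1]
    neg = s[y == 0]
    # placement values: per-positive fraction of negatives below (ties half)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size
                    for q in neg])
    return float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)


def roc_analysis(scores, labels, positive_direction: str = "higher") -> ROCResult:
    """Empirical ROC analysis with Youden-index threshold selection.

    The AUC is the Mann–Whitney probability computed from midranks; the 95%
    CI uses the DeLong variance estimator. Candidate thresholds are the
    midpoints between adjacent distinct score values (plus open ends); a
    site is called positive when its score exceeds the threshold (or falls
    below it for ``positive_direction="lower"``). The optimal threshold
    maximises Youden's J = sensitivity + specificity − 1, i.e. equal
    weighting of sensitivity and specificity; J ties resolve to the lowest
    candidate threshold.
    """
    y = _as_binary(labels)
    s_raw = np.asarray(scores, dtype=float)
    if s_raw.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    s = _oriented(s_raw, positive_direction)
    auc = _auc_rank(s, y)
    var = _delong_variance(s, y, auc)
    z = sps.norm.ppf(0.975)
    half = z * np.sqrt(var)
    ci_low, ci_high = max(auc - half, 0.0), min(auc + half, 1.0)

    uniq = np.unique(s)
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    sens = np.array([(s[y == 1] > c).mean() for c in cuts])
    spec = np.array([(s[y == 0] <= c).mean() for c in cuts])
    j = sens + spec - 1.0
    best = int(np.argmax(j))          # argmax takes the first (lowest cut) tie
    thr = cuts[best]
    if positive_direction == "lower":
        thr, cuts = -thr, -cuts
    return ROCResult(
        auc=float(auc), ci_low=float(ci_low), ci_high=float(ci_high),
        optimal_threshold=float(thr), positive_direction=positive_direction,
        thresholds=cuts, sensitivities=sens, specificities=spec,
    )


def confusion_counts(scores, labels, threshold: float,
                     positive_direction: str = "higher") -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) calling scores strictly beyond the threshold positive."""
    y = _as_binary(labels)
    s = _oriented(scores, positive_direction)
    thr = threshold if positive_direction == "higher" else -threshold
    pred = s > thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def diagnostic_performance(tp: int, fp: int, tn: int, fn: int,
                           threshold: Optional[float] = None,
                           direction: str = ">") -> DiagnosticTable:
    """Diagnostic-performance table from confusion counts."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    if sum(counts) == 0:
        raise ValueError("at least one observation is required")
    return DiagnosticTable(tp=tp, fp=fp, tn=tn, fn=fn,
                           threshold=threshold, direction=direction)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table.

    Minimum-likelihood convention: the sum of hypergeometric probabilities
    of all tables (with the observed margins) no more probable than the
    observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])
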