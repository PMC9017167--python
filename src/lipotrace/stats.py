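"""Cohort statistics: hybrid risk scores and the tests behind them.

Implements the cohort-level analysis conventions of the assay: min-max
0-1 normalization of scores, hybrid scores averaging the polygenic risk
score with inverted functional scores (low uptake/mobilization = high
risk, so a higher hybrid means higher odds of elevated LDL-c), top-q
stratification with Fisher-exact odds ratios, Levene-gated Student/Welch
group comparisons, linear-regression correlations with Wald-t p-values,
and leave-out sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One statistical comparison.

    ``estimate`` is the headline quantity (mean difference, odds ratio, or
    Pearson R), ``statistic`` the test statistic it was assessed with, and
    ``flags`` auxiliary values (Levene p, slope, Haldane correction, ...).
    """

    method: str  # student | welch | levene | fisher | wald_regression
    estimate: float
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    flags: dict = dc_field(default_factory=dict)


def minmax01(values) -> np.ndarray:
    """Scale to [0, 1] by (x - min)/(max - min); NaN propagates.

    Requires at least two distinct finite values (a constant vector has no
    defined scaling).  Invariant under any increasing affine transform of
    the input.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise ValueError("minmax01 requires >= 2 distinct finite values")
    return (arr - finite.min()) / np.ptp(finite)


def invert01(values) -> np.ndarray:
    """Orientation flip on the unit interval: x -> 1 - x."""
    return 1.0 - np.asarray(values, dtype=float)


def hybrid_score(components: Sequence) -> np.ndarray:
    """Elementwise mean of 2-3 score vectors already scaled to [0, 1].

    Functional components should be inverted (``invert01``) before calling
    so that a high hybrid score means high hypercholesterolemia risk.
    NaN in any component propagates to that subject's hybrid.
    """
    if not 2 <= len(components) <= 3:
        raise ValueError("hybrid_score expects 2 or 3 components")
    mats = [np.asarray(c, dtype=float) for c in components]
    n = {m.shape for m in mats}
    if len(n) > 1:
        raise ValueError("components must have equal length")
    for m in mats:
        finite = m[np.isfinite(m)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("components must be scaled to [0, 1]")
    return np.mean(mats, axis=0)


def stratify_top_fraction(scores, q: float) -> np.ndarray:
    """Label the ceil(q*n) highest-scoring subjects as exposed.

    Ties are broken by stable input order (earlier rows first); a tie
    spanning the cut boundary emits a warning.  NaN scores are never
    exposed.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty scores")
    k = math.ceil(q * arr.size)
    keys = np.where(np.isnan(arr), -np.inf, arr)
    order = np.argsort(-keys, kind="stable")
    exposed = np.zeros(arr.size, dtype=bool)
    exposed[order[:k]] = True
    if k < arr.size and keys[order[k - 1]] == keys[order[k]]:
        warnings.warn(
            "tie at the stratification boundary; broken by input order",
            stacklevel=2,
        )
    return exposed


def fisher_exact_or(table, p_mode: str = "prob-mass") -> StatResult:
    """Fisher's exact test and sample odds ratio for a 2x2 table.

    The odds ratio is ad/bc; when any cell is zero the Haldane-Anscombe
    correction (+0.5 on all cells) is applied to the estimate and flagged
    (the p-value always uses the uncorrected table).  ``p_mode``:
    ``prob-mass`` (default) sums hypergeometric probabilities of tables no
    more probable than the observed one; ``double-one-sided`` doubles the
    smaller tail, capped at 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])

    haldane = min(a, b, c, d) == 0
    if haldane:
        est = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        est = a * d / (b * c)

    if p_mode == "prob-mass":
        _, p = sps.fisher_exact(t, alternative="two-sided")
    elif p_mode == "double-one-sided":
        p_less = sps.fisher_exact(t, alternative="less")[1]
        p_greater = sps.fisher_exact(t, alternative="greater")[1]
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError("p_mode must be 'prob-mass' or 'double-one-sided'")
    return StatResult(
        method="fisher",
        estimate=float(est),
        statistic=float(est),
        pvalue=float(p),
        n=(a + b, c + d),
        flags={"haldane": haldane},
    )


def compare_groups(a, b, alpha: float = 0.05) -> StatResult:
    """Two-group comparison with a Levene gate on the test choice.

    Levene's test (mean-centered) assesses equality of variances at level
    ``alpha``; with equal group sizes and no evidence of unequal variance
    a two-tailed Student's t-test is used, otherwise Welch's t-test.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")

    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        levene_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            levene_p = float(sps.levene(x, y, center="mean").pvalue)
        if not np.isfinite(levene_p):
            levene_p = 1.0

    student = (x.size == y.size) and (levene_p >= alpha)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        # degenerate: both groups constant
        tstat = 0.0 if x.mean() == y.mean() else math.inf
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        res = sps.ttest_ind(x, y, equal_var=student)
        tstat, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        method="student" if student else "welch",
        estimate=float(x.mean() - y.mean()),
        statistic=tstat,
        pvalue=p,
        n=(x.size, y.size),
        flags={"levene_p": levene_p, "alpha": alpha},
    )


def correlate(x, y) -> StatResult:
    """Least-squares linear association with a Wald-t p-value.

    Fits y ~ x by ordinary least squares, reports the Pearson R as the
    estimate and the two-sided p-value for the null hypothesis of zero
    slope (t = slope/SE with n-2 degrees of freedom).  Missing pairs are
    dropped pairwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.ptp(xa) == 0:
        raise ValueError("x has zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = sps.linregress(xa, ya)
    if fit.stderr > 0:
        tstat = fit.slope / fit.stderr
    else:
        tstat = math.copysign(math.inf, fit.slope) if fit.slope else 0.0
    return StatResult(
        method="wald_regression",
        estimate=float(fit.rvalue),
        statistic=float(tstat),
        pvalue=float(fit.pvalue),
        n=(xa.size,),
        flags={
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "stderr": float(fit.stderr),
        },
    )


@dataclass
class SensitivityResult:
    full: StatResult
    reduced: StatResult
    n_removed: int


def sensitivity_drop(
    table: pd.DataFrame,
    rule,
    analysis: Callable[[pd.DataFrame], StatResult],
    group_col: str | None = "group",
) -> SensitivityResult:
    """Re-run an analysis with and without the subjects a rule selects.

    ``rule`` is either a boolean-mask callable on the table or a pandas
    query string (e.g. ``"ldl_c_mmol_l > 10"``).  Removing every member of
    a group (when ``group_col`` is present) is an error, since the paired
    comparison would be meaningless.
    """
    if callable(rule):
        mask = np.asarray(rule(table), dtype=bool)
    else:
        mask = table.eval(rule).to_numpy(dtype=bool)
    reduced = table.loc[~mask]
    if group_col and group_col in table.columns:
        lost = set(table[group_col].unique()) - set(reduced[group_col].unique())
        if lost:
            raise ValueError(f"rule removes entire group(s): {sorted(lost)}")
    return SensitivityResult(
        full=analysis(table),
        reduced=analysis(reduced),
        n_removed=int(mask.sum()),
    )


def hybrid_or_analysis(
    cohort: pd.DataFrame,
    components: Sequence[str],
    invert: Sequence[bool] | None = None,
    q: float = 0.30,
    case_col: str = "group",
    case_label: str = "hLDL-c",
    p_mode: str = "prob-mass",
) -> StatResult:
    """Odds ratio of elevated LDL-c for the top-q fraction of a hybrid score.

    Each named component is min-max scaled to [0, 1]; components marked in
    ``invert`` (default: every component except ``ldl_prs``) are flipped so
    that low function counts as high risk.  The hybrid is the mean of the
    scaled components; subjects in its top-q fraction are the exposed arm
    of a Fisher-exact 2x2 against case status.
    """
    if invert is None:
        invert = [c != "ldl_prs" for c in components]
    scaled = []
    for comp, inv in zip(components, invert):
        s = minmax01(cohort[comp].to_numpy(float))
        scaled.append(invert01(s) if inv else s)
    score = scaled[0] if len(scaled) == 1 else hybrid_score(scaled)
    keep = np.isfinite(score)
    score = score[keep]
    cases = (cohort.loc[keep, case_col] == case_label).to_numpy()
    exposed = stratify_top_fraction(score, q)
    tbl = np.array(
        [
            [int(np.sum(exposed & cases)), int(np.sum(exposed & ~cases))],
            [int(np.sum(~exposed & cases)), int(np.sum(~exposed & ~cases))],
        ]
    )
    return fisher_exact_or(tbl, p_mode=p_mode)
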