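"""Inferential layer: response transforms, GLM designs with group-specific
slopes, two-sample tests with Bonferroni correction, and channel-wise
permutation tests on scalp topographies.

Three responses link ASSR features to cognition and executive function:

* ``IQ``      — z-scored midlife IQ score, identity link.
* ``SOCmove`` — mean moves on 4-move planning problems, modeled through the
  reciprocal ``y = 1 / SOCmove`` (larger y = better performance).
* ``SOCprob`` — problems solved in minimum moves (max 12), modeled through
  the reflected log ``y = log(max - SOCprob)`` (larger y = worse).

The design follows a Wilkinson-style expansion: an intercept, shared slope
(``sigma``) and decay (``alpha``) main effects, a group indicator for the
stable group (the declining group is absorbed into the intercept), and
group-specific magnitude (A), latency (mu), their interaction A*mu — for the
AM and ITPC profiles — plus group-specific average band power P.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "FEATURE_COLUMNS",
    "GlmFit",
    "transform_response",
    "back_transform",
    "build_design",
    "fit_glm",
    "two_sample_tests",
    "bonferroni",
    "permutation_topography",
]

FEATURE_COLUMNS = ("A_am", "mu_am", "sigma_am", "alpha_am",
                   "A_itpc", "mu_itpc", "sigma_itpc", "alpha_itpc", "power")

RESPONSES = ("IQ", "SOCmove", "SOCprob")

SOC_PROB_MAX = 12


def transform_response(table: pd.DataFrame, response_id: str,
                       soc_prob_max: float | None = None,
                       degenerate_offset: float = 0.5) -> np.ndarray:
    """Map a raw cognition column to its transformed GLM response scale.

    ``IQ``: z-score of the midlife IQ column (IST60), sample SD with n-1.
    ``SOCmove``: 1 / SOC_moves_4.
    ``SOCprob``: log(max - SOC_prob_min), with max taken over the sample
    unless given.  A subject at the maximum would hit log(0); the
    ``degenerate_offset`` half-count is used for those subjects only,
    i.e. ``log(offset)``.
    """
    if response_id == "IQ":
        x = np.asarray(table["IST60"], dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("IQ column has zero variance; z-transform undefined")
        return (x - x.mean()) / sd
    if response_id == "SOCmove":
        x = np.asarray(table["SOC_moves_4"], dtype=float)
        if np.any(x <= 0):
            raise ValueError("SOC_moves_4 must be positive")
        return 1.0 / x
    if response_id == "SOCprob":
        x = np.asarray(table["SOC_prob_min"], dtype=float)
        mx = float(np.max(x)) if soc_prob_max is None else float(soc_prob_max)
        diff = mx - x
        if np.any(diff < 0):
            raise ValueError("SOC_prob_min exceeds its stated maximum")
        return np.log(np.where(diff == 0, degenerate_offset, diff))
    raise ValueError(f"unknown response {response_id!r}; choose from {RESPONSES}")


def back_transform(y: np.ndarray, response_id: str,
                   soc_prob_max: float = SOC_PROB_MAX) -> np.ndarray:
    """Invert the response transform for interpretation on the native scale.

    E[z(IQ)] = X beta; E[SOCmove] = 1 / (X beta);
    E[SOCprob] = max - exp(X beta).
    """
    y = np.asarray(y, dtype=float)
    if response_id == "IQ":
        return y
    if response_id == "SOCmove":
        return 1.0 / y
    if response_id == "SOCprob":
        return soc_prob_max - np.exp(y)
    raise ValueError(f"unknown response {response_id!r}")


def build_design(features: pd.DataFrame, formula_id: str = "IQ"):
    """Design matrix for the ASSR-cognition GLMs.

    Returns ``(X, term_names)``.  Columns: intercept; shared decays
    (alpha_AM, alpha_ITPC) and slopes (sigma_AM, sigma_ITPC); an indicator
    for the stable (highCog) group; and per group level the magnitude,
    latency and magnitude-by-latency interaction for AM and ITPC plus the
    band power P.  The same design serves all three responses
    (``formula_id`` is kept for interface symmetry).
    """
    if formula_id not in RESPONSES:
        raise ValueError(f"unknown formula {formula_id!r}")
    missing = [c for c in FEATURE_COLUMNS + ("group",) if c not in features.columns]
    if missing:
        raise KeyError(f"feature table is missing columns: {missing}")
    groups = features["group"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly two levels, found {levels}")
    # Stable group carries the indicator; declining group is the reference.
    if "highCog" in levels:
        indicator_level = "highCog"
    else:
        indicator_level = levels[0]
    ordered = [indicator_level] + [g for g in levels if g != indicator_level]

    n = len(features)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for name, col in (("alpha_AM", "alpha_am"), ("alpha_ITPC", "alpha_itpc"),
                      ("sigma_AM", "sigma_am"), ("sigma_ITPC", "sigma_itpc")):
        cols.append(np.asarray(features[col], dtype=float))
        names.append(name)
    ind = (groups == indicator_level).to_numpy(dtype=float)
    cols.append(ind)
    names.append(f"Intercept:{indicator_level}")
    for g in ordered:
        gi = (groups == g).to_numpy(dtype=float)
        a_am = np.asarray(features["A_am"], dtype=float)
        mu_am = np.asarray(features["mu_am"], dtype=float)
        a_it = np.asarray(features["A_itpc"], dtype=float)
        mu_it = np.asarray(features["mu_itpc"], dtype=float)
        p = np.asarray(features["power"], dtype=float)
        for nm, col in ((f"A_AM:{g}", a_am), (f"mu_AM:{g}", mu_am),
                        (f"A_AM*mu_AM:{g}", a_am * mu_am),
                        (f"A_ITPC:{g}", a_it), (f"mu_ITPC:{g}", mu_it),
                        (f"A_ITPC*mu_ITPC:{g}", a_it * mu_it),
                        (f"P:{g}", p)):
            cols.append(gi * col)
            names.append(nm)
    return np.column_stack(cols), names


@dataclass
class GlmFit:
    """Coefficient table and goodness-of-fit summary for one response model."""

    response_id: str
    terms: pd.DataFrame       # term, estimate, se, t, p
    r2: float
    loglik: float
    fstat: float
    f_pvalue: float
    chi2: float
    chi2_pvalue: float
    n: int
    condition_number: float
    dropped_terms: tuple[str, ...] = ()


def fit_glm(X: np.ndarray, y: np.ndarray, term_names=None,
            response_id: str = "IQ", family: str = "gaussian-identity") -> GlmFit:
    """Fit a Gaussian identity-link GLM (ordinary least squares).

    Reports per-term estimate, SE, t and two-sided p; R^2; log-likelihood;
    the overall F test against the intercept-only model; and the
    likelihood-ratio chi-square of the same comparison.  Collinear columns
    are dropped with a warning (the dropped terms are named in the result).
    """
    if family != "gaussian-identity":
        raise ValueError("only the gaussian-identity family is implemented")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(k)]
    term_names = list(term_names)

    # Rank-revealing QR: drop columns that add nothing to the column space.
    rank = np.linalg.matrix_rank(X)
    dropped: list[str] = []
    if rank < k:
        import scipy.linalg as sla
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        keep = sorted(piv[:rank])
        dropped = [term_names[i] for i in range(k) if i not in keep]
        warnings.warn(f"design is rank deficient; dropping terms {dropped}",
                      UserWarning, stacklevel=2)
        X = X[:, keep]
        term_names = [term_names[i] for i in keep]
    if n <= X.shape[1]:
        raise ValueError(f"need n > number of columns ({n} <= {X.shape[1]})")

    res = sm.OLS(y, X).fit()
    null = sm.OLS(y, np.ones((n, 1))).fit()
    df_model = X.shape[1] - 1
    if df_model > 0:
        rss, rss0 = res.ssr, null.ssr
        fstat = ((rss0 - rss) / df_model) / (rss / (n - X.shape[1]))
        f_p = float(sps.f.sf(fstat, df_model, n - X.shape[1]))
        chi2 = 2.0 * (res.llf - null.llf)
        chi2_p = float(sps.chi2.sf(chi2, df_model))
    else:
        fstat, f_p, chi2, chi2_p = np.nan, np.nan, 0.0, 1.0

    terms = pd.DataFrame({
        "term": term_names,
        "estimate": res.params,
        "se": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    })
    return GlmFit(
        response_id=response_id, terms=terms,
        r2=float(res.rsquared), loglik=float(res.llf),
        fstat=float(fstat), f_pvalue=f_p, chi2=float(chi2), chi2_pvalue=chi2_p,
        n=n, condition_number=float(np.linalg.cond(X)),
        dropped_terms=tuple(dropped),
    )


TestResult = namedtuple("TestResult", ["statistic", "pvalue", "note"])


def two_sample_tests(x, y, kind: str = "t") -> TestResult:
    """Classical two-sided two-sample tests.

    ``t``: Student two-sample t-test (equal variances); if both samples are
    constant and equal the statistic is 0 with p = 1 (flagged).
    ``ranksum``: Wilcoxon rank-sum / Mann-Whitney U, exact enumeration when
    min(n) <= 8 and there are no ties, normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "t":
        if x.size < 2 or y.size < 2:
            raise ValueError("t-test needs n >= 2 per sample")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if x.mean() == y.mean():
                return TestResult(0.0, 1.0, "zero variance in both samples")
            return TestResult(np.inf * np.sign(x.mean() - y.mean()), 0.0,
                              "zero variance, unequal means")
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(float(stat), float(p), "")
    if kind == "ranksum":
        if x.size < 1 or y.size < 1:
            raise ValueError("rank-sum test needs n >= 1 per sample")
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return TestResult(float(res.statistic), float(res.pvalue), method)
    raise ValueError(f"unknown test kind {kind!r}")


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def permutation_topography(group_a: np.ndarray, group_b: np.ndarray,
                           n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Channel-wise permutation test of group topography differences.

    The statistic is the difference of group means per channel; group labels
    are shuffled ``n_perm`` times and the two-sided p-value uses the add-one
    estimator ``(1 + #{|perm| >= |obs|}) / (1 + n_perm)``, so p is always in
    (0, 1].  No multiplicity correction (exploratory maps).
    """
    group_a = np.atleast_2d(np.asarray(group_a, dtype=float))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups must share the channel set")
    na, nb = group_a.shape[0], group_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = group_a.mean(axis=0) - group_b.mean(axis=0)
    pooled = np.concatenate([group_a, group_b], axis=0)
    rng = np.random.default_rng(seed)
    count = np.zeros(pooled.shape[1], dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(na + nb)
        diff = pooled[idx[:na]].mean(axis=0) - pooled[idx[na:]].mean(axis=0)
        count += np.abs(diff) >= np.abs(obs)
    return (1 + count) / (1 + n_perm)
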