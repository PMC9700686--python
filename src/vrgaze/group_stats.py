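"""Group-difference statistics.

Rank-based tests (Mann-Whitney with normal approximation, optional
exact permutation) for the task-performance measures, likelihood-ratio
contrasts from linear mixed models for the per-scenario eye-movement
features, the phi effect size accompanying a chi-square statistic, and
Benjamini-Hochberg false-discovery-rate adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ModelSpec",
    "ranksum_z",
    "lmm_group_contrast",
    "effect_phi",
    "bh_fdr",
]


@dataclass
class TestResult:
    __test__ = False  # not a pytest collectible despite the name

    statistic: float
    statistic_name: str  # Z | chi2 | t
    p_raw: float
    df: int | None = None
    p_fdr: float | None = None
    effect_phi: float | None = None
    warning: str | None = None


def ranksum_z(a, b, exact: bool = False) -> TestResult:
    """Two-sided rank-sum group comparison reported as |Z|.

    Uses the tie-corrected normal approximation of the Mann-Whitney U
    statistic (no continuity correction). With ``exact=True`` the
    p-value comes from the full permutation distribution of U instead
    (feasible for small groups).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations tied
        return TestResult(0.0, "Z", 1.0)
    z = abs(u1 - mu) / math.sqrt(var)
    if exact:
        p = _permutation_p(pooled, n1, abs(u1 - mu))
    else:
        p = 2.0 * stats.norm.sf(z)
    return TestResult(float(z), "Z", float(min(p, 1.0)))


def _permutation_p(pooled: np.ndarray, n1: int, observed_dev: float) -> float:
    """Exact two-sided p over all group assignments of the pooled data."""
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        r1 = ranks[list(combo)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        if abs(u1 - mu) >= observed_dev - 1e-9:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class ModelSpec:
    """Mixed-model layout for one eye-movement feature.

    ``fixed`` are fixed-effect terms (patsy-style, e.g. ``"group"``,
    ``"C(scenario)"``, ``"group:C(scenario)"``); ``random_intercepts``
    are grouping columns each contributing a random intercept. The
    first random factor is used as the primary grouping; additional
    factors enter as variance components (crossed random intercepts).
    """

    response: str
    fixed: list = field(default_factory=lambda: ["group", "C(scenario)"])
    random_intercepts: list = field(default_factory=lambda: ["participant"])
    tested: str = "group"


def _fit_ml(data: pd.DataFrame, response: str, fixed_terms, random_intercepts):
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"
    if len(random_intercepts) <= 1:
        groups = data[random_intercepts[0]] if random_intercepts else np.ones(len(data))
        model = MixedLM.from_formula(formula, data=data, groups=groups)
    else:
        # crossed random intercepts via variance components on a single
        # all-encompassing group
        vc = {r: f"0 + C({r})" for r in random_intercepts}
        model = MixedLM.from_formula(
            formula, data=data, groups=np.ones(len(data)), vc_formula=vc
        )
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # boundary/singular fits are expected under null simulations;
        # they are surfaced through TestResult.warning instead
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(reml=False, method="lbfgs", maxiter=200, disp=False)
    return fit


def lmm_group_contrast(features: pd.DataFrame, spec: ModelSpec) -> TestResult:
    """Likelihood-ratio chi-square for one term of a linear mixed model.

    Fits the model with and without ``spec.tested`` by maximum
    likelihood and compares twice the log-likelihood difference to a
    chi-square with df equal to the parameter difference. phi is
    attached as sqrt(chi2 / N participants). A singular or
    non-converged fit is flagged in ``warning`` but still reported.
    """
    data = features.dropna(subset=[spec.response]).copy()
    n_participants = data["participant"].nunique() if "participant" in data else len(data)
    full_terms = list(spec.fixed)
    if spec.tested not in full_terms:
        raise ValueError(f"tested term {spec.tested!r} not among fixed effects")
    reduced_terms = [t for t in full_terms if t != spec.tested]

    warning = None
    fit_full = _fit_ml(data, spec.response, full_terms, spec.random_intercepts)
    fit_red = _fit_ml(data, spec.response, reduced_terms, spec.random_intercepts)
    if not (fit_full.converged and fit_red.converged):
        warning = "mixed-model fit did not fully converge"

    with np.errstate(invalid="ignore"):
        delta = 2.0 * (fit_full.llf - fit_red.llf)
    if not np.isfinite(delta):  # degenerate (e.g. zero-variance) response
        delta = 0.0
        warning = warning or "non-finite log-likelihood difference; chi2 set to 0"
    chi2 = max(0.0, float(delta))
    df = int(len(fit_full.fe_params) - len(fit_red.fe_params))
    if df <= 0:
        df = 1
        warning = warning or "non-positive df from parameter count; using 1"
    p = float(stats.chi2.sf(chi2, df))
    return TestResult(
        float(chi2),
        "chi2",
        p,
        df=df,
        effect_phi=effect_phi(chi2, n_participants),
        warning=warning,
    )


def effect_phi(chi2: float, n: int) -> float:
    """phi effect size accompanying a chi-square: sqrt(chi2 / N)."""
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    if n <= 0:
        raise ValueError("n must be positive")
    return math.sqrt(chi2 / n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
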