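"""Group-comparison statistics for the staged cohort.

Covers the comparisons run on the three staging groups: chi-square for
categorical covariates, ANOVA / age-adjusted ANCOVA with Tukey post hoc
tests for continuous outcomes, Mann-Whitney for the small focal group,
Jonckheere-Terpstra ordered trend tests, bootstrap comparison of lobar
involvement frequencies, and an AIC comparison of the G/F grouping against
a grouping by dcCL bands (negative / subthreshold / positive).

ANOVA, ANCOVA and AIC computations are ordinary linear-model fits delegated
to statsmodels; Mann-Whitney and chi-square to scipy. The Jonckheere-
Terpstra statistic (with tie-corrected normal approximation and an optional
permutation p), the covariate-adjusted Tukey comparison and the bootstrap
frequency test are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .regions import LOBES
from .staging import StagingResult

METHODS = ("anova", "ancova_age", "tukey_posthoc", "mann_whitney", "chi_square",
           "jonckheere")


@dataclass
class GroupComparisonResult:
    """Statistic and p-value of one group comparison.

    ``pairwise`` maps ``(group_a, group_b)`` to ``(estimate, p)`` and is
    populated only by the Tukey post hoc method. ``extras`` carries
    method-specific diagnostics (z value, degrees of freedom, ...).
    """

    outcome: str
    method: str
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], tuple[float, float]] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.pairwise is not None and self.method != "tukey_posthoc":
            raise ValueError("pairwise results are only defined for tukey_posthoc")


def _group_arrays(cohort: pd.DataFrame, outcome: str, group_col: str) -> dict[str, np.ndarray]:
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} not in cohort table")
    if group_col not in cohort.columns:
        raise ValueError(f"group column {group_col!r} not in cohort table")
    sub = cohort[[group_col, outcome]].dropna()
    out = {str(g): grp[outcome].to_numpy() for g, grp in sub.groupby(group_col, sort=True)}
    if len(out) < 2:
        raise ValueError(f"need >= 2 groups, found {len(out)}")
    for g, vals in out.items():
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return out


def _ols_fit(cohort: pd.DataFrame, outcome: str, group_col: str,
             covariates: Sequence[str]):
    terms = [f"C(Q('{group_col}'))"] + [f"Q('{c}')" for c in covariates]
    formula = f"Q('{outcome}') ~ " + " + ".join(terms)
    cols = [outcome, group_col, *covariates]
    data = cohort[cols].dropna()
    return smf.ols(formula, data=data).fit(), data


def _anova_f(cohort: pd.DataFrame, outcome: str, group_col: str,
             covariates: Sequence[str]) -> GroupComparisonResult:
    groups = _group_arrays(cohort, outcome, group_col)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    fit, _ = _ols_fit(cohort, outcome, group_col, covariates)
    table = anova_lm(fit, typ=2)
    row = table.loc[f"C(Q('{group_col}'))"]
    method = "ancova_age" if covariates else "anova"
    return GroupComparisonResult(
        outcome=outcome,
        method=method,
        statistic=float(row["F"]),
        p_value=float(row["PR(>F)"]),
        extras={"df_group": float(row["df"]),
                "df_resid": float(fit.df_resid),
                "covariates": list(covariates)},
    )


def _tukey_posthoc(cohort: pd.DataFrame, outcome: str, group_col: str,
                   covariates: Sequence[str]) -> GroupComparisonResult:
    """All pairwise comparisons with studentized-range p-values.

    Without covariates this is the Tukey-Kramer procedure on group means;
    with covariates the comparison is between covariate-adjusted means
    (evaluated at the covariate means), with the variance of each
    difference taken from the fitted model's coefficient covariance.
    """
    groups = _group_arrays(cohort, outcome, group_col)
    fit, data = _ols_fit(cohort, outcome, group_col, covariates)
    labels = sorted(groups)
    k, df_resid = len(labels), fit.df_resid

    # Design row for each group's adjusted mean at the covariate means.
    cov_means = {c: float(data[c].mean()) for c in covariates}
    exog_names = fit.model.exog_names
    rows = {}
    for g in labels:
        row = np.zeros(len(exog_names))
        for i, name in enumerate(exog_names):
            if name == "Intercept":
                row[i] = 1.0
            elif name.startswith("C(Q("):  # treatment dummy for group g?
                row[i] = 1.0 if name.endswith(f"[T.{g}]") else 0.0
            else:
                cov = name[len("Q('"):-len("')")]
                row[i] = cov_means[cov]
        rows[g] = row

    cov_params = fit.cov_params().to_numpy()
    params = fit.params.to_numpy()
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    max_q = 0.0
    for a, b in itertools.combinations(labels, 2):
        c = rows[b] - rows[a]
        diff = float(c @ params)
        se = math.sqrt(float(c @ cov_params @ c))
        q = abs(diff) / (se / math.sqrt(2.0))
        p = float(sps.studentized_range.sf(q, k, df_resid))
        pairwise[(a, b)] = (diff, min(max(p, 0.0), 1.0))
        max_q = max(max_q, q)
    return GroupComparisonResult(
        outcome=outcome,
        method="tukey_posthoc",
        statistic=max_q,
        p_value=float(sps.studentized_range.sf(max_q, k, df_resid)),
        pairwise=pairwise,
        extras={"df_resid": float(df_resid), "k": k, "covariates": list(covariates)},
    )


def _mann_whitney(cohort: pd.DataFrame, outcome: str, group_col: str,
                  alternative: str) -> GroupComparisonResult:
    groups = _group_arrays(cohort, outcome, group_col)
    if len(groups) != 2:
        raise ValueError(f"mann_whitney requires exactly 2 groups, found {len(groups)}")
    (ga, x), (gb, y) = sorted(groups.items())
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return GroupComparisonResult(
        outcome=outcome,
        method="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        extras={"groups": (ga, gb), "p_method": method, "alternative": alternative},
    )


def _chi_square(cohort: pd.DataFrame, outcome: str, group_col: str) -> GroupComparisonResult:
    sub = cohort[[group_col, outcome]].dropna()
    table = pd.crosstab(sub[group_col], sub[outcome])
    if min(table.shape) < 2:
        # Degenerate contingency table: observed == expected by construction.
        return GroupComparisonResult(outcome=outcome, method="chi_square",
                                     statistic=0.0, p_value=1.0,
                                     extras={"dof": 0})
    stat, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return GroupComparisonResult(outcome=outcome, method="chi_square",
                                 statistic=float(stat), p_value=float(p),
                                 extras={"dof": int(dof)})


def compare_groups(
    cohort: pd.DataFrame,
    outcome: str,
    method: str,
    covariates: Sequence[str] = (),
    *,
    group_col: str = "group",
    alternative: str = "two-sided",
) -> GroupComparisonResult:
    """Compare an outcome across staging groups with the requested method.

    ``covariates`` are used by ``ancova_age`` (default ``("age",)``) and by
    ``tukey_posthoc`` (adjusted means); ``alternative`` applies to
    ``mann_whitney`` only.
    """
    if method == "anova":
        return _anova_f(cohort, outcome, group_col, ())
    if method == "ancova_age":
        return _anova_f(cohort, outcome, group_col, covariates or ("age",))
    if method == "tukey_posthoc":
        return _tukey_posthoc(cohort, outcome, group_col, covariates)
    if method == "mann_whitney":
        return _mann_whitney(cohort, outcome, group_col, alternative)
    if method == "chi_square":
        return _chi_square(cohort, outcome, group_col)
    if method == "jonckheere":
        groups = _group_arrays(cohort, outcome, group_col)
        ordered = [groups[g] for g in sorted(groups)]
        return jonckheere_trend(ordered, alternative=alternative, outcome=outcome)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """Sum of pairwise Mann-Whitney counts over ordered group pairs
    (ties count 1/2)."""
    jt = 0.0
    for i, j in itertools.combinations(range(len(groups)), 2):
        x, y = groups[i][:, None], groups[j][None, :]
        jt += float(np.sum(x < y) + 0.5 * np.sum(x == y))
    return jt


def _jt_null_moments(pooled: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the JT statistic."""
    n = int(sizes.sum())
    mean = (n * n - float(np.sum(sizes**2))) / 4.0
    _, ties = np.unique(pooled, return_counts=True)
    ni = sizes.astype(float)
    tj = ties.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(ni * (ni - 1) * (2 * ni + 5))
        - np.sum(tj * (tj - 1) * (2 * tj + 5))
    ) / 72.0
    term2 = (
        np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(tj * (tj - 1) * (tj - 2))
    ) / (36.0 * n * (n - 1) * (n - 2))
    term3 = (np.sum(ni * (ni - 1)) * np.sum(tj * (tj - 1))) / (8.0 * n * (n - 1))
    return mean, float(term1 + term2 + term3)


def jonckheere_trend(
    groups_ordered: Sequence[Sequence[float]],
    *,
    alternative: str = "two-sided",
    n_permutations: int | None = None,
    seed: int | None = None,
    outcome: str = "",
) -> GroupComparisonResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    The p-value uses the tie-corrected normal approximation;
    ``alternative`` is ``"increasing"``, ``"decreasing"`` or
    ``"two-sided"``. If ``n_permutations`` is given, a seeded permutation
    p-value (same alternative) is added to ``extras``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups_ordered]
    if len(arrays) < 3:
        raise ValueError("jonckheere_trend requires >= 3 ordered groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group passed to jonckheere_trend")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate(arrays)
    sizes = np.array([a.size for a in arrays])
    jt = _jt_statistic(arrays)
    mean, var = _jt_null_moments(pooled, sizes)

    if var <= 0:  # all observations tied: no information, z = 0
        z = 0.0
        p = 1.0
    else:
        z = (jt - mean) / math.sqrt(var)
        if alternative == "increasing":
            p = float(sps.norm.sf(z))
        elif alternative == "decreasing":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2.0 * sps.norm.sf(abs(z)))
    extras = {"z": z, "null_mean": mean, "null_var": var, "alternative": alternative}

    if n_permutations:
        rng = np.random.default_rng(seed)
        splits = np.cumsum(sizes)[:-1]
        count = 0
        for _ in range(int(n_permutations)):
            perm = rng.permutation(pooled)
            jt_p = _jt_statistic(np.split(perm, splits))
            if alternative == "increasing":
                count += jt_p >= jt
            elif alternative == "decreasing":
                count += jt_p <= jt
            else:
                count += abs(jt_p - mean) >= abs(jt - mean)
        extras["p_permutation"] = (count + 1) / (int(n_permutations) + 1)
        extras["n_permutations"] = int(n_permutations)

    return GroupComparisonResult(outcome=outcome, method="jonckheere",
                                 statistic=jt, p_value=min(p, 1.0), extras=extras)


# ---------------------------------------------------------------------------
# Bootstrap comparison of lobar involvement frequencies


@dataclass
class FrequencyBootstrapResult:
    """Lobar involvement frequencies with bootstrap pairwise p-values.

    ``frequencies`` gives, per lobe, the fraction of included subjects
    positive in either hemisphere; ``pairwise_p`` is symmetric in its
    ``(lobe_a, lobe_b)`` keys.
    """

    frequencies: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    n_resamples: int
    neg_log10_p: dict[tuple[str, str], float]
    n_subjects: int
    resample_mean: dict[str, float] = field(default_factory=dict)

    def neg_log10_matrix(self) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=list(LOBES), columns=list(LOBES))
        for (a, b), v in self.neg_log10_p.items():
            mat.loc[a, b] = v
        return mat


def involvement_frequency_bootstrap(
    staging: Sequence[StagingResult],
    n_resamples: int = 1000,
    seed: int | None = None,
) -> FrequencyBootstrapResult:
    """Compare lobar involvement frequencies by participant bootstrap.

    Only subjects with at least one involved region enter. A lobe counts as
    involved if either hemisphere's flag is set. For each lobe pair the
    two-sided bootstrap p is ``2 * min(P*(freq_a <= freq_b),
    P*(freq_a >= freq_b))`` over resamples of participants with
    replacement; ``neg_log10_p`` floors p at ``1 / n_resamples``.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    eligible = [r for r in staging if r.n_involved >= 1]
    if not eligible:
        raise ValueError("no subjects with focal involvement")
    n = len(eligible)
    flags = np.zeros((n, len(LOBES)), dtype=bool)
    for i, r in enumerate(eligible):
        for j, lobe in enumerate(LOBES):
            flags[i, j] = r.region_flags[f"{lobe}_left"] or r.region_flags[f"{lobe}_right"]

    frequencies = {lobe: float(flags[:, j].mean()) for j, lobe in enumerate(LOBES)}

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(int(n_resamples), n))
    boot_freq = flags[idx].mean(axis=1)  # (n_resamples, 5)

    pairwise_p: dict[tuple[str, str], float] = {}
    neg_log10: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(range(len(LOBES)), 2):
        le = float(np.mean(boot_freq[:, a] <= boot_freq[:, b]))
        ge = float(np.mean(boot_freq[:, a] >= boot_freq[:, b]))
        p = min(2.0 * min(le, ge), 1.0)
        nl = -math.log10(max(p, 1.0 / n_resamples))
        la, lb = LOBES[a], LOBES[b]
        pairwise_p[(la, lb)] = pairwise_p[(lb, la)] = p
        neg_log10[(la, lb)] = neg_log10[(lb, la)] = nl

    return FrequencyBootstrapResult(
        frequencies=frequencies,
        pairwise_p=pairwise_p,
        n_resamples=int(n_resamples),
        neg_log10_p=neg_log10,
        n_subjects=n,
        resample_mean={lobe: float(boot_freq[:, j].mean())
                       for j, lobe in enumerate(LOBES)},
    )


# ---------------------------------------------------------------------------
# AIC comparison of groupings


@dataclass
class AicComparison:
    """AIC of the G/F grouping vs a dcCL-band grouping for one outcome."""

    outcome: str
    aic_fg_grouping: float
    aic_cl_grouping: float
    preferred: str

    def __post_init__(self) -> None:
        if self.preferred not in ("fg", "cl"):
            raise ValueError(f"preferred must be 'fg' or 'cl', got {self.preferred!r}")


def cl_band_labels(cl: pd.Series, cl_bands: tuple[float, float]) -> pd.Series:
    """Negative / subthreshold / positive labels from dcCL bands."""
    lo, hi = cl_bands
    if not lo < hi:
        raise ValueError("cl_bands must be increasing")
    return pd.cut(
        cl, bins=[-np.inf, lo, hi, np.inf], right=False,
        labels=["negative", "subthreshold", "positive"],
    ).astype(str)


def compare_groupings_aic(
    cohort: pd.DataFrame,
    outcome: str,
    cl_bands: tuple[float, float] = (10.0, 25.11),
    covariates: Sequence[str] = ("age",),
    *,
    group_col: str = "group",
    cl_col: str = "global_cl",
) -> AicComparison:
    """Which 3-level grouping fits an outcome better by Gaussian AIC?

    Fits ``outcome ~ grouping (+ covariates)`` by least squares for (a) the
    G/F staging groups and (b) the dcCL bands; lower AIC wins, ties go to
    the G/F grouping.
    """
    data = cohort[[outcome, group_col, cl_col, *covariates]].dropna().copy()
    data["_cl_band"] = cl_band_labels(data[cl_col], cl_bands)
    for col in (group_col, "_cl_band"):
        if data[col].nunique() < 2:
            raise ValueError(f"grouping {col!r} is degenerate (single level)")
    fit_fg, _ = _ols_fit(data, outcome, group_col, covariates)
    fit_cl, _ = _ols_fit(data, outcome, "_cl_band", covariates)
    aic_fg, aic_cl = float(fit_fg.aic), float(fit_cl.aic)
    return AicComparison(
        outcome=outcome,
        aic_fg_grouping=aic_fg,
        aic_cl_grouping=aic_cl,
        preferred="fg" if aic_fg <= aic_cl else "cl",
    )
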