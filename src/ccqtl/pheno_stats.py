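"""Phenotype-level statistics for replicated inbred-line cohorts.

Summaries, pairwise Pearson correlations, multi-way covariate ANOVA with
optional pairwise interactions, Duncan's multiple-range grouping of line
means, broad-sense and line-mean heritability, Benjamini-Hochberg FDR and
Welch's t-test.

Design matrices are built by hand (intercept + treatment-coded dummies) and
nested models compared by rank-aware F-tests, which doubles as the
aliased-covariate detection the unbalanced designs need.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cc_synth import CCCohort

LOGP_CAP = 50.0

__all__ = [
    "trait_summary", "pairwise_trait_correlation", "covariate_anova",
    "broad_sense_h2", "line_mean_h2", "duncan_lsr", "bh_fdr", "welch_t_test",
    "HeritabilityResult", "CovariateDecomposition", "LSRGrouping",
    "CorrelationResult", "WelchResult",
]


# ---------------------------------------------------------------------------
# linear-model plumbing shared with the scan modules
# ---------------------------------------------------------------------------

def design_matrix(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + treatment-coded dummy columns for the given covariates."""
    cols = [np.ones(len(df))]
    for c in covariates:
        d = pd.get_dummies(df[c].astype(str), drop_first=True, dtype=float)
        cols.append(d.to_numpy())
    return np.column_stack(cols) if cols else np.ones((len(df), 1))

def _fit_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Least-squares residual sum of squares and design rank."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)

def nested_f_test(rss0: float, rank0: int, rss1: float, rank1: int,
                  n: int) -> tuple[float, float, int, int]:
    """F statistic and P for nested OLS models; returns (F, P, df1, df2)."""
    df1 = rank1 - rank0
    df2 = n - rank1
    if df1 <= 0 or df2 <= 0:
        return np.nan, np.nan, df1, df2
    if rss1 <= 0:
        return np.inf, 0.0, df1, df2
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    return f, float(stats.f.sf(f, df1, df2)), df1, df2

def neg_log10(p: float, cap: float = LOGP_CAP) -> float:
    if not np.isfinite(p) or p <= 0:
        return cap
    return float(min(-np.log10(p), cap))


# ---------------------------------------------------------------------------
# summaries and correlations
# ---------------------------------------------------------------------------

def trait_summary(cohort: CCCohort, trait: str) -> tuple[float, float, float]:
    """(min, max, mean) of a trait over all mice with a recorded value."""
    v = cohort.trait_values(trait).dropna()
    if len(v) == 0:
        raise ValueError(f"trait {trait!r} has no observed values")
    return float(v.min()), float(v.max()), float(v.mean())


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; the shared kernel of every correlation
    reported by the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ZeroDivisionError("correlation undefined for a zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)


def pairwise_trait_correlation(cohort: CCCohort, traits: list[str]) -> CorrelationResult:
    """Mouse-level Pearson correlation matrix over the named traits.

    Zero-variance traits are flagged in ``degenerate`` and their rows and
    columns set to NaN (diagonal kept at 1) rather than silently propagated.
    Requires at least 3 complete observations per pair.
    """
    df = cohort.mice[list(traits)]
    counts = df.notna().astype(int).T @ df.notna().astype(int)
    if (counts.to_numpy() < 3).any():
        raise ValueError("fewer than 3 complete observations for some trait pair")
    degenerate = [t for t in traits if df[t].dropna().std() == 0]
    mat = df.corr(method="pearson")
    for t in degenerate:
        mat.loc[t, :] = np.nan
        mat.loc[:, t] = np.nan
    np.fill_diagonal(mat.values, 1.0)
    return CorrelationResult(mat, degenerate)


# ---------------------------------------------------------------------------
# covariate ANOVA
# ---------------------------------------------------------------------------

@dataclass
class CovariateDecomposition:
    """Per-covariate Type-II P-values plus the cumulative percentage of the
    trait's total sum of squares carried by pairwise covariate interactions."""

    p_values: dict[str, float]
    interaction_percent: float | None
    dropped: list[str] = field(default_factory=list)


def covariate_anova(
    cohort: CCCohort,
    trait: str,
    covariates: list[str],
    with_interactions: bool = False,
) -> CovariateDecomposition:
    """Multi-way fixed-effects ANOVA of a trait on categorical covariates.

    Type II sums of squares: each covariate's F compares the all-main-effects
    model with the model omitting that covariate.  Covariates that add no
    rank to the design (aliased with the others) are dropped with a warning.
    With ``with_interactions`` the cumulative sum of squares of all pairwise
    interaction terms (added jointly on top of the main effects) is expressed
    as a percentage of the total sum of squares.
    """
    df = cohort.mice.dropna(subset=[trait])
    y = df[trait].to_numpy(dtype=float)
    n = len(y)

    usable, dropped = [], []
    for c in covariates:
        if df[c].nunique() < 2:
            dropped.append(c)
            warnings.warn(f"covariate {c!r} has fewer than 2 observed levels; dropped",
                          stacklevel=2)
        else:
            usable.append(c)

    X_full = design_matrix(df, usable)
    rss_full, rank_full = _fit_rss(X_full, y)
    pvals: dict[str, float] = {}
    for c in list(usable):
        others = [o for o in usable if o != c]
        X_red = design_matrix(df, others)
        rss_red, rank_red = _fit_rss(X_red, y)
        _, p, df1, _ = nested_f_test(rss_red, rank_red, rss_full, rank_full, n)
        if df1 <= 0:  # aliased: adds no rank beyond the other covariates
            dropped.append(c)
            usable.remove(c)
            warnings.warn(f"covariate {c!r} is aliased with the others; dropped",
                          stacklevel=2)
            X_full, (rss_full, rank_full) = X_red, (rss_red, rank_red)
        else:
            pvals[c] = p

    interaction_percent = None
    if with_interactions:
        cols = [X_full]
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                a = pd.get_dummies(df[usable[i]].astype(str), drop_first=True, dtype=float).to_numpy()
                b = pd.get_dummies(df[usable[j]].astype(str), drop_first=True, dtype=float).to_numpy()
                inter = np.einsum("np,nq->npq", a, b).reshape(len(df), -1)
                cols.append(inter)
        X_int = np.column_stack(cols)
        rss_int, _ = _fit_rss(X_int, y)
        ss_total = float(((y - y.mean()) ** 2).sum())
        ss_inter = max(rss_full - rss_int, 0.0)
        interaction_percent = 100.0 * ss_inter / ss_total if ss_total > 0 else 0.0

    return CovariateDecomposition(pvals, interaction_percent, dropped)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityResult:
    """Broad-sense heritability of a trait across inbred lines.

    H2 is the variance-component estimate from expected mean squares of the
    covariate-adjusted line ANOVA; logP is -log10 of the F test of the line
    factor; H2n is the heritability of line means given n_bar replicates.
    """

    H2: float
    logP: float
    H2n: float
    n_bar: float
    F: float = np.nan
    df: tuple[int, int] = (0, 0)


def broad_sense_h2(cohort: CCCohort, trait: str,
                   covariates: list[str] = ()) -> HeritabilityResult:
    """Estimate broad-sense heritability from line replication.

    Fits the covariates-only null and the covariates+line model; the line
    factor's F test gives logP, and the expected-mean-squares estimator

        H2 = (MS_line - MS_resid) / (MS_line + (n0 - 1) * MS_resid)

    gives the intraclass variance fraction, with
    n0 = (N - sum n_i^2 / N) / (k - 1) the effective replicate number for
    unbalanced designs.  H2 is clipped to [0, 1].
    """
    df = cohort.mice.dropna(subset=[trait])
    counts = df.groupby("line", sort=False).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("heritability needs at least 2 lines with >= 2 mice")
    if (counts >= 2).sum() == 0 or counts.max() < 2:
        raise ValueError("heritability undefined with one mouse per line")
    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    X0 = design_matrix(df, list(covariates))
    X1 = np.column_stack([X0, pd.get_dummies(df["line"].astype(str),
                                             drop_first=True, dtype=float)])
    rss0, rank0 = _fit_rss(X0, y)
    rss1, rank1 = _fit_rss(X1, y)
    f, p, df1, df2 = nested_f_test(rss0, rank0, rss1, rank1, n)
    ms_line = (rss0 - rss1) / df1
    ms_resid = rss1 / df2 if df2 > 0 else np.nan
    k = len(counts)
    n0 = (n - float((counts ** 2).sum()) / n) / (k - 1)
    if ms_resid == 0:
        h2 = 1.0
    else:
        h2 = (ms_line - ms_resid) / (ms_line + (n0 - 1.0) * ms_resid)
    h2 = float(np.clip(h2, 0.0, 1.0))
    n_bar = float(counts.mean())
    return HeritabilityResult(h2, neg_log10(p), line_mean_h2(h2, n_bar),
                              n_bar, f, (df1, df2))


def line_mean_h2(H2: float, n_bar: float) -> float:
    """Heritability of line means: H2n = H2 / (H2 + (1 - H2)/n_bar)."""
    if not 0.0 <= H2 <= 1.0:
        raise ValueError("H2 must lie in [0, 1]")
    if n_bar < 1:
        raise ValueError("n_bar must be >= 1")
    if H2 == 0.0:
        return 0.0
    return H2 / (H2 + (1.0 - H2) / n_bar)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class LSRGrouping:
    """Letter groups of line means under Duncan's multiple-range procedure.

    ``table`` has columns line, mean, group (letter string); lines sharing a
    letter are not separable at the protection level implied by ``alpha``.
    Rows are ordered by descending mean.
    """

    table: pd.DataFrame
    alpha: float


def duncan_critical_ranges(n_means: int, mse: float, df_error: int,
                           n_harmonic: float, alpha: float) -> np.ndarray:
    """Duncan least significant range for each span p = 2..n_means.

    Uses the studentized range at protection level 1 - (1 - alpha)^(p-1).
    Index p-2 of the returned array holds the range for span p.
    """
    spans = np.arange(2, n_means + 1)
    alpha_p = 1.0 - (1.0 - alpha) ** (spans - 1)
    q = stats.studentized_range.ppf(1.0 - alpha_p, spans, df_error)
    return q * np.sqrt(mse / n_harmonic)


def duncan_lsr(line_means: pd.Series | dict, mse: float, df_error: int,
               reps: pd.Series | dict | int, alpha: float = 0.001) -> LSRGrouping:
    """Duncan's multiple range test over line means.

    Means are sorted descending; a run of means spanning p positions is
    homogeneous when its extreme difference does not exceed the least
    significant range for span p, with the usual protection that a run
    inside a homogeneous run is never declared significant.  Maximal
    homogeneous runs receive letters a, b, c, ...; unbalanced replicate
    counts enter through their harmonic mean.
    """
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    means = pd.Series(line_means, dtype=float)
    k = len(means)
    if isinstance(reps, int):
        reps = pd.Series(reps, index=means.index)
    else:
        reps = pd.Series(reps).reindex(means.index)
    n_h = k / float((1.0 / reps).sum())

    order = means.sort_values(ascending=False, kind="mergesort")
    vals = order.to_numpy()
    if k == 1:
        table = pd.DataFrame({"line": order.index, "mean": vals, "group": ["a"]})
        return LSRGrouping(table, alpha)
    ranges = duncan_critical_ranges(k, mse, df_error, n_h, alpha)

    # homogeneous[i][j]: run i..j not separable (with containment protection)
    homogeneous = np.zeros((k, k), dtype=bool)
    for i in range(k):
        homogeneous[i, i] = True
    for span in range(k, 1, -1):  # largest spans first
        for i in range(0, k - span + 1):
            j = i + span - 1
            if vals[i] - vals[j] <= ranges[span - 2]:
                homogeneous[i, j] = True
        # protection: runs inside an established homogeneous run inherit it
        for i in range(0, k - span + 1):
            j = i + span - 1
            if not homogeneous[i, j]:
                for a in range(0, i + 1):
                    for b in range(j, k):
                        if (b - a + 1) > span and homogeneous[a, b]:
                            homogeneous[i, j] = True
                            break
                    if homogeneous[i, j]:
                        break

    # maximal homogeneous runs -> letters
    runs = []
    for i in range(k):
        for j in range(i, k):
            if homogeneous[i, j]:
                contained = any(a <= i and j <= b and (a, b) != (i, j)
                                for a, b in runs)
                if not contained:
                    runs.append((i, j))
    runs = [r for r in runs
            if not any(a <= r[0] and r[1] <= b and (a, b) != r for a, b in runs)]
    runs.sort()
    letters = _letter_sequence(len(runs))
    labels = ["" for _ in range(k)]
    for letter, (a, b) in zip(letters, runs):
        for i in range(a, b + 1):
            labels[i] += letter
    table = pd.DataFrame({"line": order.index, "mean": vals, "group": labels})
    return LSRGrouping(table.reset_index(drop=True), alpha)


def _letter_sequence(n: int) -> list[str]:
    base = string.ascii_lowercase
    out = []
    for i in range(n):
        s = ""
        i2 = i
        while True:
            s = base[i2 % 26] + s
            i2 = i2 // 26 - 1
            if i2 < 0:
                break
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# multiple testing and Welch's t
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, reject flags at FDR level q)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, adj <= q


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(group_a, group_b) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, np.nan, 1.0, degenerate=True)
        return WelchResult(np.inf if a.mean() > b.mean() else -np.inf,
                           np.nan, 0.0, degenerate=True)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)
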