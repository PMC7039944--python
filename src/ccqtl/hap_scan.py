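"""Genome-wide haplotype association scan on founder-descent probabilities.

At each marker the mouse-level phenotype is regressed on the eight
founder-descent probability columns (one dropped for identifiability, by
default the WSB/EiJ reference) on top of the experimental covariates, and
the nested-model partial F-test P-value is reported as logP = -log10(P).
Genome-wide significance thresholds come from permutations at the line
level; contiguous super-threshold runs are collapsed to QTL calls with
regional heritability and founder-effect deviations.

The `ScanEngine` pre-orthogonalises the per-marker designs against the
covariate space, so rescanning many phenotype vectors (permutations,
residual-resampling confidence intervals) reduces to one matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orth

from .cc_synth import (CCCohort, DescentProbs, N_FOUNDERS, REFERENCE_FOUNDER)
from .pheno_stats import LOGP_CAP, design_matrix, welch_t_test

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-marker association strength and founder effects for one trait.

    ``table`` columns: chrom, pos_bp, logP, degenerate, and one additive
    effect column per founder (the dropped reference founder's effect is 0;
    effect standard errors are in ``se``, aligned with ``effects``).
    """

    trait: str
    chrom: np.ndarray
    pos_bp: np.ndarray
    logp: np.ndarray
    effects: np.ndarray          # (n_markers, 8)
    se: np.ndarray               # (n_markers, 8); reference column 0
    degenerate: np.ndarray       # bool mask of rank-deficient markers
    founders: tuple[str, ...]
    reference: str = REFERENCE_FOUNDER

    @property
    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos_bp": self.pos_bp,
                           "logP": self.logp, "degenerate": self.degenerate})
        for i, f in enumerate(self.founders):
            df[f"effect_{f}"] = self.effects[:, i]
        return df

    def marker_index(self, chrom, pos_bp: int) -> int:
        hit = np.flatnonzero((self.chrom == str(chrom)) & (self.pos_bp == pos_bp))
        if len(hit) == 0:
            raise KeyError(f"no scanned marker at {chrom}:{pos_bp}")
        return int(hit[0])


@dataclass
class ThresholdSet:
    """Genome-wide logP cut-offs from null permutations."""

    cutoffs: dict[int, float]    # percentile -> logP
    n_simulations: int
    max_logp_null: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        pcts = sorted(self.cutoffs)
        for lo, hi in zip(pcts[:-1], pcts[1:]):
            if self.cutoffs[hi] < self.cutoffs[lo] - 1e-12:
                raise ValueError("threshold cut-offs must be non-decreasing in percentile")


@dataclass
class QTLCall:
    trait: str
    chrom: str
    pos_bp: int
    logp: float
    threshold: float
    h2_region: float | None = None
    ci: dict | None = None       # level -> (start bp, end bp, width Mb)


@dataclass
class FounderDeviation:
    """Additive founder effects re-expressed relative to a reference strain."""

    founders: tuple[str, ...]
    deviation: np.ndarray
    se: np.ndarray
    reference: str


# ---------------------------------------------------------------------------
# scan engine
# ---------------------------------------------------------------------------

class ScanEngine:
    """Pre-factorised haplotype-scan design for one cohort.

    Orthonormalises the covariate design once and each marker's founder
    probability columns (reference dropped, residualised against the
    covariates) once; ``logp_matrix`` then evaluates the per-marker partial
    F-test for any batch of phenotype vectors with two matrix products.
    """

    def __init__(self, cohort: CCCohort, descent: DescentProbs,
                 covariates: list[str] = (), markers: np.ndarray | None = None,
                 reference: str = REFERENCE_FOUNDER):
        self.cohort = cohort
        self.descent = descent
        self.covariates = list(covariates)
        if reference not in descent.founders:
            raise KeyError(f"unknown reference founder {reference!r}")
        self.reference = reference
        ref_idx = descent.founders.index(reference)
        self.keep_cols = [i for i in range(N_FOUNDERS) if i != ref_idx]
        self.ref_idx = ref_idx

        df = cohort.mice
        self.n = len(df)
        line_pos = {l: i for i, l in enumerate(descent.lines)}
        self.mouse_line_idx = df["line"].map(line_pos).to_numpy()

        self.marker_idx = (np.arange(descent.n_markers)
                           if markers is None else np.asarray(markers, dtype=int))
        self.chrom = descent.chrom[self.marker_idx]
        self.pos_bp = descent.pos_bp[self.marker_idx]

        X0 = design_matrix(df, self.covariates)
        self.Q0 = orth(X0)                      # (n, rank0)
        self.rank0 = self.Q0.shape[1]

        # mouse-level founder probabilities, covariate-residualised
        P = descent.probs[self.mouse_line_idx][:, self.marker_idx, :]
        self.P_mouse = P
        P7 = P[:, :, self.keep_cols]            # (n, m, 7)
        # project each marker's probability columns off the covariate space
        P7r = P7 - np.einsum("nk,kmj->nmj", self.Q0,
                             np.einsum("nk,nmj->kmj", self.Q0, P7))
        # per-marker orthonormal bases via batched SVD (rank-aware)
        A = np.transpose(P7r, (1, 0, 2))        # (m, n, 7)
        U, S, _ = np.linalg.svd(A, full_matrices=False)
        # rank threshold on an absolute scale: probability columns are O(1),
        # so a fully covariate-aliased marker must not keep noise directions
        scale = np.maximum(S.max(axis=1, keepdims=True), 1.0)
        keep = S > _RANK_TOL * scale
        self.rank_add = keep.sum(axis=1)        # numerator df per marker
        Um = U * keep[:, None, :]               # zero out null directions
        self.Q = np.transpose(Um, (1, 0, 2))    # (n, m, 7)
        m = len(self.marker_idx)
        self.Q_flat = self.Q.reshape(self.n, m * 7)

    # -- batched F-test -----------------------------------------------------
    def logp_matrix(self, Y: np.ndarray, cap: float = LOGP_CAP) -> np.ndarray:
        """logP for every marker (rows) and every phenotype column of Y."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        if Y.shape[0] != self.n:
            raise ValueError("phenotype length does not match the cohort")
        My = Y - self.Q0 @ (self.Q0.T @ Y)
        rss0 = (My ** 2).sum(axis=0)            # (k,)
        m = len(self.marker_idx)
        proj = self.Q_flat.T @ My               # (m*7, k)
        ssr = (proj.reshape(m, 7, -1) ** 2).sum(axis=1)   # (m, k)
        rss1 = np.maximum(rss0[None, :] - ssr, 0.0)
        df1 = self.rank_add.astype(float)[:, None]
        df2 = (self.n - self.rank0 - self.rank_add).astype(float)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssr / df1) / (rss1 / df2)
            p = stats.f.sf(f, df1, df2)
            logp = np.where(np.isfinite(f) & (f > 0), -np.log10(p), np.inf)
        logp = np.where(rss1 <= _RANK_TOL * np.maximum(rss0[None, :], 1e-300),
                        cap, logp)
        logp = np.where(df1 <= 0, 0.0, logp)
        # constant / covariate-explained trait: nothing left to test
        y_scale = np.maximum((Y ** 2).sum(axis=0), 1.0)
        logp = np.where(rss0[None, :] <= 1e-12 * y_scale, 0.0, logp)
        return np.minimum(np.nan_to_num(logp, nan=0.0, posinf=cap), cap)

    def max_logp(self, Y: np.ndarray) -> np.ndarray:
        return self.logp_matrix(Y).max(axis=0)

    # -- full fit with effects ---------------------------------------------
    def effects_at(self, y: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
        """Founder coefficients and SEs from the full model at marker m
        (engine-local index); reference founder fixed at 0."""
        X = np.column_stack([self.Q0, self.P_mouse[:, m, :][:, self.keep_cols]])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df2 = self.n - rank
        sigma2 = float(resid @ resid) / df2 if df2 > 0 else 0.0
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        eff = np.zeros(N_FOUNDERS)
        se = np.zeros(N_FOUNDERS)
        eff[self.keep_cols] = beta[self.rank0:]
        se[self.keep_cols] = np.sqrt(np.maximum(np.diag(cov)[self.rank0:], 0.0))
        return eff, se


def scan_trait(cohort: CCCohort, descent: DescentProbs, trait: str,
               covariates: list[str] = (), engine: ScanEngine | None = None) -> ScanResult:
    """Haplotype-based association scan of one trait across all markers."""
    if descent.n_markers == 0:
        raise ValueError("descent probabilities contain no markers")
    y = cohort.trait_values(trait).to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"trait {trait!r} contains non-finite values")
    eng = engine or ScanEngine(cohort, descent, covariates)
    logp = eng.logp_matrix(y)[:, 0]
    m = len(eng.marker_idx)
    effects = np.zeros((m, N_FOUNDERS))
    se = np.zeros((m, N_FOUNDERS))
    for i in range(m):
        effects[i], se[i] = eng.effects_at(y, i)
    degenerate = eng.rank_add < len(eng.keep_cols)
    logp = np.where(eng.rank_add == 0, 0.0, logp)
    return ScanResult(trait, eng.chrom, eng.pos_bp, logp, effects, se,
                      degenerate, descent.founders, eng.reference)


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

def permuted_phenotypes(cohort: CCCohort, trait: str, covariates: list[str],
                        n_sim: int, seed: int) -> np.ndarray:
    """Null phenotype matrix (n_mice, n_sim) by line-level permutation.

    The covariate-adjusted line-mean deviations are permuted across line
    labels while every mouse keeps its within-line residual and covariates;
    under exchangeability of lines this reproduces the no-QTL null while
    preserving the line as the unit of replication.
    """
    rng = np.random.default_rng(seed)
    df = cohort.mice
    y = df[trait].to_numpy(dtype=float)
    X0 = design_matrix(df, list(covariates))
    beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
    yr = y - X0 @ beta
    lines = list(pd.unique(df["line"]))
    line_idx = df["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    a = np.array([yr[line_idx == i].mean() for i in range(len(lines))])
    centered = yr - a[line_idx]
    perms = np.stack([rng.permutation(len(lines)) for _ in range(n_sim)], axis=1)
    return centered[:, None] + a[perms][line_idx, :]


def genome_thresholds(cohort: CCCohort, descent: DescentProbs, trait: str,
                      covariates: list[str] = (), n_sim: int = 200,
                      seed: int = 0, percentiles: tuple[int, ...] = (95, 99),
                      engine: ScanEngine | None = None) -> ThresholdSet:
    """Genome-wide significance thresholds from line-permutation nulls.

    Rescans ``n_sim`` permuted phenotypes and takes empirical percentiles of
    the per-scan maximum logP.
    """
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20")
    if cohort.mice["line"].nunique() < 5:
        raise ValueError("permutation thresholds need at least 5 lines")
    eng = engine or ScanEngine(cohort, descent, covariates)
    Y = permuted_phenotypes(cohort, trait, covariates, n_sim, seed)
    maxima = eng.max_logp(Y)
    cutoffs = {int(p): float(np.percentile(maxima, p)) for p in percentiles}
    return ThresholdSet(cutoffs, n_sim, maxima)


# ---------------------------------------------------------------------------
# QTL calling and locus statistics
# ---------------------------------------------------------------------------

MERGE_GAP_BP = 2_000_000


def call_qtls(scan: ScanResult, thresholds: ThresholdSet, percentile: int = 99,
              merge_gap_bp: int = MERGE_GAP_BP) -> list[QTLCall]:
    """Collapse contiguous super-threshold runs into QTL calls.

    Runs on one chromosome separated by less than ``merge_gap_bp`` of
    sub-threshold markers are merged; each call sits at its maximum-logP
    marker (leftmost on ties).
    """
    if len(scan.pos_bp) == 0:
        raise ValueError("empty scan")
    cutoff = thresholds.cutoffs[int(percentile)]
    calls: list[QTLCall] = []
    for c in pd.unique(scan.chrom):
        on = np.flatnonzero(scan.chrom == c)
        on = on[np.argsort(scan.pos_bp[on], kind="mergesort")]
        above = scan.logp[on] >= cutoff
        runs: list[list[int]] = []
        current: list[int] = []
        for i, idx in enumerate(on):
            if above[i]:
                current.append(idx)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        merged: list[list[int]] = []
        for r in runs:
            if merged and scan.pos_bp[r[0]] - scan.pos_bp[merged[-1][-1]] < merge_gap_bp:
                merged[-1].extend(r)
            else:
                merged.append(list(r))
        for r in merged:
            lp = scan.logp[r]
            best = r[int(np.argmax(lp))]  # argmax takes first (leftmost) max
            calls.append(QTLCall(scan.trait, str(c), int(scan.pos_bp[best]),
                                 float(scan.logp[best]), cutoff))
    return calls


def regional_h2(cohort: CCCohort, descent: DescentProbs, trait: str,
                covariates: list[str] = (), chrom=None, pos_bp: int = None,
                reference: str = REFERENCE_FOUNDER) -> float:
    """Fraction of line-mean variance explained by founder descent at a locus.

    Line means of the covariate-adjusted trait are regressed on the locus
    descent probabilities; H2_r = (RSS_null - RSS_genetic) / RSS_null,
    clipped to [0, 1].
    """
    m = descent.nearest_marker(chrom, pos_bp)
    df = cohort.mice
    y = df[trait].to_numpy(dtype=float)
    X0 = design_matrix(df, list(covariates))
    beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
    yr = y - X0 @ beta
    line_order = list(pd.unique(df["line"]))
    means = pd.Series(yr).groupby(df["line"].values).mean().reindex(line_order)
    line_pos = [descent.lines.index(l) for l in line_order]
    P = descent.probs[line_pos, m, :]
    ref_idx = descent.founders.index(reference)
    keep = [i for i in range(N_FOUNDERS) if i != ref_idx]
    ym = means.to_numpy()
    ym_c = ym - ym.mean()
    rss0 = float(ym_c @ ym_c)
    if rss0 == 0:
        return 0.0
    Xg = np.column_stack([np.ones(len(ym)), P[:, keep]])
    b, *_ = np.linalg.lstsq(Xg, ym, rcond=None)
    r = ym - Xg @ b
    rss1 = float(r @ r)
    return float(np.clip((rss0 - rss1) / rss0, 0.0, 1.0))


def founder_effects(scan: ScanResult, chrom, pos_bp: int,
                    reference: str = REFERENCE_FOUNDER) -> FounderDeviation:
    """Founder effects at a marker, re-based as deviations from a reference.

    The deviation of the reference founder is identically zero.  When the
    requested reference is the one already dropped in the scan, the stored
    coefficients and SEs are the deviations; otherwise effects are shifted
    by the new reference's coefficient (SEs of differences with the old
    reference column are approximate, ignoring coefficient covariance).
    """
    if reference not in scan.founders:
        raise KeyError(f"unknown reference founder {reference!r}")
    m = scan.marker_index(chrom, pos_bp)
    if scan.degenerate[m] and scan.logp[m] == 0:
        raise ValueError(f"marker {chrom}:{pos_bp} was degenerate in the scan")
    ref = scan.founders.index(reference)
    dev = scan.effects[m] - scan.effects[m, ref]
    se = np.hypot(scan.se[m], scan.se[m, ref])
    se[ref] = 0.0
    if reference == scan.reference:
        se = scan.se[m].copy()
        se[ref] = 0.0
    return FounderDeviation(scan.founders, dev, se, reference)


@dataclass
class AlleleGroupResult:
    group_means: dict[str, float]
    group_n: dict[str, int]
    welch: object | None          # WelchResult between the homozygote groups
    excluded: list[str] = field(default_factory=list)


def allele_group_means(cohort: CCCohort, trait: str,
                       genotype_at_marker: dict) -> AlleleGroupResult:
    """Trait means by per-line genotype group at a biallelic marker.

    ``genotype_at_marker`` maps line label to a genotype string (e.g.
    "T:T", "C:C", "C:T"); the two homozygote groups (those whose two
    alleles agree) are compared with Welch's t-test over mice.  Groups with
    fewer than 2 mice are reported but excluded from testing.
    """
    df = cohort.mice[cohort.mice["line"].isin(genotype_at_marker)]
    geno = df["line"].map(genotype_at_marker)
    groups = {g: df.loc[geno == g, trait].dropna().to_numpy()
              for g in pd.unique(geno)}
    if len(groups) < 1:
        raise ValueError("no lines with genotype assignments")
    means = {g: float(v.mean()) for g, v in groups.items() if len(v)}
    ns = {g: int(len(v)) for g, v in groups.items()}
    excluded = [g for g, v in groups.items() if len(v) < 2]

    def _is_homo(g: str) -> bool:
        parts = g.split(":") if ":" in g else list(g)
        return len(set(parts)) == 1

    homo = [g for g in groups if _is_homo(g) and len(groups[g]) >= 2]
    welch = None
    if len(homo) >= 2:
        homo_sorted = sorted(homo)
        welch = welch_t_test(groups[homo_sorted[0]], groups[homo_sorted[1]])
    return AlleleGroupResult(means, ns, welch, excluded)
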