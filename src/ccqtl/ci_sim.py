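"""Resampling confidence intervals for QTL peak location.

The full haplotype model is fitted at the observed peak; replicate
phenotypes are built as fitted values plus residuals resampled with
replacement, the window around the peak is rescanned, and the distribution
of replicate argmax positions yields central equal-tail intervals at the
50/90/95% levels.  Equal-tail quantile intervals at nested levels are
nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cc_synth import CCCohort, DescentProbs, N_FOUNDERS
from .hap_scan import QTLCall, ScanEngine
from .pheno_stats import design_matrix

CI_LEVELS = (50, 90, 95)


@dataclass
class CIResult:
    """Peak-location confidence intervals from residual resampling."""

    intervals: dict[int, tuple[int, int, float]]   # level -> (start, end, width Mb)
    peak_positions: np.ndarray
    n_sim: int

    def __post_init__(self) -> None:
        levels = sorted(self.intervals)
        for lo, hi in zip(levels[:-1], levels[1:]):
            s1, e1, _ = self.intervals[lo]
            s2, e2, _ = self.intervals[hi]
            assert s2 <= s1 and e1 <= e2, "CI levels must be nested"


def simulate_ci(cohort: CCCohort, descent: DescentProbs, trait: str,
                covariates: list[str] = (), qtl: QTLCall = None,
                n_sim: int = 1000, window_mb: float = 10.0, seed: int = 0,
                resample: str = "line",
                levels: tuple[int, ...] = CI_LEVELS) -> CIResult:
    """Simulation-based CI for a QTL's peak position.

    Parameters
    ----------
    qtl : the called QTL whose peak anchors the rescan window.
    n_sim : number of resampled phenotypes (>= 100).
    window_mb : half-width of the rescan window around the peak, Mb.
    resample : residual resampling scheme.
        "line" (default) resamples hierarchically: line-mean residual
        deviations with replacement across lines plus within-line residuals
        across mice, preserving the two variance layers of the replicated
        inbred-line design (the peak model has no line factor, so the
        polygenic line variance sits in its residuals).  "mouse" resamples
        whole-mouse residuals unconditionally; "within_line" keeps every
        draw inside the mouse's own line.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    peak = descent.nearest_marker(qtl.chrom, qtl.pos_bp)
    half = int(window_mb * 1e6)
    on = np.flatnonzero((descent.chrom == str(qtl.chrom))
                        & (np.abs(descent.pos_bp.astype(np.int64) - qtl.pos_bp) <= half))
    if len(on) < 3:
        raise ValueError("rescan window must contain at least 3 markers")

    df = cohort.mice
    y = df[trait].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    # full model at the observed peak: covariates + founder probabilities
    eng = ScanEngine(cohort, descent, list(covariates), markers=on)
    line_pos = {l: i for i, l in enumerate(descent.lines)}
    midx = df["line"].map(line_pos).to_numpy()
    Ppeak = descent.probs[midx, peak, :][:, eng.keep_cols]
    X = np.column_stack([design_matrix(df, list(covariates)), Ppeak])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted

    n = len(y)
    if resample == "line":
        lines = list(pd.unique(df["line"]))
        lidx = df["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
        a = np.array([resid[lidx == i].mean() for i in range(len(lines))])
        e = resid - a[lidx]
        a_star = a[rng.integers(len(lines), size=(len(lines), n_sim))]
        e_star = e[rng.integers(n, size=(n, n_sim))]
        Y = fitted[:, None] + a_star[lidx, :] + e_star
    elif resample == "mouse":
        Y = fitted[:, None] + resid[rng.integers(n, size=(n, n_sim))]
    elif resample == "within_line":
        idx = np.empty((n, n_sim), dtype=int)
        for l in pd.unique(df["line"]):
            rows = np.flatnonzero(df["line"].to_numpy() == l)
            idx[rows] = rows[rng.integers(len(rows), size=(len(rows), n_sim))]
        Y = fitted[:, None] + resid[idx]
    else:
        raise ValueError(f"unknown resampling scheme {resample!r}")

    logp = eng.logp_matrix(Y)                       # (n_window_markers, n_sim)
    peaks = eng.pos_bp[np.argmax(logp, axis=0)]     # first max = leftmost tie

    intervals = {}
    for lev in levels:
        tail = (100.0 - lev) / 2.0
        lo, hi = np.percentile(peaks, [tail, 100.0 - tail])
        intervals[int(lev)] = (int(np.floor(lo)), int(np.ceil(hi)),
                               float((np.ceil(hi) - np.floor(lo)) / 1e6))
    return CIResult(intervals, peaks.astype(np.int64), n_sim)


def attach_ci(qtl: QTLCall, ci: CIResult) -> QTLCall:
    """Return the QTL call with the CI dictionary filled in."""
    qtl.ci = dict(ci.intervals)
    return qtl
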