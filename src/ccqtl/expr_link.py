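"""Expression-phenotype linkage for candidate genes.

qPCR relative expression by the delta-delta-Ct method (target Ct minus
housekeeping Ct, re-centred on a reference line, fold = 2^(-ddCt)),
Pearson correlation of per-line expression with a per-line trait mean, and
windowed inspection of an externally summarised RNA-seq count table around
a locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pheno_stats import pearson_r

ND_CYCLE_CAP = 35.0


@dataclass
class ExpressionTable:
    """Per-sample qPCR folds and per-line summary after ddCt normalisation.

    ``samples`` columns: sample, line, ct_target, ct_housekeeping, dct, fold,
    nd (undetected flag); ``line_folds`` maps line to the fold of its mean
    dCt relative to the reference line (reference exactly 1).
    """

    samples: pd.DataFrame
    line_folds: pd.Series
    reference_line: str
    nd_samples: list = field(default_factory=list)


def relative_expression(ct: pd.DataFrame, target: str, housekeeping: str,
                        reference_line: str,
                        cycle_cap: float = ND_CYCLE_CAP) -> ExpressionTable:
    """ddCt relative expression, normalised to a housekeeping gene and a
    reference line.

    ``ct`` needs columns sample, line, and one Ct column per gene.  Samples
    whose target Ct reaches ``cycle_cap`` (or is missing) are flagged ND and
    excluded from folds.  Per-line folds are 2^-(mean dCt(line) - mean
    dCt(reference)), so the reference line's fold is exactly 1.
    """
    for col in ("sample", "line", target, housekeeping):
        if col not in ct.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    if reference_line not in set(ct["line"]):
        raise ValueError(f"reference line {reference_line!r} absent from the table")
    df = ct.copy()
    nd = df[target].isna() | (df[target] >= cycle_cap) | ~np.isfinite(df[target])
    if df[housekeeping].isna().any() or (~np.isfinite(df[housekeeping])).any():
        raise ValueError("housekeeping Ct values must all be finite")
    df["nd"] = nd
    df["dct"] = df[target] - df[housekeeping]
    detected = df[~nd]
    ref = detected[detected["line"] == reference_line]
    if len(ref) == 0:
        raise ValueError(f"no detected samples in reference line {reference_line!r}")
    ref_dct = ref["dct"].mean()
    df["fold"] = np.where(nd, np.nan, 2.0 ** (-(df["dct"] - ref_dct)))
    line_means = detected.groupby("line")["dct"].mean()
    line_folds = 2.0 ** (-(line_means - ref_dct))
    samples = df[["sample", "line", target, housekeeping, "dct", "fold", "nd"]]
    return ExpressionTable(samples, line_folds, reference_line,
                           list(df.loc[nd, "sample"]))


def expression_phenotype_correlation(folds, line_trait_means) -> float:
    """Pearson r between per-line expression folds and per-line trait means.

    Inputs may be dicts/Series keyed by line (aligned on shared lines) or
    plain aligned sequences; at least 3 lines are required.
    """
    if isinstance(folds, (dict, pd.Series)) and isinstance(line_trait_means, (dict, pd.Series)):
        f = pd.Series(folds, dtype=float)
        t = pd.Series(line_trait_means, dtype=float)
        shared = f.index.intersection(t.index)
        f, t = f.loc[shared].to_numpy(), t.loc[shared].to_numpy()
    else:
        f = np.asarray(list(folds), dtype=float)
        t = np.asarray(list(line_trait_means), dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 lines for a correlation")
    return pearson_r(f, t)


@dataclass
class LocusCountWindow:
    """Genes overlapping a window with raw counts and expressed flags.

    ``signed_count`` reports minus-strand genes on a negative axis, the
    convention used for strand-split locus plots.
    """

    table: pd.DataFrame          # gene, strand, start, end, count,
                                 # signed_count, expressed
    center_bp: int
    half_width_bp: int
    expressed_min: int


def locus_expression_window(counts: pd.DataFrame, annotation: pd.DataFrame,
                            center_bp: int, half_width_bp: int,
                            expressed_min: int = 10) -> LocusCountWindow:
    """Genes overlapping [center - half_width, center + half_width] with
    their raw counts and an expressed flag (count >= expressed_min).

    ``counts`` needs columns gene, count; ``annotation`` needs gene, strand,
    start, end.  An empty window yields an empty table, not an error.
    """
    merged = annotation.merge(counts[["gene", "count"]], on="gene", how="inner")
    lo, hi = center_bp - half_width_bp, center_bp + half_width_bp
    win = merged[(merged["end"] >= lo) & (merged["start"] <= hi)].copy()
    if (win["count"] < 0).any():
        raise ValueError("raw counts must be non-negative")
    win["signed_count"] = np.where(win["strand"] == "-", -win["count"], win["count"])
    win["expressed"] = win["count"] >= expressed_min
    win = win[["gene", "strand", "start", "end", "count", "signed_count",
               "expressed"]].reset_index(drop=True)
    return LocusCountWindow(win, center_bp, half_width_bp, expressed_min)
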