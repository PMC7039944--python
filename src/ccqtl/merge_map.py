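"""Merge analysis: imputed-variant fine mapping within QTL intervals.

A biallelic variant segregating among the eight CC founders is "merged"
through each line's haplotype mosaic: the imputed dosage is twice the
probability-weighted alternate-allele count at the nearest marker.  Testing
the dosage (1 df) against the covariate null and comparing its logP with the
local 7-df haplotype logP separates variants whose strain distribution
pattern (SDP) matches the causal founder grouping — these gain power and
score above the haplotype test — from loci whose effects no catalogued SDP
can express.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cc_synth import CCCohort, DescentProbs, FounderPanel, N_FOUNDERS, InvalidParameterError
from .hap_scan import ScanResult
from .pheno_stats import LOGP_CAP, design_matrix


@dataclass
class VariantCatalogue:
    """Biallelic founder variants: positions, ref/alt and 8-founder SDPs."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sdp: np.ndarray              # (n_variants, 8) of 0/1
    founders: tuple[str, ...]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.sdp = np.asarray(self.sdp, dtype=np.int8)
        if self.sdp.shape != (len(self.pos_bp), N_FOUNDERS):
            raise InvalidParameterError("SDP matrix must be (n_variants, 8)")
        for c in pd.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise InvalidParameterError(f"variants unsorted on chromosome {c}")

    def __len__(self) -> int:
        return len(self.pos_bp)

    @property
    def monomorphic(self) -> np.ndarray:
        s = self.sdp.sum(axis=1)
        return (s == 0) | (s == N_FOUNDERS)

    def sdp_strings(self) -> list[str]:
        return ["".join(str(int(b)) for b in row) for row in self.sdp]


def simulate_variant_catalogue(panel: FounderPanel, n_variants: int,
                               seed: int = 0) -> VariantCatalogue:
    """Random polymorphic variants placed uniformly within the marker map."""
    rng = np.random.default_rng(seed)
    chroms = panel.chromosomes
    rows = []
    for _ in range(n_variants):
        c = chroms[rng.integers(len(chroms))]
        span = panel.pos_bp[panel.chrom == c]
        pos = int(rng.integers(span.min(), span.max() + 1))
        k = int(rng.integers(1, N_FOUNDERS))
        sdp = np.zeros(N_FOUNDERS, dtype=np.int8)
        sdp[rng.choice(N_FOUNDERS, size=k, replace=False)] = 1
        rows.append((c, pos, sdp))
    rows.sort(key=lambda r: (str(r[0]), r[1]))
    bases = np.array(list("ACGT"))
    refalt = [rng.choice(4, size=2, replace=False) for _ in rows]
    return VariantCatalogue(
        chrom=np.array([r[0] for r in rows]),
        pos_bp=np.array([r[1] for r in rows]),
        ref=bases[[ra[0] for ra in refalt]],
        alt=bases[[ra[1] for ra in refalt]],
        sdp=np.stack([r[2] for r in rows]),
        founders=panel.founder_names,
    )


@dataclass
class MergeResult:
    """Per-variant merge statistics paired with the local haplotype logP."""

    table: pd.DataFrame          # chrom, pos_bp, ref, alt, sdp, merge_logP,
                                 # hap_logP, candidate
    dosages: np.ndarray          # (n_lines, n_variants tested)
    lines: list[str]
    n_dropped_zero_variance: int = 0


def impute_dosages(catalogue: VariantCatalogue, descent: DescentProbs
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Impute per-line alt-allele dosages through the founder mosaic.

    dosage(line, v) = 2 * sum_s P(line from founder s at v) * allele_s(v),
    with the nearest marker's probabilities standing in for position v.
    Returns (dosage matrix (n_lines, n_kept), kept variant indices); variants
    outside the marker-map span of their chromosome are skipped with a
    warning.
    """
    kept = []
    nearest = []
    for i in range(len(catalogue)):
        c, p = catalogue.chrom[i], int(catalogue.pos_bp[i])
        on = np.flatnonzero(descent.chrom == str(c))
        if len(on) == 0 or not (descent.pos_bp[on].min() <= p <= descent.pos_bp[on].max()):
            continue
        kept.append(i)
        nearest.append(descent.nearest_marker(c, p))
    if len(kept) < len(catalogue):
        warnings.warn(f"{len(catalogue) - len(kept)} variant(s) outside the "
                      "marker map span were skipped", stacklevel=2)
    kept = np.asarray(kept, dtype=int)
    nearest = np.asarray(nearest, dtype=int)
    P = descent.probs[:, nearest, :]                       # (L, V, 8)
    D = 2.0 * np.einsum("lvf,vf->lv", P, catalogue.sdp[kept].astype(float))
    return np.clip(D, 0.0, 2.0), kept


def merge_scan(cohort: CCCohort, catalogue: VariantCatalogue,
               hap_scan_result: ScanResult, trait: str,
               covariates: list[str] = (),
               descent: DescentProbs | None = None) -> MergeResult:
    """Test imputed dosages against the phenotype and flag candidates.

    merge logP is the 1-df partial F-test adding the mouse-level dosage to
    the covariate null; the haplotype logP is read off the scan at the
    variant's nearest marker; the candidate flag is set where the merge test
    is the stronger of the two.  Zero-variance dosages are dropped and
    counted.
    """
    descent = descent or cohort.descent
    if descent is None:
        raise ValueError("descent probabilities are required")
    D, kept = impute_dosages(catalogue, descent)
    df = cohort.mice
    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    line_pos = {l: i for i, l in enumerate(descent.lines)}
    midx = df["line"].map(line_pos).to_numpy()
    Dm = D[midx, :]                                        # (n_mice, V)

    X0 = design_matrix(df, list(covariates))
    from scipy.linalg import orth
    Q0 = orth(X0)
    rank0 = Q0.shape[1]
    My = y - Q0 @ (Q0.T @ y)
    rss0 = float(My @ My)
    Dr = Dm - Q0 @ (Q0.T @ Dm)
    norms = (Dr ** 2).sum(axis=0)
    nonzero = norms > 1e-12
    n_dropped = int((~nonzero).sum())

    ssr = np.zeros(D.shape[1])
    ssr[nonzero] = (Dr[:, nonzero].T @ My) ** 2 / norms[nonzero]
    rss1 = np.maximum(rss0 - ssr, 0.0)
    df2 = n - rank0 - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssr / (rss1 / df2)
        logp = -np.log10(stats.f.sf(f, 1, df2))
    logp = np.where(rss1 <= 1e-12 * max(rss0, 1e-300), LOGP_CAP, logp)
    logp = np.minimum(np.nan_to_num(logp, nan=0.0, posinf=LOGP_CAP), LOGP_CAP)

    hap_lp = np.empty(D.shape[1])
    for j, vi in enumerate(kept):
        m = np.argmin(np.where(hap_scan_result.chrom == str(catalogue.chrom[vi]),
                               np.abs(hap_scan_result.pos_bp - catalogue.pos_bp[vi]),
                               np.inf))
        hap_lp[j] = hap_scan_result.logp[int(m)]

    mask = nonzero
    table = pd.DataFrame({
        "chrom": catalogue.chrom[kept][mask],
        "pos_bp": catalogue.pos_bp[kept][mask],
        "ref": np.asarray(catalogue.ref)[kept][mask],
        "alt": np.asarray(catalogue.alt)[kept][mask],
        "sdp": np.array(catalogue.sdp_strings())[kept][mask],
        "merge_logP": logp[mask],
        "hap_logP": hap_lp[mask],
    })
    table["candidate"] = table["merge_logP"] > table["hap_logP"]
    return MergeResult(table.reset_index(drop=True), D[:, mask],
                       list(descent.lines), n_dropped)


@dataclass
class GeneRanking:
    table: pd.DataFrame          # gene, chrom, start, end, best_merge_logP,
                                 # n_variants, ambiguous


def shortlist_candidates(merge: MergeResult, window: tuple,
                         annotation: pd.DataFrame) -> GeneRanking:
    """Rank genes in a window by their best merge logP.

    ``window`` is (chrom, start bp, end bp); ``annotation`` needs columns
    gene, chrom, start, end (1-based closed).  Variants inside a gene are
    assigned to it; intergenic variants go to the nearest gene, or to both
    and are flagged ambiguous when exactly equidistant.
    """
    chrom, wstart, wend = str(window[0]), int(window[1]), int(window[2])
    if wend < wstart:
        return GeneRanking(pd.DataFrame(
            columns=["gene", "chrom", "start", "end", "best_merge_logP",
                     "n_variants", "ambiguous"]))
    t = merge.table
    inwin = t[(t["chrom"].astype(str) == chrom)
              & (t["pos_bp"] >= wstart) & (t["pos_bp"] <= wend)]
    genes = annotation[annotation["chrom"].astype(str) == chrom].reset_index(drop=True)
    best: dict[str, float] = {}
    nvar: dict[str, int] = {}
    ambiguous: set[str] = set()
    for _, v in inwin.iterrows():
        pos, lp = int(v["pos_bp"]), float(v["merge_logP"])
        inside = genes[(genes["start"] <= pos) & (pos <= genes["end"])]
        if len(inside):
            targets = list(inside["gene"])
        else:
            d = np.where(pos < genes["start"], genes["start"] - pos,
                         np.where(pos > genes["end"], pos - genes["end"], 0))
            if len(d) == 0:
                continue
            dmin = d.min()
            targets = list(genes.loc[d == dmin, "gene"])
            if len(targets) > 1:
                ambiguous.update(targets)
        for g in targets:
            best[g] = max(best.get(g, -np.inf), lp)
            nvar[g] = nvar.get(g, 0) + 1
    rows = []
    for g, lp in best.items():
        grow = genes[genes["gene"] == g].iloc[0]
        rows.append({"gene": g, "chrom": chrom, "start": int(grow["start"]),
                     "end": int(grow["end"]), "best_merge_logP": lp,
                     "n_variants": nvar[g], "ambiguous": g in ambiguous})
    out = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                      "best_merge_logP", "n_variants", "ambiguous"])
    out = out.sort_values(["best_merge_logP", "gene"],
                          ascending=[False, True]).reset_index(drop=True)
    return GeneRanking(out)
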