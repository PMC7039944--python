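"""Synthetic Collaborative Cross cohorts.

The Collaborative Cross (CC) is a panel of recombinant inbred mouse lines,
each an (almost) homozygous mosaic of eight founder genomes.  This module
generates cohorts with the statistical structure the downstream mapping
assumes: a biallelic founder panel on a marker map, per-line haplotype
mosaics with residual heterozygosity, founder-descent probability matrices,
and replicated phenotypes with covariate shifts, planted QTLs, line effects
of a chosen broad-sense heritability, and i.i.d. residual noise.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical CC founder strains, fixed order used everywhere in the package.
FOUNDERS: tuple[str, ...] = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/LtJ",
    "NZO/HiLtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)
N_FOUNDERS = 8
REFERENCE_FOUNDER = "WSB/EiJ"

#: the seven experimental covariates recorded per mouse
COVARIATES: tuple[str, ...] = (
    "sex", "age_weeks", "batch", "month", "season", "year", "experimenter",
)

#: default µCT trait set (units: %, mm^-1, µm, mm^-3, -, mm, mgHA/cm^3, mm)
TRAITS: tuple[str, ...] = (
    "BV/TV", "Tb.N", "Tb.Th", "Conn.D", "SMI", "Tb.Sp", "vBMD", "Ct.Th",
)

#: trait grand means used as simulation baselines (cohort-scale values)
TRAIT_MEANS: dict[str, float] = {
    "BV/TV": 10.2, "Tb.N": 2.7, "Tb.Th": 47.0, "Conn.D": 104.2,
    "SMI": 2.3, "Tb.Sp": 0.33, "vBMD": 581.1, "Ct.Th": 0.2,
}

DEFAULT_MARKER_SPACING_BP = 500_000


class InvalidParameterError(ValueError):
    """Raised when a simulation parameter is outside its admissible range."""


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """Eight founder genomes: a marker map plus biallelic alleles.

    Attributes
    ----------
    founder_names : names of the 8 founders, canonical order.
    chrom : per-marker chromosome label.
    pos_bp : per-marker position, bp, 1-based, strictly increasing within a
        chromosome.
    alleles : (n_markers, 8) 0/1 matrix, 0 = reference allele.
    """

    founder_names: tuple[str, ...]
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        if len(self.founder_names) != N_FOUNDERS:
            raise InvalidParameterError("a founder panel has exactly 8 founders")
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.pos_bp), N_FOUNDERS):
            raise InvalidParameterError("alleles must be (n_markers, 8)")
        for c in self.chromosomes:
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise InvalidParameterError(
                    f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.pos_bp)

    @property
    def chromosomes(self) -> list:
        seen: list = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean mask of markers where all founders share one allele."""
        s = self.alleles.sum(axis=1)
        return (s == 0) | (s == N_FOUNDERS)

    def allele_frequency(self) -> np.ndarray:
        """Founder-level alternate-allele frequency per marker."""
        return self.alleles.mean(axis=1)


def simulate_founder_panel(
    n_chrom: int,
    n_markers_per_chrom: int,
    maf_range: tuple[float, float] = (0.1, 0.4),
    seed: int = 0,
    marker_spacing_bp: int = DEFAULT_MARKER_SPACING_BP,
) -> FounderPanel:
    """Draw a biallelic founder panel on an evenly spaced marker map.

    At each marker the number of alternate-allele founders is drawn uniformly
    among the counts k whose minor-allele frequency min(k, 8-k)/8 lies inside
    ``maf_range``; the carrying founders are then drawn uniformly.

    Parameters
    ----------
    n_chrom, n_markers_per_chrom : map dimensions (markers every
        ``marker_spacing_bp`` bp starting at one spacing).
    maf_range : closed interval of admissible founder minor-allele
        frequencies, within (0, 0.5].
    """
    if n_markers_per_chrom < 2:
        raise InvalidParameterError("need at least 2 markers per chromosome")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise InvalidParameterError(f"empty or invalid maf_range {maf_range!r}")
    valid_k = [k for k in range(1, N_FOUNDERS)
               if lo <= min(k, N_FOUNDERS - k) / N_FOUNDERS <= hi]
    if not valid_k:
        raise InvalidParameterError(
            f"maf_range {maf_range!r} admits no allele count out of 8 founders")

    rng = np.random.default_rng(seed)
    n_total = n_chrom * n_markers_per_chrom
    chrom = np.repeat([str(c + 1) for c in range(n_chrom)], n_markers_per_chrom)
    pos = np.tile(
        (np.arange(n_markers_per_chrom) + 1) * marker_spacing_bp, n_chrom
    ).astype(np.int64)
    alleles = np.zeros((n_total, N_FOUNDERS), dtype=np.int8)
    ks = rng.choice(valid_k, size=n_total)
    for m in range(n_total):
        carriers = rng.choice(N_FOUNDERS, size=ks[m], replace=False)
        alleles[m, carriers] = 1
    return FounderPanel(FOUNDERS, chrom, pos, alleles)


# ---------------------------------------------------------------------------
# haplotype mosaics and descent probabilities
# ---------------------------------------------------------------------------

@dataclass
class MosaicGenome:
    """One line's founder mosaic.

    ``segments`` is a list of (chromosome, start bp, end bp, founder_a,
    founder_b) closed intervals tiling each chromosome; homozygous segments
    have founder_a == founder_b, residually heterozygous segments carry two
    founders at probability one half each.
    """

    segments: list[tuple]
    residual_het_fraction: float


@dataclass
class DescentProbs:
    """Founder-descent probability matrices for a set of lines.

    probs has shape (n_lines, n_markers, 8); every row sums to one.
    """

    lines: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    founders: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.probs.shape != (len(self.lines), len(self.pos_bp), N_FOUNDERS):
            raise InvalidParameterError("probs must be (n_lines, n_markers, 8)")
        if np.any(self.probs < 0):
            raise InvalidParameterError("negative descent probability")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-9)[0]
            raise InvalidParameterError(
                f"descent probabilities for line {self.lines[bad[0]]} at marker "
                f"{self.chrom[bad[1]]}:{self.pos_bp[bad[1]]} sum to "
                f"{sums[bad[0], bad[1]]!r}, not 1")

    @property
    def n_markers(self) -> int:
        return len(self.pos_bp)

    def marker_index(self, chrom, pos_bp: int) -> int:
        """Exact marker lookup; raises KeyError if absent."""
        hit = np.flatnonzero((self.chrom == str(chrom)) & (self.pos_bp == pos_bp))
        if len(hit) == 0:
            raise KeyError(f"no marker at {chrom}:{pos_bp}")
        return int(hit[0])

    def nearest_marker(self, chrom, pos_bp: int) -> int:
        """Index of the nearest marker on ``chrom`` (ties go left)."""
        on = np.flatnonzero(self.chrom == str(chrom))
        if len(on) == 0:
            raise KeyError(f"no markers on chromosome {chrom}")
        d = np.abs(self.pos_bp[on].astype(np.int64) - int(pos_bp))
        return int(on[np.argmin(d)])


def simulate_cc_lines(
    panel: FounderPanel,
    n_lines: int,
    expected_segments_per_chrom: float = 8.0,
    residual_het: float = 0.15,
    prob_sharpness: float = 0.95,
    seed: int = 0,
) -> tuple[list[MosaicGenome], DescentProbs]:
    """Simulate inbred-line mosaics and their descent-probability matrices.

    Per chromosome the breakpoint count is Poisson(expected_segments-1),
    breakpoints uniform, and each segment's founder is uniform over the
    eight.  A segment is residually heterozygous (two founders at one half
    each) with probability ``residual_het``, emulating incomplete inbreeding
    (the CC lines are 80-90% homozygous).  The emitted probabilities are the
    mosaic's exact descent mixed with uniform noise,
    ``(1-eps)*mosaic + eps/8`` with ``eps = 1 - prob_sharpness``, standing in
    for haplotype-reconstruction uncertainty.
    """
    if n_lines < 1:
        raise InvalidParameterError("n_lines must be >= 1")
    if not 0.0 <= prob_sharpness <= 1.0:
        raise InvalidParameterError("prob_sharpness must lie in [0, 1]")
    if not 0.0 <= residual_het <= 0.2:
        raise InvalidParameterError("residual_het must lie in [0, 0.2]")
    if expected_segments_per_chrom < 1:
        raise InvalidParameterError("expected_segments_per_chrom must be >= 1")

    rng = np.random.default_rng(seed)
    chroms = panel.chromosomes
    eps = 1.0 - prob_sharpness

    mosaics: list[MosaicGenome] = []
    probs = np.empty((n_lines, panel.n_markers, N_FOUNDERS))
    for li in range(n_lines):
        segments: list[tuple] = []
        het_len = 0
        tot_len = 0
        base = np.zeros((panel.n_markers, N_FOUNDERS))
        for c in chroms:
            on = np.flatnonzero(panel.chrom == c)
            length = int(panel.pos_bp[on].max())
            n_break = rng.poisson(expected_segments_per_chrom - 1.0)
            cuts = np.sort(rng.integers(2, length, size=n_break)) if n_break else np.array([], dtype=int)
            bounds = np.concatenate(([1], cuts, [length + 1]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                start, end = int(s), int(e) - 1
                if end < start:
                    continue
                fa = int(rng.integers(N_FOUNDERS))
                if rng.random() < residual_het:
                    fb = int((fa + 1 + rng.integers(N_FOUNDERS - 1)) % N_FOUNDERS)
                    het_len += end - start + 1
                else:
                    fb = fa
                tot_len += end - start + 1
                segments.append((c, start, end, fa, fb))
                inside = on[(panel.pos_bp[on] >= start) & (panel.pos_bp[on] <= end)]
                base[inside, fa] += 0.5
                base[inside, fb] += 0.5
        mosaics.append(MosaicGenome(segments, het_len / tot_len if tot_len else 0.0))
        probs[li] = (1.0 - eps) * base + eps / N_FOUNDERS

    lines = [f"CC{li + 1:03d}" for li in range(n_lines)]
    descent = DescentProbs(lines, panel.chrom, panel.pos_bp, panel.founder_names, probs)
    return mosaics, descent


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class QTLSpec:
    """A planted quantitative trait locus.

    Haplotype mode: ``founder_effects`` gives 8 additive values applied
    through the descent probabilities.  Variant mode: ``sdp`` is the 8-bit
    strain distribution pattern and ``effect_size`` the per-alt-dose effect.
    ``variance_explained`` is the target fraction of the line-level genetic
    variance; when None the raw effects are used verbatim.
    """

    chrom: str
    pos_bp: int
    founder_effects: np.ndarray | None = None
    sdp: np.ndarray | None = None
    effect_size: float = 1.0
    variance_explained: float | None = None

    def __post_init__(self) -> None:
        if (self.founder_effects is None) == (self.sdp is None):
            raise InvalidParameterError(
                "exactly one of founder_effects / sdp must be given")
        if self.variance_explained is not None and not 0.0 <= self.variance_explained < 1.0:
            raise InvalidParameterError("variance_explained must lie in [0, 1)")
        if self.sdp is not None:
            self.sdp = np.asarray(self.sdp, dtype=np.int8)
            if self.sdp.shape != (N_FOUNDERS,):
                raise InvalidParameterError("SDP must have 8 entries")
            if self.sdp.sum() in (0, N_FOUNDERS):
                raise InvalidParameterError("SDP must not be monomorphic")
        if self.founder_effects is not None:
            self.founder_effects = np.asarray(self.founder_effects, dtype=float)
            if self.founder_effects.shape != (N_FOUNDERS,):
                raise InvalidParameterError("founder_effects must have 8 entries")

    @property
    def mode(self) -> str:
        return "haplotype-effect" if self.founder_effects is not None else "variant-effect"

    def line_values(self, descent: DescentProbs) -> np.ndarray:
        """Per-line genetic value at the nearest marker to the QTL."""
        try:
            m = descent.marker_index(self.chrom, self.pos_bp)
        except KeyError:
            m = descent.nearest_marker(self.chrom, self.pos_bp)
            warnings.warn(
                f"QTL position {self.chrom}:{self.pos_bp} is not on the marker "
                f"map; using nearest marker {descent.chrom[m]}:{descent.pos_bp[m]}",
                stacklevel=2)
        P = descent.probs[:, m, :]
        if self.founder_effects is not None:
            return P @ self.founder_effects
        return self.effect_size * 2.0 * (P @ self.sdp.astype(float))


@dataclass
class CohortDesign:
    """Replicate structure and covariate levels for a simulated cohort."""

    replicates_per_line: int = 5
    covariate_levels: dict = field(default_factory=lambda: {
        "sex": ["F", "M"],
        "age_weeks": [9, 10, 11, 12, 13],
        "batch": [f"B{i:02d}" for i in range(1, 11)],
        "month": list(range(1, 13)),
        "season": ["winter", "spring", "summer"],
        "year": [1, 2, 3],
        "experimenter": ["E1", "E2"],
    })


@dataclass
class CCCohort:
    """Replicated mice over CC lines: covariates, traits, descent.

    ``mice`` is a DataFrame with columns mouse_id, line, the seven covariates
    and one column per trait; ``descent`` holds per-line founder-descent
    probabilities (may be None for phenotype-only cohorts).
    """

    mice: pd.DataFrame
    descent: DescentProbs | None = None

    def __post_init__(self) -> None:
        if "line" not in self.mice.columns:
            raise InvalidParameterError("cohort table must have a 'line' column")
        if self.descent is not None:
            known = set(self.descent.lines)
            missing = set(self.mice["line"]) - known
            if missing:
                raise InvalidParameterError(
                    f"mice reference lines without descent data: {sorted(missing)}")

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.mice["line"]))

    @property
    def traits(self) -> list[str]:
        reserved = {"mouse_id", "line", *COVARIATES}
        return [c for c in self.mice.columns if c not in reserved]

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.mice.columns:
            raise KeyError(f"unknown trait {trait!r}")
        return self.mice[trait]

    def replicates_per_line(self) -> pd.Series:
        return self.mice.groupby("line", sort=False).size()


def simulate_phenotypes(
    design: CohortDesign,
    descent: DescentProbs | None,
    qtls: list[QTLSpec] = (),
    h2_line: float = 0.6,
    covariate_effects: dict | None = None,
    trait: str = "BV/TV",
    mu: float | None = None,
    sigma_e: float = 1.0,
    seed: int = 0,
    n_lines: int = 34,
) -> CCCohort:
    """Simulate a replicated single-trait cohort.

    The mouse-level model is

        y_ij = mu + covariate shifts + sum_q g_q(line i) + u_i + e_ij

    with line effect u_i ~ N(0, sigma_L^2), residual e_ij ~ N(0, sigma_e^2)
    and sigma_G^2 = sigma_L^2 + var(QTL terms) chosen so that
    sigma_G^2 / (sigma_G^2 + sigma_e^2) = h2_line on the single-mouse scale.
    QTLs with a ``variance_explained`` target are centred and rescaled to
    their share of sigma_G^2 (sample variance over lines); QTLs without one
    contribute their raw effects outside this budget.

    ``covariate_effects`` maps a covariate name to {level: shift}, or a pair
    of covariate names to {(level_a, level_b): shift} for an interaction.
    """
    if not 0.0 <= h2_line < 1.0:
        raise InvalidParameterError("h2_line must lie in [0, 1)")
    if sigma_e < 0:
        raise InvalidParameterError("sigma_e must be >= 0")
    qtls = list(qtls)
    ves = [q.variance_explained for q in qtls if q.variance_explained is not None]
    if sum(ves) >= 1.0:
        raise InvalidParameterError("QTL variance_explained fractions must sum below 1")
    if ves and sigma_e == 0 and h2_line == 0:
        raise InvalidParameterError(
            "variance_explained targets need a nonzero genetic variance; "
            "pass raw effects (variance_explained=None) in the noiseless limit")
    if qtls and descent is None:
        raise InvalidParameterError("planting QTLs requires descent probabilities")

    rng = np.random.default_rng(seed)
    if descent is not None:
        lines = list(descent.lines)
    else:
        lines = [f"CC{i + 1:03d}" for i in range(n_lines)]
    n_lines = len(lines)
    reps = design.replicates_per_line
    if mu is None:
        mu = TRAIT_MEANS.get(trait, 0.0)

    var_e = sigma_e ** 2
    var_g = h2_line / (1.0 - h2_line) * var_e if h2_line > 0 else 0.0

    # line-level genetic values
    g = np.zeros(n_lines)
    for q in qtls:
        gq = q.line_values(descent)
        if q.variance_explained is not None:
            gq = gq - gq.mean()
            sd = gq.std(ddof=1)
            if sd == 0:
                raise InvalidParameterError(
                    f"planted QTL at {q.chrom}:{q.pos_bp} is degenerate "
                    "(no descent variation across lines)")
            gq = gq / sd * np.sqrt(q.variance_explained * var_g)
        g = g + gq
    var_poly = var_g * (1.0 - sum(ves))
    u = rng.normal(0.0, np.sqrt(var_poly), size=n_lines) if var_poly > 0 else np.zeros(n_lines)

    rows = []
    levels = design.covariate_levels
    for li, line in enumerate(lines):
        for j in range(reps):
            cov = {c: levels[c][rng.integers(len(levels[c]))] for c in COVARIATES}
            shift = 0.0
            if covariate_effects:
                for key, eff in covariate_effects.items():
                    if isinstance(key, tuple):
                        shift += eff.get((cov[key[0]], cov[key[1]]), 0.0)
                    else:
                        shift += eff.get(cov[key], 0.0)
            y = mu + shift + g[li] + u[li] + (rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0)
            rows.append({"mouse_id": f"{line}_m{j + 1}", "line": line, **cov, trait: y})
    mice = pd.DataFrame(rows)
    return CCCohort(mice, descent)


def simulate_correlated_traits(
    design: CohortDesign,
    descent: DescentProbs | None,
    trait_names: list[str],
    line_cov: np.ndarray,
    sigma_e: float = 1.0,
    mus: dict | None = None,
    seed: int = 0,
) -> CCCohort:
    """Multi-trait cohort with user-supplied line-effect covariance.

    Line effects are drawn jointly N(0, line_cov) across traits; residuals
    are independent per trait.  No QTLs or covariate effects are planted.
    """
    line_cov = np.asarray(line_cov, dtype=float)
    k = len(trait_names)
    if line_cov.shape != (k, k):
        raise InvalidParameterError("line_cov must be (n_traits, n_traits)")
    rng = np.random.default_rng(seed)
    lines = list(descent.lines) if descent is not None else [f"CC{i + 1:03d}" for i in range(34)]
    u = rng.multivariate_normal(np.zeros(k), line_cov, size=len(lines))
    mus = mus or {}
    rows = []
    levels = design.covariate_levels
    for li, line in enumerate(lines):
        for j in range(design.replicates_per_line):
            cov = {c: levels[c][rng.integers(len(levels[c]))] for c in COVARIATES}
            vals = {t: mus.get(t, TRAIT_MEANS.get(t, 0.0)) + u[li, ti]
                    + rng.normal(0.0, sigma_e)
                    for ti, t in enumerate(trait_names)}
            rows.append({"mouse_id": f"{line}_m{j + 1}", "line": line, **cov, **vals})
    return CCCohort(pd.DataFrame(rows), descent)
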