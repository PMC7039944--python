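"""Haplotype scan: F-test correctness, thresholds, QTL calling, effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccqtl import (CCCohort, CohortDesign, DescentProbs, FOUNDERS, QTLSpec,
                   ScanEngine, ScanResult, ThresholdSet, allele_group_means,
                   call_qtls, founder_effects, genome_thresholds, regional_h2,
                   scan_trait, simulate_cc_lines, simulate_founder_panel,
                   simulate_phenotypes)
from ccqtl.pheno_stats import LOGP_CAP

from conftest import HAP_4V4


def _tiny_cohort(n_lines=6, reps=3, n_markers=4, seed=0, y=None):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(8), size=(n_lines, n_markers))
    descent = DescentProbs([f"L{i}" for i in range(n_lines)],
                           np.array(["1"] * n_markers),
                           (np.arange(n_markers) + 1) * 1_000_000,
                           FOUNDERS, probs)
    rows = []
    for li in range(n_lines):
        for j in range(reps):
            rows.append({"mouse_id": f"L{li}_m{j}", "line": f"L{li}",
                         "sex": ["F", "M"][j % 2], "age_weeks": 9,
                         "batch": "B1", "month": 1, "season": "w", "year": 1,
                         "experimenter": "E",
                         "y": rng.normal() if y is None else y[li * reps + j]})
    return CCCohort(pd.DataFrame(rows), descent), descent


def _brute_force_logp(cohort, descent, trait, covariates):
    """Independent nested-model F computation: raw lstsq + f tail."""
    df = cohort.mice
    yv = df[trait].to_numpy(dtype=float)
    n = len(yv)
    cols = [np.ones(n)]
    for c in covariates:
        cols.append(pd.get_dummies(df[c].astype(str), drop_first=True,
                                   dtype=float).to_numpy())
    X0 = np.column_stack(cols)
    b0, _, r0, _ = np.linalg.lstsq(X0, yv, rcond=None)
    rss0 = float(((yv - X0 @ b0) ** 2).sum())
    line_idx = df["line"].map({l: i for i, l in enumerate(descent.lines)}).to_numpy()
    out = []
    ref = descent.founders.index("WSB/EiJ")
    keep = [i for i in range(8) if i != ref]
    for m in range(descent.n_markers):
        P = descent.probs[line_idx, m, :][:, keep]
        X1 = np.column_stack([X0, P])
        b1, _, r1, _ = np.linalg.lstsq(X1, yv, rcond=None)
        rss1 = float(((yv - X1 @ b1) ** 2).sum())
        df1, df2 = r1 - r0, n - r1
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
        out.append(min(-np.log10(stats.f.sf(f, df1, df2)), LOGP_CAP))
    return np.array(out)


class TestScan:
    def test_constant_trait_gives_zero_logp(self):
        cohort, descent = _tiny_cohort(y=np.full(18, 3.0))
        s = scan_trait(cohort, descent, "y")
        assert np.all(s.logp == 0.0)

    def test_perfect_fit_hits_cap(self):
        cohort, descent = _tiny_cohort(seed=4)
        m = 1
        line_idx = cohort.mice["line"].map(
            {l: i for i, l in enumerate(descent.lines)}).to_numpy()
        cohort.mice["y"] = descent.probs[line_idx, m, 2]  # one founder's probability
        s = scan_trait(cohort, descent, "y")
        assert s.logp[m] == LOGP_CAP

    @pytest.mark.parametrize("seed,covs", [(0, []), (1, ["sex"]), (2, ["sex"])])
    def test_matches_brute_force_oracle(self, seed, covs):
        cohort, descent = _tiny_cohort(n_lines=8, reps=4, n_markers=5, seed=seed)
        s = scan_trait(cohort, descent, "y", covs)
        oracle = _brute_force_logp(cohort, descent, "y", covs)
        assert np.allclose(s.logp, oracle, atol=1e-8)

    def test_affine_trait_invariance(self):
        cohort, descent = _tiny_cohort(seed=7)
        s1 = scan_trait(cohort, descent, "y")
        cohort.mice["y"] = 3.5 * cohort.mice["y"] - 12.0
        s2 = scan_trait(cohort, descent, "y")
        assert np.allclose(s1.logp, s2.logp, atol=1e-9)

    def test_monomorphic_descent_marker_is_degenerate(self):
        cohort, descent = _tiny_cohort(seed=8)
        descent.probs[:, 0, :] = 0.0
        descent.probs[:, 0, 3] = 1.0  # every line from the same founder
        s = scan_trait(cohort, descent, "y")
        assert s.degenerate[0]
        assert s.logp[0] == 0.0


class TestThresholds:
    def test_cutoff_ordering(self, null_cohort, small_descent):
        th = genome_thresholds(null_cohort, small_descent, "BV/TV",
                               n_sim=50, seed=1)
        assert th.cutoffs[99] >= th.cutoffs[95] >= 0

    def test_single_marker_threshold_matches_pointwise_f_tail(self):
        # one marker: permutation 95th/99th percentile ~ -log10 of the
        # matching F-distribution tail quantile (p uniform pointwise)
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(8) * 0.3, size=(34, 1))
        descent = DescentProbs([f"CC{i:03d}" for i in range(34)],
                               np.array(["1"]), np.array([1_000_000]),
                               FOUNDERS, probs)
        cohort = simulate_phenotypes(CohortDesign(), descent, [],
                                     h2_line=0.0, seed=1)
        th = genome_thresholds(cohort, descent, "BV/TV", n_sim=1000, seed=2)
        assert th.cutoffs[95] == pytest.approx(-np.log10(0.05), abs=0.25)
        assert th.cutoffs[99] == pytest.approx(-np.log10(0.01), abs=0.6)

    def test_more_markers_never_lower_expected_threshold(self, small_panel):
        panel2 = simulate_founder_panel(2, 60, (0.1, 0.4), seed=11)
        t_small, t_big = [], []
        for r in range(5):
            _, d1 = simulate_cc_lines(small_panel, 34, 6, 0.1, 0.95, seed=50 + r)
            _, d2 = simulate_cc_lines(panel2, 34, 6, 0.1, 0.95, seed=50 + r)
            c1 = simulate_phenotypes(CohortDesign(), d1, [], 0.6, seed=60 + r)
            c2 = simulate_phenotypes(CohortDesign(), d2, [], 0.6, seed=60 + r)
            t_small.append(genome_thresholds(c1, d1, "BV/TV", n_sim=100,
                                             seed=70 + r).cutoffs[95])
            t_big.append(genome_thresholds(c2, d2, "BV/TV", n_sim=100,
                                           seed=70 + r).cutoffs[95])
        assert np.mean(t_big) >= np.mean(t_small)

    def test_too_few_lines_refused(self):
        cohort, descent = _tiny_cohort(n_lines=4)
        with pytest.raises(ValueError):
            genome_thresholds(cohort, descent, "y", n_sim=30)


class TestPower:
    def test_well_powered_planted_qtl_detected_at_99_threshold(self):
        # QTL holding ~2/3 of line-mean variance in a 34 x 5 cohort is a
        # well-powered design for the 7-df fixed-effects test; detection
        # rate at the 99% permutation threshold should exceed 80%
        det = 0
        R = 100
        for r in range(R):
            panel = simulate_founder_panel(2, 100, (0.1, 0.4), seed=1000 + r)
            _, descent = simulate_cc_lines(panel, 34, 8, 0.1, 0.95,
                                           seed=2000 + r)
            qtl = QTLSpec("1", 25_000_000, founder_effects=HAP_4V4,
                          variance_explained=0.756)
            cohort = simulate_phenotypes(CohortDesign(), descent, [qtl],
                                         h2_line=0.6, seed=3000 + r)
            eng = ScanEngine(cohort, descent, [])
            lp = eng.logp_matrix(cohort.mice["BV/TV"].to_numpy())
            th = genome_thresholds(cohort, descent, "BV/TV", n_sim=200,
                                   seed=4000 + r, engine=eng)
            det += lp.max() >= th.cutoffs[99]
        assert det / R >= 0.8


def _scan_from_vector(logp, pos=None):
    m = len(logp)
    pos = np.asarray(pos if pos is not None else (np.arange(m) + 1) * 500_000)
    z = np.zeros((m, 8))
    return ScanResult("y", np.array(["1"] * m), pos, np.asarray(logp, float),
                      z, z, np.zeros(m, bool), FOUNDERS)


class TestCallQtls:
    def test_all_below_cutoff_empty(self):
        s = _scan_from_vector([1.0, 2.0, 1.5])
        assert call_qtls(s, ThresholdSet({95: 3.0, 99: 4.0}, 100), 99) == []

    def test_single_spike(self):
        s = _scan_from_vector([1.0, 6.0, 1.0])
        calls = call_qtls(s, ThresholdSet({95: 3.0, 99: 5.0}, 100), 99)
        assert len(calls) == 1
        assert calls[0].pos_bp == 1_000_000 and calls[0].logp == 6.0

    def test_two_spikes_with_wide_valley_give_two_calls(self):
        pos = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10]) * 1_000_000
        lp = [6, 1, 1, 1, 1, 1, 1, 1, 1, 7.0]
        calls = call_qtls(_scan_from_vector(lp, pos),
                          ThresholdSet({99: 5.0}, 100), 99)
        assert [(c.pos_bp, c.logp) for c in calls] == [(1_000_000, 6.0),
                                                       (10_000_000, 7.0)]

    def test_narrow_valley_merged_to_one_call(self):
        pos = np.array([1.0, 1.5, 2.0]) * 1_000_000
        lp = [6.0, 1.0, 7.0]
        calls = call_qtls(_scan_from_vector(lp, pos.astype(int)),
                          ThresholdSet({99: 5.0}, 100), 99)
        assert len(calls) == 1 and calls[0].pos_bp == 2_000_000


class TestRegionalH2:
    def test_independent_locus_near_zero(self, null_cohort, small_descent):
        h = regional_h2(null_cohort, small_descent, "BV/TV", [],
                        "1", 15_000_000)
        assert h < 0.35  # chance capture of 7 df on 34 line means

    def test_deterministic_line_means_give_one(self, small_panel):
        _, descent = simulate_cc_lines(small_panel, 20, 1.0, 0.0, 1.0, seed=9)
        qtl = QTLSpec("1", 15_000_000, founder_effects=np.arange(8.0))
        cohort = simulate_phenotypes(CohortDesign(), descent, [qtl],
                                     h2_line=0.0, sigma_e=0.0, seed=10)
        assert regional_h2(cohort, descent, "BV/TV", [], "1", 15_000_000) \
            == pytest.approx(1.0)

    def test_planted_fraction_recovered_on_average(self, small_descent):
        ests = []
        for r in range(60):
            qtl = QTLSpec("1", 15_000_000, founder_effects=HAP_4V4,
                          variance_explained=0.5)
            cohort = simulate_phenotypes(CohortDesign(), small_descent, [qtl],
                                         h2_line=0.6, seed=700 + r)
            ests.append(regional_h2(cohort, small_descent, "BV/TV", [],
                                    "1", 15_000_000))
        # QTL holds 50% of sigma_G^2 = 44% of line-mean variance; the 7-df
        # regression also captures part of the polygenic remainder
        assert abs(np.mean(ests) - 0.5) < 0.1


class TestFounderEffects:
    def test_reference_deviation_is_zero(self, qtl_cohort, small_descent):
        s = scan_trait(qtl_cohort, small_descent, "BV/TV")
        dev = founder_effects(s, "1", 15_000_000)
        ref = dev.founders.index("WSB/EiJ")
        assert dev.deviation[ref] == 0.0 and dev.se[ref] == 0.0

    def test_constant_shift_of_effects_leaves_deviations_unchanged(self):
        s = _scan_from_vector([5.0, 5.0])
        s.effects[0] = np.arange(8.0)
        s.effects[1] = np.arange(8.0) + 100.0
        d0 = founder_effects(s, "1", 500_000)
        d1 = founder_effects(s, "1", 1_000_000)
        assert np.allclose(d0.deviation, d1.deviation)

    def test_planted_effects_recovered_within_two_se(self, small_descent):
        eff = np.array([2.0, 2, 2, 2, 0, 0, 0, 0])
        qtl = QTLSpec("1", 15_000_000, founder_effects=eff)
        cohort = simulate_phenotypes(CohortDesign(replicates_per_line=8),
                                     small_descent, [qtl], h2_line=0.0,
                                     sigma_e=0.3, seed=77)
        s = scan_trait(cohort, small_descent, "BV/TV")
        dev = founder_effects(s, "1", 15_000_000)
        truth = eff - eff[7]
        z = np.abs(dev.deviation - truth) / np.maximum(dev.se, 1e-12)
        z[dev.founders.index(dev.reference)] = 0.0
        assert (z <= 3).all()
        assert (z <= 2).sum() >= 6  # a couple of 2-SE misses tolerated

    def test_unknown_reference_rejected(self, qtl_cohort, small_descent):
        s = scan_trait(qtl_cohort, small_descent, "BV/TV")
        with pytest.raises(KeyError):
            founder_effects(s, "1", 15_000_000, reference="BALB/c")


class TestAlleleGroups:
    def test_single_genotype_no_test(self, null_cohort):
        geno = {l: "C:C" for l in null_cohort.lines}
        res = allele_group_means(null_cohort, "BV/TV", geno)
        assert res.welch is None and set(res.group_means) == {"C:C"}

    def test_planted_variant_separates_homozygote_means(self, small_descent):
        sdp = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        qtl = QTLSpec("1", 15_000_000, sdp=sdp, effect_size=2.0)
        cohort = simulate_phenotypes(CohortDesign(), small_descent, [qtl],
                                     h2_line=0.0, sigma_e=0.5, seed=91)
        m = small_descent.marker_index("1", 15_000_000)
        dose = 2 * small_descent.probs[:, m, :] @ sdp
        geno = {l: ("T:T" if d > 1.5 else "C:C" if d < 0.5 else "C:T")
                for l, d in zip(small_descent.lines, dose)}
        res = allele_group_means(cohort, "BV/TV", geno)
        assert res.group_means["T:T"] > res.group_means["C:C"]
        assert res.welch.p < 1e-6

    def test_permuted_genotypes_give_uniform_p(self):
        # independent mice (no line effects): permuted labels -> uniform P
        cohort = simulate_phenotypes(CohortDesign(), None, [], h2_line=0.0,
                                     seed=95)
        rng = np.random.default_rng(5)
        lines = cohort.lines
        ps = []
        for _ in range(80):
            labels = rng.permutation(["T:T"] * 17 + ["C:C"] * 17)
            res = allele_group_means(cohort, "BV/TV",
                                     dict(zip(lines, labels)))
            ps.append(res.welch.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
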