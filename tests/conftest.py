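import numpy as np
import pytest

from ccqtl import (CohortDesign, DescentProbs, FOUNDERS, QTLSpec,
                   simulate_cc_lines, simulate_founder_panel,
                   simulate_phenotypes)

HAP_4V4 = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])


@pytest.fixture(scope="session")
def small_panel():
    """1 chromosome x 60 markers, 0.5 Mb spacing."""
    return simulate_founder_panel(1, 60, (0.1, 0.4), seed=11)


@pytest.fixture(scope="session")
def small_descent(small_panel):
    _, descent = simulate_cc_lines(small_panel, 34, 6.0, 0.1, 0.95, seed=12)
    return descent


@pytest.fixture(scope="session")
def qtl_cohort(small_descent):
    """34 lines x 5 mice with a strong 4-vs-4 haplotype QTL at 15 Mb."""
    qtl = QTLSpec("1", 15_000_000, founder_effects=HAP_4V4,
                  variance_explained=0.7)
    return simulate_phenotypes(CohortDesign(), small_descent, [qtl],
                               h2_line=0.6, seed=13)


@pytest.fixture(scope="session")
def null_cohort(small_descent):
    """34 lines x 5 mice, line effects but no QTL."""
    return simulate_phenotypes(CohortDesign(), small_descent, [],
                               h2_line=0.6, seed=14)
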