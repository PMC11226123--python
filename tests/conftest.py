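import numpy as np
import pytest

from liabtwin import ConcordanceTable, cell_probabilities

# frozen with an independent inverse-normal routine (R qnorm) before the build
TAU_017 = 0.954165253146194
# frozen independent quadrature value of P(L1>tau, L2>tau), rho=0.5, tau=0.9542
P11_RHO05_TAU09542 = 0.0690067014974794


def exact_table(rho, tau, n, group="same_sex", stratum="all"):
    """Concordance table holding exactly N times the model cell probabilities."""
    p = cell_probabilities(rho, tau)
    return ConcordanceTable(group, stratum, *(pi * n for pi in p))


@pytest.fixture
def paper_design_tables():
    """Exact tables for the two-group twin design at the published scale:
    gamma = 0.74, a2 = 0.57, c2 = 0, prevalence threshold tau = qnorm(0.83)."""
    r_ss = 0.74 * 0.57
    r_os = 0.5 * 0.57
    return [
        exact_table(r_ss, TAU_017, 1e5, group="same_sex"),
        exact_table(r_os, TAU_017, 1e5, group="opposite_sex"),
    ]
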