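"""Shared fixtures: the heavy simulation products are session-scoped."""

import numpy as np
import pytest

from hapscan.simulate import PanelConfig, StratConfig, simulate_panel, stratification_study


@pytest.fixture(scope="session")
def euro_panel():
    """20,000-haplotype, 1 Mb European-demography coalescent panel."""
    return simulate_panel(PanelConfig(seed=5))


@pytest.fixture(scope="session")
def strat_lambdas():
    """Inflation factors at delta = 0.08, mu = 0.08 over 5000 replicates."""
    return stratification_study(StratConfig(delta=0.08, mu=0.08), reps=5000, seed=11)


@pytest.fixture(scope="session")
def strat_null_lambdas():
    """Inflation factors with stratified frequencies but no phenotype shift (mu = 0)."""
    return stratification_study(StratConfig(delta=0.08, mu=0.0), reps=8000, seed=13)


@pytest.fixture(scope="session")
def table1_results(euro_panel):
    """Adjacent-interaction improvement study at both marker spacings."""
    from hapscan.hapfreq import hapfreq_study

    return {
        5: hapfreq_study(euro_panel, n_sets=1000, spacing=5, seed=101),
        20: hapfreq_study(euro_panel, n_sets=1000, spacing=20, seed=102),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
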