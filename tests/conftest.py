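import numpy as np
import pytest

import hfetype as h


@pytest.fixture(scope="session")
def panel():
    return h.default_panel()


@pytest.fixture(scope="session")
def templates(panel):
    return h.build_fixture_templates(panel, seed=1)


@pytest.fixture(scope="session")
def pure_cohort(panel):
    """A clean single-source cohort with random STR genotypes, used for
    stutter characterization."""
    rng = np.random.default_rng(2024)
    tables = []
    for _ in range(250):
        g = h.make_genotype(0, 0, str_alleles=h.random_str_alleles(panel, rng))
        tables.append(h.simulate_sample(panel, g, int(rng.integers(2**31))))
    return tables


@pytest.fixture(scope="session")
def stutter_stats(panel, pure_cohort):
    return h.estimate_stutter_stats(pure_cohort, panel)
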