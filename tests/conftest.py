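import numpy as np
import pytest

from heteroscreen import synthetic_data as sd


@pytest.fixture(scope="session")
def programs():
    """Seven disjoint 50-gene lineage programs."""
    return sd.build_reference_programs(7, 50, 0.0, 2.0, seed=11)


@pytest.fixture(scope="session")
def pure_atlas(programs):
    """One organoid per subtype, 200 cells each, single subpopulation."""
    specs = [
        sd.OrganoidSpec(f"PDO{i + 1:02d}", (sd.SubpopulationSpec("sub1", st, 1.0),))
        for i, st in enumerate(programs.subtype_names)
    ]
    return sd.simulate_atlas(programs, specs, cells_per_organoid=200, seed=21)


@pytest.fixture(scope="session")
def limiting_cohort():
    """Planted cohort where the lowest-expressing clone limits depletion."""
    return sd.simulate_limiting_cohort(seed=31)


@pytest.fixture(scope="session")
def cohort_beta(limiting_cohort):
    """Gene-level beta estimated end-to-end from the planted cohort's counts."""
    from heteroscreen import screen_stats as ss

    co = limiting_cohort
    norm = ss.normalize_counts(co.screens, co.library)
    lfc = ss.guide_lfc(norm, co.library)
    return ss.gene_beta(lfc, co.library, co.doublings)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
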