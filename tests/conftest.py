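import pytest

from chaoscope import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """10 donors x 800 cells: quick but large enough for gating stats."""
    cfg = synthetic.SimulationConfig(
        n_healthy=5, n_patients=5, cells_per_donor=800, seed=42,
        n_expression_cells_per_donor=100,
    )
    return cfg, synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    from chaoscope import gating

    cfg, cohort = small_cohort
    thr = gating.derive_marker_thresholds(cohort.cell_table, seed=0)
    labeled = gating.classify_subsets(cohort.cell_table, thr)
    profiles = gating.subset_frequencies(labeled)
    return cfg, cohort, labeled, profiles
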