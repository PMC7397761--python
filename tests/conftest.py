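import numpy as np
import pytest

from metacov import (
    GroupConfig,
    HierarchicalModelSpec,
    McmcConfig,
    counts_by_subject_task,
    fit_hmetad_multitask,
    simulate_group,
    uniform_correlation,
)


@pytest.fixture(scope="session")
def small_group():
    """A small 2-task group: 15 subjects x 80 trials, rho = 0.5."""
    cfg = GroupConfig(
        n_subjects=15, n_tasks=2, n_trials=80,
        rho=uniform_correlation(2, 0.5), seed=42,
    )
    trials, truth = simulate_group(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def small_posterior(small_group):
    """A quick hierarchical fit of the small group (short chains)."""
    cfg, trials, _ = small_group
    counts = counts_by_subject_task(trials, cfg.n_levels, collapse_to=4)
    return fit_hmetad_multitask(
        counts,
        HierarchicalModelSpec(n_tasks=2),
        McmcConfig(n_chains=2, n_samples=300, n_burnin=250, seed=7),
    )
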