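import numpy as np
import pandas as pd
import pytest

from hostpanel.simcohort import (
    SimConfig,
    build_effect_table,
    default_panel_manifest,
    simulate_study,
)


@pytest.fixture(scope="session")
def panel_manifest():
    return default_panel_manifest()


@pytest.fixture(scope="session")
def effect_table(panel_manifest):
    return build_effect_table(panel_manifest)


@pytest.fixture(scope="session")
def small_study(effect_table):
    """A compact simulated multi-cohort study shared across tests."""
    cfg = SimConfig(
        n_cohorts=4,
        samples_per_class_per_cohort=20,
        n_noise_markers=5,
        seed=42,
    )
    matrix, annotation = simulate_study(cfg, effect_table)
    return matrix, annotation


@pytest.fixture(scope="session")
def split_study(small_study):
    """(X_train, y_train, groups, X_val, y_val) on the normalized scale."""
    from hostpanel.expression_io import normalize_to_housekeepers

    matrix, annotation = small_study
    norm = normalize_to_housekeepers(matrix, ["HKG1", "HKG2", "HKG3"])
    ann = annotation.set_index("sample_id")
    tr = ann.index[ann["split"] == "train"]
    va = ann.index[ann["split"] == "validation"]
    return (
        norm.loc[tr],
        ann.loc[tr, "class"].to_numpy(),
        ann.loc[tr, "cohort_id"].to_numpy(),
        norm.loc[va],
        ann.loc[va, "class"].to_numpy(),
    )
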