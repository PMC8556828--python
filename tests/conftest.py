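import numpy as np
import pandas as pd
import pytest

from emonet import (
    SimConfig,
    StudyDesign,
    build_lagged_design,
    fit_mlvar,
    simulate_panel,
)


@pytest.fixture(scope="session")
def toy_panel_frame():
    """2 subjects x 2 days x 3 slots, all cells present."""
    rows = []
    rng = np.random.default_rng(7)
    for sid in ("a", "b"):
        for day in (1, 2):
            for slot in (1, 2, 3):
                rows.append((sid, day, slot, *rng.uniform(10, 90, 4)))
    from emonet.ema_data import NEGATIVE_EMOTIONS

    return pd.DataFrame(
        rows, columns=["subject_id", "day_index", "slot_index", *NEGATIVE_EMOTIONS]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Moderately sized simulated cohort with full ground truth."""
    cfg = SimConfig(n_subjects=20, seed=42)
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A fitted multilevel VAR on the small cohort (diagonal slopes)."""
    cfg, panel, truth = small_cohort
    design = build_lagged_design(panel, cfg.emotions)
    return cfg, truth, design, fit_mlvar(design, re_structure="diagonal")
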