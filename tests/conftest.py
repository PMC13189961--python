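"""Shared fixtures: synthetic cohorts, window stores, and one trained model.

The "easy" cohort is the package's standard desk-scale recovery benchmark:
20 patients × 450 s, 30% of patients with a deterioration episode, target
window-level imbalance 1:40, precursor intensity 3 (strong, clearly
separable precursors).  Training it once per session keeps the heavier
end-to-end checks (threshold optimality, attribution completeness, score
separation) on a single shared model.
"""

import numpy as np
import pytest

from dsfnet import net, simdata, train, windows

EASY_SEED = 7
SMALL_SEED = 11


@pytest.fixture(scope="session")
def easy_cohort():
    return simdata.simulate_cohort(
        n_patients=20, duration_s=450, end_prevalence=0.3,
        imbalance_target=40.0, seed=EASY_SEED, intensity=3.0)


@pytest.fixture(scope="session")
def easy_split(easy_cohort):
    return windows.split_by_patient(easy_cohort, seed=EASY_SEED)


@pytest.fixture(scope="session")
def easy_store(easy_cohort, easy_split, tmp_path_factory):
    out = tmp_path_factory.mktemp("easy_store")
    return windows.materialize_windows(easy_cohort, easy_split,
                                       windows.WindowConfig(), out)


@pytest.fixture(scope="session")
def trained_state(easy_store, easy_split):
    """One cost-sensitive (ω=160) training run on the easy cohort."""
    tcfg = train.TrainConfig(batch_size=128, max_epochs=4, patience=3,
                             seed=EASY_SEED)
    return train.train_model(easy_store, easy_split, net.ModelConfig(seed=EASY_SEED),
                             tcfg, train.LossConfig(160.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller cohort for paired-training comparisons and k-fold runs."""
    return simdata.simulate_cohort(
        n_patients=12, duration_s=240, end_prevalence=1 / 3,
        imbalance_target=25.0, seed=SMALL_SEED, intensity=3.0)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return windows.split_by_patient(small_cohort, ratios=(8, 2, 2), seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_store(small_cohort, small_split, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_store")
    return windows.materialize_windows(small_cohort, small_split,
                                       windows.WindowConfig(), out)


@pytest.fixture(scope="session")
def omega_pair(small_store, small_split):
    """Paired trainings (same seed/data) at ω=160 vs ω=1; val recalls at τ=0.5."""
    from dsfnet import evaluation
    tcfg = train.TrainConfig(batch_size=128, max_epochs=2, patience=2,
                             seed=SMALL_SEED)
    out = {}
    for omega in (160.0, 1.0):
        state = train.train_model(small_store, small_split,
                                  net.ModelConfig(seed=SMALL_SEED), tcfg,
                                  train.LossConfig(omega))
        preds = train.predict_split(state, small_store, small_split.val_ids)
        out[omega] = evaluation.evaluate_predictions(preds, 0.5)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
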