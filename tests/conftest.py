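import numpy as np
import pytest

import arginylome as ag


@pytest.fixture(scope="session")
def default_dataset():
    """Planted-signal PU dataset at the package's default study conditions."""
    peptides, truth = ag.generate_dataset(n_pos=300, n_unl=600, seed=7)
    return peptides, truth


@pytest.fixture(scope="session")
def default_training_set(default_dataset):
    peptides, _ = default_dataset
    return ag.to_training_set(peptides)


@pytest.fixture(scope="session")
def small_model(default_training_set):
    """A modest ensemble reused across read-only tests."""
    return ag.train_ensemble(default_training_set, n_members=20, seed=7)


@pytest.fixture(scope="session")
def campaign_base():
    """A small literature + designed-array campaign for baseline tests."""
    return ag.generate_campaign(
        n_lit_pos=30, n_lit_unl=150, n_array_per_bin=20, seed=5
    )


def brute_force_auc(scores, labels):
    """All-pairs oracle: P(score_pos > score_neg) with ties counting 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)


def brute_force_kendall_tau_b(x, y):
    """Pair-enumeration oracle for tau-b with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n_pairs = n * (n - 1) / 2
    denom = np.sqrt((n_pairs - ties_x) * (n_pairs - ties_y))
    return (conc - disc) / denom
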