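import numpy as np
import pandas as pd
import pytest

from fcnet import CohortSpec, ConnectivityMatrix, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny paired cohort with a strong planted effect, shared across tests."""
    spec = CohortSpec(
        n_subjects=8,
        n_regions=20,
        n_timepoints=120,
        n_communities=4,
        effect_regions=(1, 2, 3),
        effect_delta_corr=0.3,
        seed=42,
    )
    return generate_cohort(spec)


def random_connectivity(n_regions, rng):
    """A valid random correlation matrix (sample correlation of noise)."""
    X = rng.standard_normal((4 * n_regions, n_regions))
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    labels = [f"R{i}" for i in range(n_regions)]
    return ConnectivityMatrix(values=C, region_labels=labels)


def adjacency_from_edges(n, edges):
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


@pytest.fixture
def metric_table_paired(small_cohort):
    """Stacked metric table for the small cohort over a 2-point grid."""
    from fcnet import compute_connectivity, metric_sweep

    frames = [
        metric_sweep(
            compute_connectivity(ts), [0.2, 0.4], subject_id=subj, session=sess
        )
        for (subj, sess), ts in sorted(small_cohort.timeseries.items())
    ]
    return pd.concat(frames, ignore_index=True)
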