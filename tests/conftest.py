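import numpy as np
import pytest

from adsubtype.cluster import similarity_matrix
from adsubtype.normalization import fit_reference, vertex_zscores
from adsubtype.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_hc=60, n_ads=80, cluster_sizes=(25, 25, 15, 15),
                      n_vertices=300, slope_by_cluster=(0.1, 0.2, 0.3, 0.4),
                      seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_zscores(small_cohort):
    out = {}
    for modality, mat in (("tau", small_cohort.tau),
                          ("atrophy", small_cohort.thickness)):
        ref = fit_reference(mat.loc[small_cohort.hc_ids])
        out[modality] = vertex_zscores(mat.loc[small_cohort.ads_ids], ref)
    return out


@pytest.fixture(scope="session")
def small_similarity(small_zscores):
    return {m: similarity_matrix(z.to_numpy()) for m, z in small_zscores.items()}


@pytest.fixture()
def block_similarity():
    """Planted 4-block similarity matrix (n=80) with its ground-truth labels."""
    rng = np.random.default_rng(0)
    labels = np.repeat(np.arange(4), 20)
    S = np.where(labels[:, None] == labels[None, :], 0.8, 0.1)
    S = S + rng.normal(0, 0.02, S.shape)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S, labels


@pytest.fixture()
def two_triangles():
    """Two disconnected unit-weight triangles."""
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[a, b] = W[b, a] = 1.0
    return W
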