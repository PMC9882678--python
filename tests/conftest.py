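import numpy as np
import pytest

from microdisparity import simulate
from microdisparity.datasets import (CompositionMatrix, MediationDataset,
                                     StudyFrame)


@pytest.fixture(scope="session")
def fixture_config():
    """The reference truth scenario: J=20 taxa, 3 mediating, K=2, n=150/group."""
    return simulate.default_scenario(seed=0)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_config):
    return simulate.generate_dataset(fixture_config, seed=7)


@pytest.fixture
def small_dataset():
    """Tiny balanced dataset (n=80, J=5, K=1) for fast fits."""
    cfg = simulate.default_scenario(n_per_group=40, n_taxa=5, n_covariates=1,
                                    n_mediators=2, seed=11)
    return simulate.generate_dataset(cfg, seed=11)


def make_dataset(M, R, Y, X=None):
    n, J = M.shape
    X = np.empty((n, 0)) if X is None else np.atleast_2d(X)
    comp = CompositionMatrix(values=M, subject_ids=[f"s{i}" for i in range(n)],
                             taxon_ids=[f"t{j}" for j in range(J)])
    frame = StudyFrame(exposure=R, outcome=Y, covariates=X,
                       covariate_names=[f"x{k}" for k in range(X.shape[1])],
                       subject_ids=[f"s{i}" for i in range(n)])
    return MediationDataset(composition=comp, frame=frame)
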