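import numpy as np
import pytest

import qscrosstalk as q


@pytest.fixture(scope="session")
def strains():
    """The packaged five-strain community, in order A-E."""
    return q.table1_params()


@pytest.fixture(scope="session")
def strain_map(strains):
    return {p.strain_id: p for p in strains}


@pytest.fixture(scope="session")
def tester_env():
    return q.EnvironmentParams.tester_default()


@pytest.fixture(scope="session")
def fixture_W():
    return q.fig3d_signs()


@pytest.fixture(scope="session")
def W_AB(fixture_W):
    """2x2 sub-matrix of the packaged weights for the A/B coculture."""
    return q.WeightMatrix(
        ("A", "B"), fixture_W.w[np.ix_([0, 1], [0, 1])]
    )


@pytest.fixture(scope="session")
def W_ABC(fixture_W):
    """3x3 sub-matrix for the A/B coculture with exogenous C signal."""
    return q.WeightMatrix(
        ("A", "B", "C"), fixture_W.w[np.ix_([0, 1, 2], [0, 1, 2])]
    )
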