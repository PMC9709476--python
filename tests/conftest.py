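import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cardiosim import pharmacology as ph
from cardiosim import strand
from cardiosim.surrogate import SurrogateCellParams


@pytest.fixture(scope="session")
def drug_library():
    return ph.load_drug_library()


@pytest.fixture(scope="session")
def surrogate_critical_factory():
    """Factory of homogeneous surrogate strands with a centered EAD-forced
    block, used by the critical-mass protocol tests."""
    def make(count, params=None):
        return strand.build_homogeneous_strand(
            affected_count=count, affected_factors={"I_Kr": 0.5},
            model="surrogate", dt=0.1, rec_dt=0.5, bcl=1500.0, n_beats=1,
            surrogate_params=params or SurrogateCellParams())
    return make


@pytest.fixture(scope="session")
def surrogate_strand_cfg():
    return strand.StrandConfig(model="surrogate", dt=0.1, rec_dt=0.5,
                               bcl=2000.0, n_beats=1)
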