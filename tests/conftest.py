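import numpy as np
import pytest

from arcticpop import synthdata
from arcticpop.core import StrHaplotype


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two Balding-Nichols populations (F=0.1, 50 each, 5000 SNPs)."""
    return synthdata.sim_admixed_genotypes(
        [50, 50], 5000, 2, 0.1, [10.0, 0.05], seed=42)


@pytest.fixture(scope="session")
def admixed_cohort_k2():
    """Admixed cohort at the standard recovery conditions (K=2, F=0.2)."""
    return synthdata.sim_admixed_genotypes(
        [50, 50], 5000, 2, 0.2, [0.5, 0.5], seed=7)


@pytest.fixture
def str_founder():
    return StrHaplotype(("DYS19", "DYS390", "DYS391", "DYS392", "DYS393",
                         "DYS388"), (14, 23, 10, 14, 13, 12))


def align_q(Q, Q_true):
    """Mean |Q - Q_true| under the best column permutation (K=2 or 3)."""
    import itertools
    K = Q.shape[1]
    return min(np.abs(Q[:, perm] - Q_true).mean()
               for perm in itertools.permutations(range(K)))
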