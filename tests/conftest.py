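import numpy as np
import pytest

from rbprofiler import FamilySpec, ScoringScheme, simulate_rbp_families


@pytest.fixture(scope="session")
def blosum():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def toy_scheme():
    """Match +1 / mismatch -1 over a 3-letter alphabet, gaps -5/-2."""
    return ScoringScheme.simple("ABC", match=1, mismatch=-1, gap_open=-5, gap_extend=-2)


@pytest.fixture(scope="session")
def small_family():
    """Three groups (one split into two subgroups) plus one orphan, seed-fixed."""
    spec = FamilySpec(
        n_groups=3, members_per_group=5, subgroup_plan={0: [3, 3]}, n_ungrouped=1, seed=11
    )
    seqs, truth = simulate_rbp_families(spec)
    return spec, seqs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
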