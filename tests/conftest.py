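import numpy as np
import pytest

from cgrfs.event_model import SubjectHistory, derive_all
from cgrfs.simulator import DEFAULT_SPEC, Censoring, IntensitySpec, simulate_cohort


@pytest.fixture
def two_subject_histories():
    """The worked two-subject cohort showing non-monotone recovery."""
    return [
        SubjectHistory("A", t_gvhd1=2.0, t_res1=4.0, t_censor=10.0),
        SubjectHistory("B", t_censor=10.0),
    ]


@pytest.fixture
def two_subject_records(two_subject_histories):
    return derive_all(two_subject_histories)


@pytest.fixture(scope="session")
def benchmark_spec():
    return DEFAULT_SPEC


@pytest.fixture(scope="session")
def small_cohort(benchmark_spec):
    """A 150-subject simulated cohort with events of every kind."""
    return simulate_cohort(benchmark_spec, 150, seed=20240915)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return derive_all(small_cohort)


@pytest.fixture
def no_gvhd_spec():
    """Death/relapse only: every composite endpoint coincides with DFS."""
    return IntensitySpec(rates={(0, 1): 0.4}, censoring=Censoring("uniform", (1.0, 5.0)))


def random_histories(rng: np.random.Generator, n: int) -> list:
    """Directly generated random histories exercising every path depth."""
    out = []
    for i in range(n):
        depth = rng.integers(0, 5)  # how many GVHD events occurred
        times = np.sort(rng.uniform(0.1, 10.0, size=5))
        fields = dict(t_gvhd1=None, t_res1=None, t_gvhd2=None, t_res2=None)
        names = ["t_gvhd1", "t_res1", "t_gvhd2", "t_res2"]
        for j in range(depth):
            fields[names[j]] = float(times[j])
        terminal = float(times[depth]) if depth < 5 else float(times[-1] + 1)
        if rng.random() < 0.5:
            out.append(SubjectHistory(i, t_fail=terminal, **fields))
        else:
            out.append(SubjectHistory(i, t_censor=terminal, **fields))
    return out
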