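import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from coevopool import SimConfig, SyncTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Fast branching-process configuration for unit tests."""
    return SimConfig(n_generations=16, per_division_mutation_rate=2.0, seed=7)


def make_sync(counts, ref=None, pos=None, chrom="chr1", timepoints=None):
    """Helper: build a SyncTable from a (sites, timepoints, 6) count array."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    return SyncTable(
        np.full(n, chrom, dtype=object),
        np.arange(1, n + 1) * 100 if pos is None else np.asarray(pos),
        np.full(n, "A", dtype=object) if ref is None else np.asarray(ref, dtype=object),
        counts,
        list(timepoints) if timepoints is not None else [],
    )
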