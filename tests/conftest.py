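import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from olcorrect.pipeline import make_benchmark, run_pipeline


@pytest.fixture(scope="session")
def benchmark_runs():
    """Full train/correct/assemble runs of the standard benchmark at three
    fixed seeds.  Shared across the acceptance tests; computed lazily so the
    cost is paid once per session."""
    return {seed: run_pipeline(*_benchmark_pair(seed), seed=seed)
            for seed in (1, 2, 3)}


def _benchmark_pair(seed):
    bench = make_benchmark(seed)
    return bench.train, bench.test


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
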