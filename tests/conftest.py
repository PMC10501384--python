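"""Shared fixtures: cached full-pipeline runs on the synthetic benchmark.

The representation learning is the expensive step, so fitted pipelines are
cached per substitution rate and shared across the end-to-end tests.  The
training scale used here (two encoder blocks, 30 epochs, graph refresh every
10 epochs) is the package's documented evaluation setting for the synthetic
benchmark.
"""

import numpy as np
import pytest

from m6atmr import M6ATMR, GcnConfig, SynthConfig, TransformerConfig, generate

SEED = 1
BENCH_M = 1000
BENCH_N = 101

_cache: dict = {}


def fit_pipeline(eps: float, m: int = BENCH_M, seed: int = SEED,
                 epochs: int = 30):
    """Generate one benchmark dataset and fit the full pipeline (cached)."""
    key = (eps, m, seed, epochs)
    if key not in _cache:
        data_seed = (seed + int(1000 * eps) * 7919) % (2 ** 31)
        recs, _ = generate(SynthConfig(m=m, n=BENCH_N, eps=eps, seed=data_seed))
        model = M6ATMR(recs,
                       transformer=TransformerConfig(blocks=2, seed=seed),
                       gcn=GcnConfig(epochs=epochs, refresh_every=10, seed=seed))
        res = model.fit(cv=False)
        y = np.array([r.label for r in recs])
        _cache[key] = (res, y)
    return _cache[key]


@pytest.fixture(scope="session")
def pipeline():
    """Factory fixture: pipeline(eps) -> (fitted results, labels)."""
    return fit_pipeline
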