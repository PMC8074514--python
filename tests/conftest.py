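"""Shared fixtures: a scaled-down synthetic cohort for fast unit tests.

The scaled cohort keeps the six-wave structure, availability pattern and
calibrated marginals of the full design but divides every wave's household
count by five, so fits run in milliseconds.
"""

import copy

import pytest

from assetindex import build_benchmark, default_paper_spec, simulate_external, simulate_panel


def scaled_spec(seed: int = 7, factor: int = 5):
    spec = default_paper_spec(seed=seed)
    for w in spec.waves:
        w.n = max(w.n // factor, 30)
    spec.pool_size = 320
    return spec


@pytest.fixture(scope="session")
def small_spec():
    return scaled_spec()


@pytest.fixture(scope="session")
def small_panel_truth(small_spec):
    return simulate_panel(small_spec, return_truth=True)


@pytest.fixture(scope="session")
def small_panel(small_panel_truth):
    return small_panel_truth[0]


@pytest.fixture(scope="session")
def small_truth(small_panel_truth):
    return small_panel_truth[1]


@pytest.fixture(scope="session")
def small_benchmark(small_panel):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_benchmark(small_panel)


@pytest.fixture(scope="session")
def small_external(small_spec, small_truth):
    return simulate_external(small_spec, small_truth)
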