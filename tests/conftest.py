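import numpy as np
import pytest

from hybridgp import (SimConfig, maf_filter, marker_kernel, canopy_kernel,
                      simulate_nam, standardize_columns, toy_fixture)
from hybridgp.canopy_growth import build_canopy_matrix


@pytest.fixture
def toy():
    """Deterministic 8-line, 10-marker, 6-week dataset."""
    return toy_fixture()


@pytest.fixture
def small_pop():
    """One simulated population (60 lines) with QC applied."""
    cfg = SimConfig(n_families=3, lines_per_family=20, n_markers=120, seed=7)
    g, series, y, truth = simulate_nam(cfg)
    return maf_filter(g, 0.05), series, y, truth


def standardized_blocks(g, series):
    """Standardize marker and (expanded) canopy features for a population."""
    xs = standardize_columns(g.line_ids, g.calls.astype(float))
    canopy = build_canopy_matrix(series)
    cs = standardize_columns(canopy.line_ids, canopy.values)
    return xs, cs


@pytest.fixture
def small_kernels(small_pop):
    g, series, y, _truth = small_pop
    xs, cs = standardized_blocks(g, series)
    return marker_kernel(xs), canopy_kernel(cs), y
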