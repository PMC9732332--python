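import numpy as np
import pytest

from contextmem.pattern_extraction import collect_patterns
from contextmem.study_design import build_t4_schedule, build_word_design, default_contexts
from contextmem.synthetic_data import FmriSimParams, simulate_fmri

#: blob layout that fits small grids used in fast tests
SMALL_BLOBS = (((3, 4, 4), 1.5),)


@pytest.fixture(scope="session")
def contexts():
    return default_contexts()


@pytest.fixture(scope="session")
def design():
    words, assignment = build_word_design(10, 10, 30, "dual", seed=1)
    return words, assignment


@pytest.fixture(scope="session")
def schedule(design, contexts):
    words, assignment = design
    return build_t4_schedule(words, assignment, contexts, n_runs=10, seed=2)


@pytest.fixture(scope="session")
def fmri_default(schedule):
    """One participant's default-geometry dataset (16^3, 10 runs x 330 vols)."""
    return simulate_fmri(FmriSimParams(), schedule, seed=5)


@pytest.fixture(scope="session")
def patterns_default(fmri_default):
    ds = fmri_default
    return collect_patterns(ds.runs, ds.mask, ds.events, ds.tr_seconds)


@pytest.fixture(scope="session")
def searchlight_default(fmri_default, patterns_default):
    """Full radius-4 searchlight on the default dataset (shared: it is the
    expensive step)."""
    from contextmem.searchlight_mvpa import SearchlightConfig, run_searchlight

    X, meta = patterns_default.matrix("imagery")
    acc_map = run_searchlight(
        X, meta["label"], meta["run"], fmri_default.mask, SearchlightConfig()
    )
    return acc_map


def small_fmri_params(**overrides) -> FmriSimParams:
    defaults = dict(grid_shape=(8, 8, 8), signal_blobs=SMALL_BLOBS)
    defaults.update(overrides)
    return FmriSimParams(**defaults)
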