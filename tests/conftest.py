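"""Shared fixtures: synthetic projects and feature matrices.

Session-scoped so the (relatively) expensive semi-Markov simulations are
run once and reused across test modules.
"""

from __future__ import annotations

import pytest

from bseqlab.categories import get_scheme
from bseqlab.features import available_windows, build_features, define_windows
from bseqlab.synth import STRONG_NIGHT_WALK_EFFECT, SimConfig, simulate_project, simulate_tables


def matrix_from_cfg(cfg: SimConfig, scheme_name: str = "berlin",
                    drop_distance: bool = False):
    """Simulate a project in memory and build its full feature matrix."""
    tables, rows, lab = simulate_tables(cfg)
    span = (min(float(t["bintodark"].min()) for t in tables),
            max(float(t["bintodark"].max()) for t in tables) + 1.0)
    windows = available_windows(tables, define_windows(lab, span))
    matrix = build_features(tables, windows, get_scheme(scheme_name),
                            drop_distance=drop_distance)
    return matrix, tables, rows, lab


@pytest.fixture(scope="session")
def null_pipeline():
    """Default two-group cohort with no planted effect."""
    return matrix_from_cfg(SimConfig(seed=7))


@pytest.fixture(scope="session")
def null_matrix(null_pipeline):
    return null_pipeline[0]


@pytest.fixture(scope="session")
def effect_pipeline():
    """Cohort with a strong planted night-activity shift in one group."""
    return matrix_from_cfg(SimConfig(seed=8, effects=STRONG_NIGHT_WALK_EFFECT))


@pytest.fixture(scope="session")
def effect_matrix(effect_pipeline):
    return effect_pipeline[0]


@pytest.fixture(scope="session")
def small_project(tmp_path_factory):
    """A small on-disk project (4 animals/group) for metadata/IO tests."""
    out = tmp_path_factory.mktemp("proj")
    cfg = SimConfig(seed=101, n_per_group=4)
    master = simulate_project(cfg, out)
    return master, cfg
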