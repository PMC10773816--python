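"""Shared fixtures: a small field for unit tests and one full-size
synthetic season (the expensive part) shared across the whole session."""

from __future__ import annotations

import pandas as pd
import pytest

from canopytex.evaluation import stage_feature_tables
from canopytex.synthetic import (
    default_stage_params,
    generate_field_layout,
    generate_season,
)

SEASON_SEED = 11


@pytest.fixture(scope="session")
def stage_params():
    return default_stage_params()


@pytest.fixture(scope="session")
def small_design():
    """A fast 36-plot layout for rendering-level tests."""
    return generate_field_layout(plot_shape_px=(32, 128), buffer_px=4, seed=7)


@pytest.fixture(scope="session")
def season():
    """The default full-size four-stage synthetic campaign."""
    return generate_season(seed=SEASON_SEED)


@pytest.fixture(scope="session")
def season_tables(season):
    """Per-stage full texture feature tables of the default season."""
    tables, n_components = stage_feature_tables(
        season.scenes, season.agb, season.design
    )
    return tables, n_components


@pytest.fixture(scope="session")
def pooled_table(season_tables):
    tables, _ = season_tables
    return pd.concat(tables.values(), ignore_index=True)
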