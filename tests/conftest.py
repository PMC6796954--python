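import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import traitfilter as tf

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> tf.GeneratorConfig:
    return tf.GeneratorConfig()


@pytest.fixture(scope="session")
def small_config() -> tf.GeneratorConfig:
    """A reduced design for fast exercising of the full chain."""
    cfg = tf.GeneratorConfig(
        n_bee_species=40, n_fly_species=20,
        n_bee_individuals=300, n_fly_individuals=150,
    )
    return cfg


@pytest.fixture(scope="session")
def default_table(default_config) -> pd.DataFrame:
    return tf.assemble_dataset(default_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def default_bundle(default_config) -> tf.ResultBundle:
    """One full pipeline run shared by summary-level tests (reduced B)."""
    return tf.run_pipeline(default_config, seed=11, B=300)


def make_table(rows) -> pd.DataFrame:
    """Specimen table from (taxon, species, zone, cup, volume, darkness)."""
    recs = []
    for i, (taxon, sp, zone, cup, vol, dark) in enumerate(rows):
        recs.append({
            "specimen_id": f"x{i:04d}", "taxon": taxon, "species_id": sp,
            "life_zone": zone, "site_id": f"{zone}_site1", "habitat": "meadow",
            "season": "pre_monsoon", "cup_color": "blue",
            "body_volume_mm3": float(vol), "darkness": float(dark),
            "cup_id": cup,
        })
    return pd.DataFrame(recs)
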