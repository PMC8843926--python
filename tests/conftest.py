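import numpy as np
import pandas as pd
import pytest

from mergedchl.matchup import SceneGrid, SatelliteScene
from mergedchl.synthetic import (LakeSpec, RecordSpec, SceneRecipe,
                                 generate_scene_stack, sample_insitu_records,
                                 scene_from_stack)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def demo_recipe():
    # one large resolvable lake, one 2x2 lake that erodes away entirely
    return SceneRecipe(
        shape=(40, 40),
        lakes=(LakeSpec((20, 20), (13, 15), 1), LakeSpec((4, 35), (1.5, 1.5), 2)),
        chla_field=("constant", 20.0),
        dates=("2011-07-01",),
    )


@pytest.fixture
def demo_stack(demo_recipe, rng):
    return generate_scene_stack(demo_recipe, rng)


@pytest.fixture
def demo_scene(demo_recipe, demo_stack):
    return scene_from_stack(demo_stack, 0, demo_recipe.grid(),
                            pd.Timestamp("2011-07-01 17:30", tz="UTC"))


@pytest.fixture
def truth_field(demo_recipe, rng):
    # unmasked truth (defined on land too, for record sampling at any pixel)
    return np.full(demo_recipe.shape, 20.0)


@pytest.fixture
def violation_spec():
    return RecordSpec(frac_wrong_pigment=0.10, frac_deep=0.15,
                      frac_missing_time=0.10, frac_offwindow=0.10,
                      frac_shore=0.05)


@pytest.fixture
def record_table(demo_scene, truth_field, violation_spec):
    gen = np.random.default_rng(777)
    return sample_insitu_records(demo_scene, truth_field, 100,
                                 violation_spec, gen)
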