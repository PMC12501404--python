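import numpy as np
import pandas as pd
import pytest

from imcpatch import synth


@pytest.fixture(scope="session")
def default_pop():
    return synth.default_population()


@pytest.fixture(scope="session")
def small_layout():
    """Small tissue with one follicle and one planted small patch."""
    return synth.TissueLayout(
        width=400,
        height=400,
        follicles=[synth.FollicleSpec(cx=130.0, cy=210.0, radius=55.0)],
        small_patches=[synth.SmallPatchSpec(cx=310.0, cy=220.0, n_cells=15)],
    )


@pytest.fixture(scope="session")
def small_sample(small_layout, default_pop):
    """One fully simulated sample (bundle + ground-truth cells)."""
    bundle, cells, layout_truth = synth.simulate_sample(small_layout, default_pop, seed=7)
    return bundle, cells, layout_truth


def make_cell_table(xy, types, image_id="img", segment=None, **extra):
    """Minimal cell table for graph/interaction/patch tests."""
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(xy) + 1),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "population": list(types),
            "image_id": image_id,
        }
    )
    if segment is not None:
        df["segment"] = list(segment)
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture
def make_cells():
    return make_cell_table
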