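import numpy as np
import pytest

import invasivefront as iv


@pytest.fixture(scope="session")
def rich_field_spec():
    """A field containing every planted object class."""
    return iv.FieldSpec(
        n_buds=3,
        bud_nucleus_counts=[2, 3, 4],
        n_pdc=2,
        pdc_nucleus_counts=[6, 8],
        n_vessels=2,
        lvi_events=[(0, 6), (1, 3)],
        tumor_fraction=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def rich_field(rich_field_spec):
    return iv.generate_field(rich_field_spec)


@pytest.fixture(scope="session")
def rich_hierarchy(rich_field):
    field, _ = rich_field
    return iv.segment_field(field)


@pytest.fixture(scope="session")
def rich_classified(rich_hierarchy):
    return iv.classify_objects(rich_hierarchy)


@pytest.fixture(scope="session")
def small_empty_field():
    """Tumor + stroma only, no planted objects, smaller raster."""
    spec = iv.FieldSpec(image_size_px=(384, 384), tumor_fraction=0.4, seed=11)
    return iv.generate_field(spec)


def make_step_cohort(seed, n=150, n_noise=122, cut=35_647.0, lo=20_000.0, hi=50_000.0):
    """Feature table with one step-function outcome driver among noise columns."""
    rng = np.random.default_rng(seed)
    import pandas as pd

    X = pd.DataFrame(
        rng.normal(size=(n, n_noise)), columns=[f"noise_{i}" for i in range(n_noise)]
    )
    driver = rng.uniform(lo, hi, size=n)
    X["area_pdc_um2"] = driver
    y = (driver > cut).astype(int)
    return X, y
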