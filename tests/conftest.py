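"""Shared fixtures: all test data is generated in-process, no scanner data."""

import numpy as np
import pytest

from mrcoilqa.dicom_io import SliceMeta
from mrcoilqa.synthetic_data import PhantomSpec, make_phantom_series


def meta_factory(spacing=1.5, rows=256, cols=256, **kw) -> SliceMeta:
    defaults = dict(
        pixel_spacing_row=spacing,
        pixel_spacing_col=spacing,
        slice_location=0.0,
        rows=rows,
        cols=cols,
    )
    defaults.update(kw)
    return SliceMeta(**defaults)


@pytest.fixture
def meta15() -> SliceMeta:
    """256x256 slice at 1.5 mm isotropic spacing."""
    return meta_factory()


@pytest.fixture(scope="session")
def weekly_dir(tmp_path_factory):
    """A weekly-QA DICOM fixture on disk (default study conditions, seed 1)."""
    out = tmp_path_factory.mktemp("weekly")
    manifest = make_phantom_series(PhantomSpec(seed=1), out)
    return out, manifest


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
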