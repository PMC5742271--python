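import numpy as np
import pytest

from dyadrec.categorize import DETAILED, SIMPLE, CategoricalSeries
from dyadrec.trajectory import BoxTrajectory


def make_trajectory(centers, valid=None, fps=25.0, w=10.0, h=10.0, **kw):
    """Build a BoxTrajectory from an (N, 2) array of centers."""
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return BoxTrajectory(
        x=centers[:, 0] - w / 2.0,
        y=centers[:, 1] - h / 2.0,
        w=np.full(n, w),
        h=np.full(n, h),
        valid=np.asarray(valid, dtype=bool),
        fps=fps,
        **kw,
    )


def make_series(codes, system=SIMPLE, fps=25.0, **kw):
    return CategoricalSeries(np.asarray(codes), fps=fps, system=system, **kw)


def random_series(rng, n, system=SIMPLE, fps=25.0):
    return CategoricalSeries(
        rng.integers(0, system.n_categories, size=n), fps=fps, system=system
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple():
    return SIMPLE


@pytest.fixture
def detailed():
    return DETAILED
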