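import numpy as np
import pytest

from petrad.discretize import DiscretizedROI
from petrad.phantom import PhantomSpec
from petrad.pipeline import StudyConfig, run_study


def make_discretized(levels: np.ndarray, mask: np.ndarray, ng: int) -> DiscretizedROI:
    """Build a DiscretizedROI directly from integer levels (test helper)."""
    levels = np.asarray(levels, dtype=np.int32)
    mask = np.asarray(mask, dtype=bool)
    grid = np.where(mask, levels, 0).astype(np.int32)
    return DiscretizedROI(
        levels=grid,
        mask=mask,
        ng=ng,
        bin_size=1.0,
        suv_min=0.0,
        suv_max=float(ng),
        spacing_mm=(1.0, 1.0, 1.0),
    )


def random_roi(rng: np.random.Generator, max_shape=(6, 6, 4), ng_max=8):
    """Random small discretized ROI guaranteed to have adjacent voxel pairs."""
    while True:
        shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
        ng = int(rng.integers(2, ng_max + 1))
        mask = rng.random(shape) < 0.7
        if mask.sum() < 4:
            continue
        levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
        d = make_discretized(levels, mask, ng)
        # require at least one in-mask adjacent pair so all builders are defined
        from petrad.texture_features import DIRECTIONS_3D, _offset_slices

        has_pair = False
        for off in DIRECTIONS_3D:
            src, dst = _offset_slices(shape, off)
            if (mask[src] & mask[dst]).any():
                has_pair = True
                break
        if has_pair:
            return d


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom spec used across tests."""
    return PhantomSpec(
        grid_shape=(32, 32, 24),
        tumor_radius_mm=18.0,
        heterogeneity_amp=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def study_report():
    """One seeded 10-case phantom study shared by pipeline/acceptance tests."""
    return run_study(StudyConfig(n_cases=10, seed=7))
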