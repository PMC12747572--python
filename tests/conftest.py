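import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_morph_scene():
    """Zero-noise stack of 3 disjoint ellipsoid cells at 0.62 um pitch."""
    from gliascope import synthetic as s

    rng = np.random.default_rng(11)
    cells = s.random_cell_truths(3, (56, 168, 168), 0.62, rng)
    spec = s.MorphStackSpec(
        grid_shape=(56, 168, 168), voxel_pitch_um=0.62, cells=cells,
        noise_sd=0.0, seed=11,
    )
    img, truth = s.generate_morphology_stack(spec)
    return img, truth


@pytest.fixture(scope="session")
def small_calcium_scene():
    """Short zero-noise movie with 3 cells: one event in cells 0 and 2."""
    from gliascope import synthetic as s

    cells = [
        s.CalciumCellSpec(center_px=(16.0, 16.0)),
        s.CalciumCellSpec(center_px=(40.0, 16.0)),
        s.CalciumCellSpec(center_px=(28.0, 40.0)),
    ]
    events = [
        s.EventTruth(0, 30.0, 0.5, 1.2, 4.0),
        s.EventTruth(2, 70.0, 0.3, 1.0, 3.5),
    ]
    spec = s.CalciumMovieSpec(
        frame_shape=(56, 56), duration_s=120.0, cells=cells, events=events,
        noise_sd=0.0, seed=5,
    )
    return s.generate_calcium_movie(spec)
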