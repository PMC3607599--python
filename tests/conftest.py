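import numpy as np
import pytest

from sporetrace.simulate import GroundTruthManifest, SporeScript, simulate_movie
from sporetrace.stack_io import RunConfig


@pytest.fixture(scope="session")
def three_fate_manifest() -> GroundTruthManifest:
    """One spore of each fate: outgrowing (with a coat burst), germinating
    without outgrowth, and dormant.  Noise-free, 30 s frames."""
    scripts = [
        SporeScript(
            0, (30.0, 30.0), "outgrow",
            t_germ_start_min=10.0, germ_duration_min=4.0,
            t_first_division_min=60.0, generation_time_min=40.0,
            burst_time_min=30.0, burst_jump=0.4,
        ),
        SporeScript(
            1, (30.0, 90.0), "germinate_only",
            t_germ_start_min=20.0, germ_duration_min=3.0,
        ),
        SporeScript(2, (90.0, 60.0), "dormant"),
    ]
    return GroundTruthManifest(scripts=scripts, frame_interval_s=30.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def three_fate_stack(three_fate_manifest):
    """Rendered 140-minute movie of the three-fate manifest."""
    return simulate_movie(three_fate_manifest, n_frames=280, shape=(120, 120), seed=1)


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def explicit_config() -> RunConfig:
    """Thresholds pinned to the simulator's default intensity scale
    (background 100, bright 180, dark 40)."""
    return RunConfig(bright_threshold=140.0, dark_threshold=70.0)
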