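import numpy as np
import pytest

from activecomm import ArenaSpec, generate_trajectory


@pytest.fixture
def circular_arena():
    return ArenaSpec(kind="circular", size_m=0.345, px_per_m=1000.0, fps=10.0)


@pytest.fixture
def big_arena():
    # roomy open field so random walks rarely hit the wall
    return ArenaSpec(kind="open_field", size_m=2.0, px_per_m=500.0, fps=10.0)


@pytest.fixture
def linear_arena():
    return ArenaSpec(kind="linear", size_m=1.2, px_per_m=1000.0, fps=10.0)


@pytest.fixture
def pirouette(circular_arena):
    """Two full clockwise turns at a uniform 4.5 deg/frame (161 frames)."""
    return generate_trajectory(circular_arena, duration_s=16.1, mean_speed=0.0,
                               n_full_turns=2, seed=11)


def monotone_traverse(arena, n=121):
    """Pose stream walking the full track left to right at constant speed."""
    from activecomm import PoseStream
    x = np.linspace(0.0, arena.size_m, n) * arena.px_per_m
    y = np.full(n, 50.0)
    return PoseStream(
        frame_index=np.arange(n),
        timestamp_s=np.arange(n) / arena.fps,
        head_xy=np.column_stack([x, y]),
        tail_xy=np.column_stack([x - 60.0, y]),
        head_conf=np.ones(n),
        tail_conf=np.ones(n),
    )
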