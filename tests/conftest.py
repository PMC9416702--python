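import numpy as np
import pytest
from hypothesis import settings
from hypothesis import strategies as st

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paniclecount.boxgeom import Box


def nonempty_int_box(grid: int = 64):
    """Hypothesis strategy: integer boxes with positive area in a grid."""

    def build(draw):
        x0 = draw(st.integers(0, grid - 1))
        y0 = draw(st.integers(0, grid - 1))
        x1 = draw(st.integers(x0 + 1, grid))
        y1 = draw(st.integers(y0 + 1, grid))
        return Box(x0, y0, x1, y1)

    return st.composite(build)()


def random_boxes(rng: np.random.Generator, n: int, extent: float = 200.0,
                 scale_mix: bool = True) -> list[Box]:
    """Random boxes mixing small and large area scales (>= 10x span)."""
    boxes = []
    for _ in range(n):
        if scale_mix and rng.random() < 0.5:
            w = rng.uniform(2.0, 10.0)
            h = rng.uniform(2.0, 10.0)
        else:
            w = rng.uniform(30.0, 80.0)
            h = rng.uniform(30.0, 80.0)
        x = rng.uniform(0.0, extent - w)
        y = rng.uniform(0.0, extent - h)
        boxes.append(Box(x, y, x + w, y + h, score=float(rng.random())))
    return boxes


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
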