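import numpy as np
import pytest

from edframes import EventList


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def isolated_events(rng, n, shape, min_separation, margin=2):
    """Random events with pairwise separation >= min_separation, kept
    ``margin`` pixels away from the image edge."""
    h, w = shape
    pos = []
    while len(pos) < n:
        y = int(rng.integers(margin, h - margin))
        x = int(rng.integers(margin, w - margin))
        if all((y - py) ** 2 + (x - px) ** 2 >= min_separation ** 2
               for py, px in pos):
            pos.append((y, x))
    ys = np.array([p[0] for p in pos])
    xs = np.array([p[1] for p in pos])
    return EventList(x=xs, y=ys, dx=rng.random(n), dy=rng.random(n),
                     frame=np.zeros(n, dtype=int))


def event_count_image(events, shape):
    img = np.zeros(shape, dtype=np.int64)
    np.add.at(img, (events.y, events.x), 1)
    return img
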