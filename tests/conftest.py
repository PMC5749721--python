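import numpy as np
import pandas as pd
import pytest

from flimpair.metrics import CELL_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_cells(
    lifetimes,
    construct="Clv",
    platform="FD",
    day=1,
    timepoint=0.0,
    intensity=1000.0,
):
    """Minimal per-cell measurement table for one construct/day/timepoint."""
    rows = [
        (f"{construct}_d{day}_c{i:02d}", f"d{day}_s1", day, platform, construct,
         timepoint, intensity, tau)
        for i, tau in enumerate(lifetimes)
    ]
    return pd.DataFrame(rows, columns=list(CELL_COLUMNS))


def stack(*frames):
    return pd.concat(frames, ignore_index=True)
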