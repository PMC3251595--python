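import numpy as np
import pytest

from arqiv.plate_io import Channel, ScanGrid


@pytest.fixture
def make_grid():
    """Factory for small scan grids with sensible defaults."""

    def _make(values, well="A1", subject="fish-001", channel="YFP", replicate=1):
        n = int(round(len(values) ** 0.5))
        return ScanGrid(
            well_id=well,
            subject_id=subject,
            channel=Channel(name=channel),
            pattern_n=n,
            values=list(values),
            replicate_index=replicate,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
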