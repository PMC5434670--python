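import numpy as np
import pytest

from interorsa.ingest import RRSeries


def make_rr(intervals, start_ms: float = 0.0) -> RRSeries:
    """RRSeries from a plain interval list (onsets implied)."""
    vals = np.asarray(intervals)
    onsets = start_ms + np.concatenate(([0], np.cumsum(vals[:-1])))
    return RRSeries(onsets, vals)


@pytest.fixture(scope="session")
def band_filter():
    from interorsa.rsa import design_band_filter

    return design_band_filter()
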