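"""Shared fixtures: small deterministic recordings and envelopes.

Everything is generated programmatically; geometry is kept at desk scale
(seconds to a few minutes, a handful of channels) so the whole suite runs
on one CPU in minutes.
"""

import numpy as np
import pytest

from lrtcpipe.containers import ContinuousRecording
from lrtcpipe.dfa import FitRange, make_window_grid
from lrtcpipe.synthetic import FgnSpec, gen_fgn

FS = 400.0
DURATION = 300.0


@pytest.fixture(scope="session")
def default_grid():
    return make_window_grid()


@pytest.fixture(scope="session")
def fit_range():
    return FitRange(1.0, 60.0)


@pytest.fixture(scope="session")
def fgn_envelope_h08():
    """A 300 s, 400 Hz fGn series with H=0.8, used directly as an envelope."""
    return gen_fgn(FgnSpec(hurst=0.8, n_samples=int(FS * DURATION), seed=42))


@pytest.fixture()
def white_recording():
    rng = np.random.default_rng(7)
    data = rng.standard_normal((2, int(FS * 60)))
    return ContinuousRecording(data, FS, ["CH001", "CH002"])
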