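import numpy as np
import pytest

import ptdna


@pytest.fixture
def untreated_params():
    """WLC ground truth for untreated lambda-DNA."""
    return ptdna.WLCParameters(44.0, 16.5)


@pytest.fixture
def straight_trace():
    """Perfectly straight 680-nm backbone (2-kb molecule, 2-nm segments)."""
    n = 341
    pts = np.column_stack([np.arange(n) * 2.0, np.zeros(n)])
    return ptdna.PolylineTrace(pts, segment_nm=2.0)


def make_decay_series(plateau, amplitudes, taus, duration=600.0, dt=1.0,
                      sigma=0.0, seed=None):
    spec = {"plateau": plateau, "amplitudes": amplitudes,
            "time_constants": taus}
    return ptdna.gen_extension_timeseries(
        spec, sampling_interval_min=dt, duration_min=duration,
        noise=ptdna.NoiseModel("additive-gaussian", sigma), seed=seed)
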