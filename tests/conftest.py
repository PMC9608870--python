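import numpy as np
import pytest

from cortexlrp.sourcespace import CorticalSourceSpace
from cortexlrp.synthdata import TrialSet


def make_trialset(data, eog=None, subject_id=None, group=None, fs=400.0, t0=-200.0):
    """Assemble a TrialSet from raw arrays with a uniform time grid."""
    data = np.asarray(data, dtype=np.float32)
    n, _, n_s = data.shape
    if eog is None:
        eog = np.zeros((n, n_s), dtype=np.float32)
    if subject_id is None:
        subject_id = np.zeros(n, dtype=int)
    if group is None:
        group = np.array(["control"] * n)
    return TrialSet(
        data=data,
        eog=np.asarray(eog, dtype=np.float32),
        subject_id=np.asarray(subject_id),
        group=np.asarray(group, dtype=str),
        retained=np.ones(n, dtype=bool),
        time_ms=t0 + 1000.0 * np.arange(n_s) / fs,
    )


def make_space(lat, lon, hemisphere=None, region=None):
    """Hand-built source space for projection tests."""
    lat = np.asarray(lat, dtype=float)
    n = len(lat)
    if hemisphere is None:
        hemisphere = np.array(["left"] * n)
    if region is None:
        region = np.array(["background"] * n)
    return CorticalSourceSpace(
        lat=lat,
        lon=np.asarray(lon, dtype=float),
        hemisphere=np.asarray(hemisphere, dtype=str),
        region=np.asarray(region, dtype=str),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
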