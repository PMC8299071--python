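import numpy as np
import pytest

import pupilload as pl
from pupilload.simulate import generate_cohort, workload_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fully generated 4-participant workload cohort (samples, segments,
    manifest); session-scoped because generation is the expensive part."""
    design = workload_cohort(n_participants=4, master_seed=11)
    return generate_cohort(design)


@pytest.fixture()
def make_series():
    """Factory for PupilSeries on a regular 300 Hz grid."""
    def _make(d, fs=300.0, eye="left", valid=None):
        d = np.asarray(d, dtype=float)
        t = np.arange(len(d)) / fs
        v = np.ones(len(d), dtype=bool) if valid is None \
            else np.asarray(valid, dtype=bool)
        return pl.PupilSeries(eye=eye, t=t, d=d, valid=v)
    return _make


@pytest.fixture()
def noisy_series(make_series):
    """A realistic pupil series: baseline + transients + tracker noise."""
    def _make(seed, duration=10.0, rate=1.0, **kw):
        rng = np.random.default_rng(seed)
        params = pl.SignalParams(event_rate_hz=rate, blink_rate_hz=0.0, **kw)
        chunk = pl.generate_pupil_segment(duration, 300.0, params, rng)
        return pl.PupilSeries(eye="left", t=chunk["t"], d=chunk["left"],
                              valid=chunk["valid"])
    return _make
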