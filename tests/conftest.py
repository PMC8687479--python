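import numpy as np
import pandas as pd
import pytest

from tepkit.io import CohortTable, TEPTimeSeries
from tepkit.simulate import SimulationConfig


def make_tep(data, subject_id="s1", target="DLPFC", t0_ms=-1000.0, fs_hz=1000.0,
             space="sensor", series_ids=None):
    data = np.asarray(data, dtype=float)
    if series_ids is None:
        series_ids = [f"c{i}" for i in range(data.shape[1])]
    return TEPTimeSeries(subject_id=subject_id, target=target, data=data,
                         t0_ms=t0_ms, fs_hz=fs_hz, space=space,
                         series_ids=series_ids)


def coarse_tep(data, **kw):
    """TEP whose few samples still span the required -900..400 ms window
    (coarse sampling rate), for hand-computed small cases."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    fs = 1000.0 * (n - 1) / 3000.0  # span exactly -1000..2000 ms
    return make_tep(data, t0_ms=-1000.0, fs_hz=fs, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Small, quick simulation config (short epoch, few vertices/sensors)."""
    return SimulationConfig(n_subjects=8, epoch_ms=(-1000.0, 500.0),
                            n_roi_vertices=10, n_sensors=6)


def make_cohort_df(n=3):
    rows = []
    for i in range(n):
        rows.append(dict(
            subject_id=f"sub-{i + 1:03d}", phq_pre=2, phq_pandemic=[2, 1, 2],
            phq2_pre=1, gad2_pre=1,
            phq2_pandemic=[1, 0, 1], gad2_pandemic=[1, 1, 1],
            pss14=14, age=50 + i, gender="female" if i % 2 else "male",
            education_years=12 + i, months_since_tms=6,
            targeting_method="anatomical" if i % 2 else "functional",
            completed_targets=["DLPFC", "IPL"],
        ))
    return pd.DataFrame(rows)


@pytest.fixture
def small_cohort():
    return CohortTable(make_cohort_df())
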