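import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stick_row_run():
    """One full LiDAR pipeline run on the synthetic stick calibration row.

    19 sticks at 240-mm nominal spacing on a raised seedbed, 5-mm range
    noise, fixed seed; shared across tests because the run takes ~1 s.
    """
    from rowoptics import lidar, synthetic

    cfg = synthetic.SimConfig.stick_row(rng_seed=1)
    truth = synthetic.gen_row_truth(cfg)
    scans = synthetic.gen_lidar_scans(truth, cfg)
    lc = lidar.LidarConfig(theoretical_spacing=cfg.nominal_spacing, rng_seed=1)
    result = lidar.run_lidar_pipeline(
        scans,
        lc,
        y_bounds=(cfg.row_offset - cfg.bed_halfwidth, cfg.row_offset + cfg.bed_halfwidth),
    )
    return cfg, truth, scans, lc, result
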