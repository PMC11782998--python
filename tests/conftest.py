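import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_curve():
    """A calibration curve fitted to a noiseless synthetic dilution ladder,
    run end to end through chromatogram simulation and peak integration."""
    from tandemquant import mrm_quant as mq
    from tandemquant import synthetic_data as sd

    cfg = sd.SimulationConfig(seed=11, area_cv=0.0)
    nominal, ratios = [], []
    for cs in sd.simulate_calibration_series(cfg):
        if cs.kind != "calibrator":
            continue
        heavy = mq.extract_peak_areas(cs, "GAFQQAAQILR", "heavy")
        light = mq.extract_peak_areas(cs, "GAFQQAAQILR", "light", window=heavy.window)
        nominal.append(cs.nominal)
        ratios.append(mq.light_heavy_ratio(light, heavy))
    return mq.fit_calibration(nominal, ratios)
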