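import numpy as np
import pytest

import p3dseize as pz


@pytest.fixture(scope="session")
def small_windows() -> pz.WindowSet:
    """One 1200-s synthetic recording with an onset at 1200 s: the SPH zone
    [300, 900) yields 100 preictal windows, [0, 300) yields 50 interictal,
    balanced to 50:50."""
    cfg = pz.PipelineConfig(
        synth=pz.SynthConfig(duration_s=1200.0, seizure_onsets_s=(1200.0,)),
        n_recordings=1,
        seed=11,
    )
    return pz.pipeline.extract_windows(cfg)


@pytest.fixture(scope="session")
def small_block(small_windows) -> pz.FeatureBlock:
    """All four nonlinear features on the small window set."""
    return pz.extract_feature_block(
        pz.split_steps(small_windows),
        pz.FeatureParams(),
        pz.FEATURE_NAMES,
        small_windows.channel_names,
    )
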