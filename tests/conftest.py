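import numpy as np
import pytest

import fpvs


@pytest.fixture(scope="session")
def montage():
    return fpvs.make_montage()


@pytest.fixture(scope="session")
def tiny_cfg():
    """Short trains, no artifacts: fast end-to-end runs."""
    return fpvs.SimulationConfig(
        n_cycles=16, segment_s=15.0, pad_s=0.5,
        n_per_group={"NT": 2, "autism": 2},
        blink_amp=0.0, line_amp=0.0)


@pytest.fixture(scope="session")
def clean_cfg():
    """Full-length train, all stochastic sources silenced."""
    return fpvs.SimulationConfig(noise_scale=0.0, line_amp=0.0,
                                 blink_amp=0.0, between_subject_sd=0.0)


@pytest.fixture(scope="session")
def default_epoch_with_blinks(montage):
    """One default-config recording preprocessed up to (not including)
    ocular correction, plus its ground truth.  Shared because ICA is the
    most expensive single step in the suite."""
    cfg = fpvs.SimulationConfig()
    rec, gt = fpvs.simulate_recording(cfg, "NT01", "NT", "Self", "Faces",
                                      montage=montage)
    ep = fpvs.segment(fpvs.bandpass(fpvs.rereference_average(rec)),
                      "Self", "Faces")
    return cfg, ep, gt


def cluster_mean_summed_bs(spectrum, channels, targets):
    return float(np.mean([
        fpvs.oddball_response(spectrum, ch, targets).summed_bs
        for ch in channels]))
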