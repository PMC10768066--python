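import numpy as np
import pytest

from pupileffort.cohort import Design, TraceConfig, build_schedule, generate_profiles
from pupileffort.types import LatentParams, ParticipantProfile


@pytest.fixture
def default_profiles():
    """A 17-listener cohort under the default generative conditions."""
    return generate_profiles(17, seed=1)


@pytest.fixture
def quiet_profile():
    """One hand-built participant with convenient round-number latents."""
    return ParticipantProfile(
        participant_id="PX",
        age=50.0, ci_duration=40.0, sex="F",
        word_recognition=80.0, t_level=30.0, qol_total=70.0,
        matrices_correct=22, stroop_interference=-0.05,
        stroop_control_rt=0.7, nback_dprime=2.0, smrt_threshold=2.5,
        latent=LatentParams(tip_snr=12.0, peak_amp=8.0, curve_width=6.0,
                            srt=8.0, slope=0.3, baseline_mm=4.0,
                            blink_rate=0.0),
    )


@pytest.fixture
def noiseless_trace_cfg():
    """Trace simulation with every stochastic component switched off."""
    return TraceConfig(noise_sd=0.0, drift_sd=0.0, artifact_burst_prob=0.0)


@pytest.fixture
def tiny_design():
    return Design(lists_per_snr=1, sentences_per_list=1)


@pytest.fixture
def one_trial(quiet_profile, tiny_design):
    return build_schedule(quiet_profile, tiny_design, seed=0)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
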