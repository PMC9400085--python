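import numpy as np
import pytest

from nervedose import (DoseResponseSimConfig, FourPLParams, NerveSimConfig,
                       ToneProtocol)


@pytest.fixture
def small_protocol():
    """A scaled-down tone protocol for fast simulation-based tests."""
    return ToneProtocol(
        baseline_duration=10.0,
        spl_levels=(30.0, 50.0, 70.0, 90.0, 110.0),
        repetitions_per_spl=2,
        inter_tone_gap=0.5,
        sampling_rate=12500.0,
    )


@pytest.fixture
def flat_config():
    """Evoked curve identically 1: no tone-evoked change in activity."""
    return NerveSimConfig(evoked_curve=FourPLParams(b=-0.15, c=1.0, d=1.0, e=75.0),
                          seed=0)


@pytest.fixture
def null_dose_config():
    """Both treatment groups share the same truth (null treatment effect)."""
    truth = FourPLParams(b=-0.15, c=1.0, d=8.0, e=75.0)
    return DoseResponseSimConfig(
        truth_per_group={"control": truth, "noise": truth},
        n_animals_per_group=30, animal_intercept_sd=0.0, residual_sd=0.3,
        seed=0)


def make_square_trace(level_base, level_tone, protocol):
    """Piecewise alternating +/-A trace: |x| = level everywhere, zero mean.

    Baseline and inter-tone spans alternate at +/-level_base; each tone
    window alternates at +/-level_tone.  Used for exact sigma fixtures.
    """
    from nervedose import NerveTrace
    sr = protocol.sampling_rate
    n = protocol.n_samples
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    x = sign * level_base
    for onset, _ in protocol.tone_schedule():
        i0 = int(round(onset * sr))
        i1 = i0 + int(round(protocol.tone_duration * sr))
        x[i0:i1] = sign[i0:i1] * level_tone
    return NerveTrace(samples=x, sampling_rate=sr,
                      annotations=protocol.tone_schedule(),
                      baseline_span=(0.0, protocol.baseline_duration))
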