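import dataclasses

import pytest

from snapage import LOCUS_ORDER, MethylationProfile, default_config


def make_profile(levels, sample_id="S", replicate_key="averaged"):
    """Profile from a locus→level map or a 5-vector in canonical locus order."""
    if not isinstance(levels, dict):
        levels = dict(zip(LOCUS_ORDER, levels))
    return MethylationProfile(sample_id=sample_id, replicate_key=replicate_key, levels=levels)


@pytest.fixture
def zero_noise_config():
    """Default study conditions with every stochastic term switched off."""
    cfg = default_config(seed=123)
    quiet = {
        locus: dataclasses.replace(p, noise_sd=0.0)
        for locus, p in cfg.locus_params.items()
    }
    return dataclasses.replace(
        cfg,
        locus_params=quiet,
        replicate_noise_sd=0.0,
        conversion_shift=0.0,
        total_intensity_sd=0.0,
        intensity_noise_cv=0.0,
    )
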