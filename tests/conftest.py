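import numpy as np
import pytest

from midgap import gapcall, synthgen


@pytest.fixture
def default_params():
    return synthgen.TraceParams(seed=7)


@pytest.fixture
def gapped_embryo():
    """One embryo with a single 12-point implanted gap."""
    params = synthgen.TraceParams(seed=3, gap_intervals=((100, 112),))
    return synthgen.generate_trace(params, embryo_id="emb-gap", genotype="mutant")


def make_background(thresholds: dict[str, float], cyto_mean: float = 100.0):
    """Hand-built background model with explicit per-channel thresholds."""
    channels = tuple(
        gapcall.ChannelBackground(
            channel=name,
            cyto_mean=cyto_mean,
            cyto_sd=cyto_mean * thr / 2.0,
            n=100,
            norm_sd=thr / 2.0,
            threshold=thr,
            coverage=np.nan,
        )
        for name, thr in thresholds.items()
    )
    return gapcall.BackgroundModel(channels=channels)
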