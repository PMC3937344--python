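import numpy as np
import pytest

from mfaquant import (
    GroundTruth,
    NFEstimate,
    PadCondition,
    PadLayout,
    RampProtocol,
)


@pytest.fixture
def ramp():
    return RampProtocol(loading_rate=100.0)


@pytest.fixture
def single_pad_layout():
    """One 160 px pad centred in a 256x256 image, high-affinity vs 20 bp."""
    return PadLayout(
        grid_rows=1,
        grid_cols=1,
        pad_size_px=160,
        pitch_px=160,
        image_shape=(256, 256),
        pad_conditions={(0, 0): PadCondition("high_affinity", 20)},
    )


def make_truth(layout, p, *, density=10000.0, p_sd=0.0, noise_free=False, seed=0, **kwargs):
    """GroundTruth with a uniform transfer probability on every pad."""
    shape = (layout.grid_rows, layout.grid_cols)
    params = dict(
        protein_density=np.full(shape, float(density)),
        transfer_probability=np.full(shape, float(p)),
        transfer_probability_sd=np.full(shape, float(p_sd)),
        seed=seed,
    )
    if noise_free:
        params.update(
            background_sd=0.0,
            multiplicative_noise_cv=0.0,
            read_noise_sd=0.0,
            inhomogeneity_amplitude=0.0,
        )
    params.update(kwargs)
    return GroundTruth(**params)


def make_estimate(nf_mean, nf_sd, motif="m", n_bp=20, status="fitted", n_pixels=10000):
    return NFEstimate(
        pad_id=(0, 0),
        motif_label=motif,
        reference_n_bp=n_bp,
        nf_mean=nf_mean,
        nf_sd=nf_sd,
        n_pixels=n_pixels,
        status=status,
    )
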