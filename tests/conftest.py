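import numpy as np
import pytest

from gonadfoci.core import ChannelMeta, ImageStack
from gonadfoci.synth import (
    AxisSpec,
    ColocSpec,
    SceneSpec,
    SpeciesParams,
    generate_scene,
)


@pytest.fixture(scope="session")
def demo_scene():
    """A small two-species scene with axis tracks and colocalization truth."""
    spec = SceneSpec(
        n_nuclei=8,
        rows=2,
        seed=11,
        species_params={
            "RAD-51": SpeciesParams(n_foci=5, emission_nm=555),
            "MSH-5": SpeciesParams(n_foci=5, emission_nm=647),
        },
        coloc_spec=[ColocSpec("RAD-51", "MSH-5", fraction=0.5)],
        axis_spec=AxisSpec(association_fraction={"RAD-51": 0.6}),
        background_mean=50.0,
        background_sd=10.0,
    )
    return spec, generate_scene(spec)


@pytest.fixture()
def tiny_stack():
    """Deterministic 2-channel 4x8x8 stack for I/O round trips."""
    rng = np.random.default_rng(0)
    vox = rng.integers(0, 1000, size=(2, 4, 8, 8)).astype(np.float32)
    channels = [ChannelMeta("RAD-51", 555.0), ChannelMeta("MSH-5", 647.0)]
    return ImageStack(voxels=vox, spacing=(200.0, 80.0, 80.0), channels=channels)


def render_spot(shape, pos, sigma=(0.8, 1.3, 1.3), peak=1000.0):
    """Single separable Gaussian spot in an otherwise empty volume."""
    vol = np.zeros(shape, dtype=float)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vol += peak * np.exp(
        -0.5
        * (
            ((zz - pos[0]) / sigma[0]) ** 2
            + ((yy - pos[1]) / sigma[1]) ** 2
            + ((xx - pos[2]) / sigma[2]) ** 2
        )
    )
    return vol


def single_channel_stack(vol, name="RAD-51", spacing=(200.0, 80.0, 80.0)):
    return ImageStack(
        voxels=np.asarray(vol)[None],
        spacing=spacing,
        channels=[ChannelMeta(name, 555.0)],
    )
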