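import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wing_noiseless():
    """A rendered mosaic wing with zero pixel noise and zero wing effect."""
    from wingpol import junctions as jx
    from wingpol import synthwing as sw

    spec = sw.WingSpec(seed=7, noise_sd=0.0, wing_scale_sd_log=0.0)
    label, clone = sw.make_lattice(spec)
    stack = sw.render_membrane_stack(label, clone, spec)
    skel = jx.build_skeleton(label, clone)
    return spec, label, clone, stack, skel


@pytest.fixture(scope="session")
def two_cell_mask():
    """Two side-by-side cells split by a one-pixel membrane column."""
    from wingpol.imgio import LabelMask

    labels = np.ones((12, 21), dtype=np.int64)
    labels[:, 10] = 0
    labels[:, 11:] = 2
    return LabelMask(labels)
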