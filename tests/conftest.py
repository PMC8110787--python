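import numpy as np
import pytest

from cellindent.curves import ForceCurve


def make_kink_curve(k=2.0, z0=5.0, z_max=10.0, step=0.02, noise_sd=0.0, rng=None,
                    **meta):
    """Piecewise-linear approach curve: zero baseline, then slope k past z0."""
    z = np.arange(0.0, z_max + step / 2, step)
    F = k * np.clip(z - z0, 0.0, None)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        F = F + rng.normal(0.0, noise_sd, z.size)
    return ForceCurve(z=z, F=F, **meta)


@pytest.fixture
def kink_curve():
    return make_kink_curve()
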