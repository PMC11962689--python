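import numpy as np
import pytest

from cytomech.containers import ForceCurve, ForceVolumeMap
from cytomech.mechanics import ContactPoint
from cytomech.synth import SynthFVSpec, generate_force_volume


NOISELESS_16 = SynthFVSpec(rows=16, cols=16, dome_radius=6e-6,
                           dome_height=2.5e-6, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def fv16():
    """Noiseless 16x16 dome map plus its ground truth (session-cached)."""
    return generate_force_volume(NOISELESS_16)


@pytest.fixture(scope="session")
def fv16_spec():
    return NOISELESS_16


def make_plane_map(rows=8, cols=8, pitch=1e-6, alpha=0.1):
    """A fake force-volume map whose contacts lie on the plane z = alpha*x.

    The curves themselves are shared boilerplate (only their pixel indices
    matter for topography); the per-pixel contact heights carry the plane.
    """
    k = 0.2
    z = np.linspace(0.0, 2e-7, 20)
    defl = np.linspace(0.0, 1.5e-9 / k, 20)
    curves = [ForceCurve(z_piezo=z, deflection=defl, spring_constant=k,
                         pixel=(r, c))
              for r in range(rows) for c in range(cols)]
    fv = ForceVolumeMap(rows=rows, cols=cols, pitch=pitch, curves=curves)
    # deepest contact at x=0; topography flips sign (height above substrate)
    contacts = [ContactPoint(index=0, z=float(-alpha * c * pitch),
                             baseline=0.0, noise_sd=0.0)
                for r in range(rows) for c in range(cols)]
    return fv, contacts
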