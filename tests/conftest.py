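import math

import numpy as np
import pytest

from pprism.bloch_rf import design_slr, refocused_signal, simulate_profile
from pprism.prism_encoding import default_slice_plan, generate_prism_pattern
from pprism.pseudo_slab_rf import PseudoSlabSpec, compose_pseudo_slab
from pprism.psf_model import fine_grid


@pytest.fixture(scope="session")
def exc_pulse():
    """Default 90-degree excitation: 8 ms, time-bandwidth 5.4."""
    return design_slr(90.0, 8e-3, 5.4, "none", "excitation")


@pytest.fixture(scope="session")
def ref_pulse():
    """Default refocusing: 180 degrees, 9.6 ms, TB 3.4, Hamming window."""
    return design_slr(180.0, 9.6e-3, 3.4, "hamming", "refocusing")


@pytest.fixture(scope="session")
def slab_spec():
    """Paper-style pseudo slab: 5 slices, 0.86 mm, schedule (0,0,0,pi,0),
    polarities (-,+,+,-,+)."""
    return PseudoSlabSpec(
        n_p=5, slice_thickness=0.86,
        phases=np.array([0.0, 0.0, 0.0, math.pi, 0.0]),
        polarities=np.array([-1.0, 1.0, 1.0, -1.0, 1.0]),
    )


@pytest.fixture(scope="session")
def slab_pulses(exc_pulse, ref_pulse, slab_spec):
    return {
        "exc": compose_pseudo_slab(exc_pulse, slab_spec),
        "ref": compose_pseudo_slab(ref_pulse, slab_spec,
                                   use_polarity=True),
    }


@pytest.fixture(scope="session")
def slab_refocused_profile(slab_pulses, slab_spec):
    """Composed-slab crushed-spin-echo profile on a grid covering the
    PSF fine grid with margin."""
    zf = fine_grid(slab_spec)
    zz = np.linspace(zf[0] - 1.5, zf[-1] + 1.5, 4001)
    ep = simulate_profile(slab_pulses["exc"], zz)
    rp = simulate_profile(slab_pulses["ref"], zz)
    return refocused_signal(ep, rp)


@pytest.fixture(scope="session")
def small_geometry():
    """M=2, n_p=5, q=1 pattern with the default slab pitch."""
    spec = PseudoSlabSpec(
        n_p=5, slice_thickness=0.86,
        phases=np.array([0.0, 0.0, 0.0, math.pi, 0.0]),
    )
    fov = 2 * 5 * spec.slice_spacing
    pattern = generate_prism_pattern(2, 5, 1, fov)
    return spec, pattern, default_slice_plan(pattern)
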