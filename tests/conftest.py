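import math

import numpy as np
import pytest

from ssnvol import SeedInput, quantify, segment_nodule
from ssnvol.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def iso_spacing():
    return (0.7, 0.7, 0.7)


def offset_spec(d_mm, rng, **kwargs):
    """Phantom spec with a random sub-voxel center offset (avoids lattice resonance)."""
    spec = PhantomSpec(diameter_mm=d_mm, **kwargs)
    off = rng.uniform(-0.5, 0.5, 3) * np.asarray(spec.spacing)
    spec.center = tuple(np.asarray(spec.center) + off)
    return spec


def run_pipeline(spec, params=None):
    """Generate, segment with a diameter stroke, quantify; return (truth, metrics, result)."""
    vol, truth = generate_phantom(spec)
    c, r = spec.center, spec.radius
    stroke = ((c[0], c[1] - r, c[2]), (c[0], c[1] + r, c[2]))
    result = segment_nodule(vol, SeedInput(stroke=stroke), params)
    return truth, quantify(vol, result.mask), result


def rel_err_pct(measured, truth):
    return 100.0 * (measured - truth) / truth


def sphere_volume(d_mm):
    return math.pi / 6.0 * d_mm**3
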