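import numpy as np
import pytest

from vesisort.phantom import PhantomSpec, generate_phantom_stack


def digital_ball(radius: int, pad: int = 2) -> np.ndarray:
    """Boolean voxel ball: centers within `radius` of the middle voxel."""
    n = 2 * (radius + pad) + 1
    c = radius + pad
    zz, yy, xx = np.mgrid[:n, :n, :n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Seeded 20-vesicle noiseless phantom with its ground truth."""
    spec = PhantomSpec(n_vesicles=20, seed=1, noise_sd=0.0)
    stack, truth = generate_phantom_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def segmented_phantom(noiseless_phantom):
    """Segmentation of the shared noiseless phantom (computed once)."""
    from vesisort.segmentation import segment

    spec, stack, truth = noiseless_phantom
    labels, scaled = segment(stack, spec.spacing[0])
    return spec, truth, labels, scaled
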