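import numpy as np
import pytest

from myofiberct import (
    DisarrayRegion,
    LesionRegion,
    PhantomSpec,
    ShellSpec,
    analyze_orientation,
    generate_ring_phantom,
    generate_shell_stack,
)

# Small ring used across the suite: 25-voxel wall, 48 slices.
SMALL_RING = dict(shape=(48, 120, 120), inner_radius=25.0, outer_radius=50.0)


def disarray_pair(seed: int) -> tuple[PhantomSpec, PhantomSpec]:
    """Matched aligned / disarray phantom specs (same texture seed).

    Disarray: four spheres of radius 16 at mid-wall, 90 degrees apart —
    extensive enough that their cores are not dominated by aligned streaks
    reaching in from outside (streak half-length + tensor window ~ 9 vox).
    """
    cy = cx = 59.5
    regs = tuple(
        DisarrayRegion(
            (24.0, cy + 37.5 * np.sin(np.radians(a)), cx + 37.5 * np.cos(np.radians(a))), 16.0
        )
        for a in (0, 90, 180, 270)
    )
    aligned = PhantomSpec(**SMALL_RING, seed=seed)
    disarray = PhantomSpec(**SMALL_RING, seed=seed, disarray_regions=regs)
    return aligned, disarray


def lesion_spec(intensity_factor: float, seed: int = 11) -> PhantomSpec:
    return PhantomSpec(
        **SMALL_RING,
        seed=seed,
        lesion_regions=(LesionRegion((24.0, 22.0, 60.0), (10.0, 8.0, 8.0), intensity_factor),),
    )


@pytest.fixture(scope="session")
def aligned_small():
    spec = PhantomSpec(**SMALL_RING, seed=7)
    vol, truth = generate_ring_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def aligned_analysis(aligned_small):
    _, vol, truth = aligned_small
    return analyze_orientation(vol, truth.mask())


@pytest.fixture(scope="session")
def shell_stack():
    spec = ShellSpec()  # cylindrical annulus, r 20/10, 50 slices, 100 um
    vol, truth = generate_shell_stack(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def lesion_phantom():
    spec = lesion_spec(0.5)
    vol, truth = generate_ring_phantom(spec)
    return spec, vol, truth
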