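import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_palette():
    from mucofract.pixelseg import ClassPalette

    return ClassPalette.default_ihc()


@pytest.fixture(scope="session")
def small_ihc_field():
    """One deterministic noisy synthetic field shared across tests."""
    from mucofract.synthgen import generate_ihc_field

    return generate_ihc_field(
        n_positive=40, n_negative=120, n_apoptotic=10, canvas=(320, 320), seed=11
    )


@pytest.fixture(scope="session")
def fold_outline():
    from mucofract.synthgen import OutlineSpec, generate_outline

    return generate_outline(
        OutlineSpec("fold_curve", roughness=1.0, canvas=(1024, 1024), rng_seed=3)
    )


def brute_force_box_count(mask: np.ndarray, size: int) -> int:
    """Exhaustive per-box scan, grid anchored at the foreground bounding box.

    Independent oracle for fracdim.box_count: visits every box of the
    lattice and tests occupancy directly.
    """
    ys, xs = np.nonzero(mask)
    y0, x0 = ys.min(), xs.min()
    sub = mask[y0:, x0:]
    h, w = sub.shape
    n = 0
    for by in range(0, h, size):
        for bx in range(0, w, size):
            if sub[by : by + size, bx : bx + size].any():
                n += 1
    return n
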