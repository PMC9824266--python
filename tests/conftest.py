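import numpy as np
import pytest

from hemophoton import PhantomSpec, build_digit_phantom, build_wrist_phantom


@pytest.fixture(scope="session")
def small_digit():
    """A reduced fingertip phantom: fast enough for repeated transport runs."""
    spec = PhantomSpec(
        kind="digit", outer_radius=5.0, fat_thickness=1.0, muscle_thickness=1.5,
        length=16.0, nail_length=5.0, nail_halfwidth=2.0,
    )
    return build_digit_phantom(spec)


@pytest.fixture(scope="session")
def small_wrist():
    spec = PhantomSpec(
        kind="wrist", wrist_semiaxis_x=9.0, wrist_semiaxis_z=7.0, wrist_length=12.0,
        bone_offset_x=3.5, bone_radius=2.0,
    )
    return build_wrist_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
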