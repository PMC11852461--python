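import numpy as np
import pytest

from oculoscreen.geometry import PupilEllipse
from oculoscreen.simulator import SceneTruth, render_eye_frame, sample_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_disc_scene():
    """Noise-free centered circular pupil, no glints or lashes."""
    return SceneTruth(
        pupil_ellipse=PupilEllipse((160.0, 120.0), 30.0, 30.0, 0.0),
        canthus_inner=(265.0, 121.0),
        canthus_outer=(55.0, 119.0),
        glint_centers=[],
        glint_radius=5.0,
        eyelash_segments=[],
        eyelid_coverage=0.0,
        noise_sd=0.0,
        illumination_tilt=0.0,
    )


@pytest.fixture(scope="session")
def clean_disc_frame(clean_disc_scene):
    return render_eye_frame(clean_disc_scene, seed=0)


@pytest.fixture(scope="session")
def glinted_scene():
    """Deterministic scene with one boundary-straddling glint."""
    rng = np.random.default_rng(99)
    return sample_scene(rng, glint_arc_fraction=(0.12, 0.18), n_eyelashes=4)


def circle_points(r=30.0, n=360, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], axis=1)


@pytest.fixture(scope="session")
def unit_circle_360():
    return circle_points()
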