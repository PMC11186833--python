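"""Shared fixtures: small simulated rings reused across the suite.

Unit tests run on a reduced sphere (1 mm radius, ~23 frames per ring) so a
full ring stays cheap; the acceptance tests build the full-size study ring
themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pearlring import simulate as sim

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SMALL_RADIUS = 1.0
SMALL_N_FRAMES = 23  # closes a 2*pi*1.0 mm ring at the default step


@pytest.fixture(scope="session")
def small_texture() -> sim.SphereGroundTruth:
    return sim.generate_texture(
        texture_resolution=2048, seed=7, semi_axes=(SMALL_RADIUS, SMALL_RADIUS)
    )


@pytest.fixture(scope="session")
def optics() -> sim.Optics:
    return sim.study_optics()


@pytest.fixture(scope="session")
def noiseless_ring(small_texture, optics):
    """Full noiseless ring around the 1 mm sphere, single focus depth."""
    motion = sim.MotionModel(step_mm=0.36, arc_noise_sd=0.0, lateral_sd=0.0, seed=7)
    zstacks, poses, manifest = sim.simulate_ring(
        small_texture, optics, motion, n_frames=SMALL_N_FRAMES, z_plan=(0.0,), seed=7
    )
    return zstacks, poses, manifest


@pytest.fixture(scope="session")
def small_zstack(small_texture, optics):
    """One z-stack with a single clearly in-focus depth (index 1).

    The visible surface spans depths [wd, wd + 0.05] mm, so the middle plan
    depth (wd + 0.016) is sharp over most of the frame while the outer two
    are defocused everywhere.
    """
    motion = sim.MotionModel(step_mm=0.36, arc_noise_sd=0.0, lateral_sd=0.0, seed=3)
    zstacks, _poses, _manifest = sim.simulate_ring(
        small_texture,
        optics,
        motion,
        n_frames=2,
        z_plan=(-0.1, 0.016, 0.13),
        seed=3,
    )
    return zstacks[0]


@pytest.fixture(scope="session")
def pearl_texture() -> sim.SphereGroundTruth:
    """Full-size (8.3 mm) pearl texture for study-scale arc tests."""
    return sim.generate_texture(
        texture_resolution=4096, seed=13, semi_axes=(4.15, 4.15)
    )


@pytest.fixture(scope="session")
def study_arc(pearl_texture, optics):
    """Seven noiseless frames at the study step (~3.9 deg/frame)."""
    motion = sim.MotionModel(step_mm=0.36, arc_noise_sd=0.0, lateral_sd=0.0, seed=13)
    zstacks, poses, manifest = sim.simulate_ring(
        pearl_texture, optics, motion, n_frames=7, z_plan=(0.0,), seed=13
    )
    return zstacks, poses, manifest


@pytest.fixture(scope="session")
def sharp_render(small_texture, optics):
    """A single sharp (defocus-free) view of the textured sphere."""
    from dataclasses import replace

    from pearlring import geometry as geo

    sharp_optics = replace(optics, blur_scale=0.0)
    pose = geo.build_ring_poses(
        [0.0], SMALL_RADIUS, sharp_optics.resolved_working_distance, sharp_optics
    )[0]
    return sim.render_view(small_texture, pose, sharp_optics)


@pytest.fixture(scope="session")
def translated_pair_base(small_texture):
    """Wide flat textured strip for synthetic pure-translation pairs."""
    tex = small_texture.texture.astype(float)
    # a 256-row strip away from the poles, wide enough for 35% shifts
    strip = tex[384:640, :700]
    return np.clip(strip, 0, 255).astype(np.uint8)
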