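import numpy as np
import pytest
import trimesh

from bipedsim.mesh import MeshBody
from bipedsim.model import DoF, JointSpec, SegmentSpec, SkeletonModel
from bipedsim.synth import SynthConfig, generate_hindlimb_model


@pytest.fixture(scope="session")
def full_bundle():
    """The default synthetic hindlimb model (36 muscles)."""
    return generate_hindlimb_model(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def reduced_bundle():
    """The fast 10-muscle (one per group) model."""
    return generate_hindlimb_model(SynthConfig(seed=1, muscle_set="reduced"))


def _cube_mesh(center=(0.0, 0.0, 0.0), size=1.0, density=1000.0, role="body",
               name="cube"):
    box = trimesh.creation.box(extents=[size, size, size])
    return MeshBody(box.vertices + np.asarray(center, dtype=float), box.faces,
                    density, role, name)


@pytest.fixture
def cube_mesh_factory():
    return _cube_mesh


def _hinge_model(axis=(0, 0, 1), location=(0.0, 0.0, 0.0), with_meshes=False):
    """Minimal two-segment model: fixed base, one rotational d.f."""
    meshes = ([_cube_mesh(size=0.01)] if with_meshes else [])
    segments = [SegmentSpec("base", "ground", list(meshes)),
                SegmentSpec("foot", "hinge",
                            [_cube_mesh(size=0.01)] if with_meshes else [])]
    joints = [JointSpec("ground", None, "base", (0, 0, 0), []),
              JointSpec("hinge", "base", "foot", location,
                        [DoF("q", np.asarray(axis, dtype=float), "rotation")])]
    return SkeletonModel(segments, joints, name="hinge_toy")


@pytest.fixture
def hinge_model_factory():
    return _hinge_model
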