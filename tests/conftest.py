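import numpy as np
import pytest
import trimesh

from ctvdelta import PhantomSpec, StructureMask, TriangularMesh, generate_phantom


def tm(primitive: "trimesh.Trimesh") -> TriangularMesh:
    return TriangularMesh.from_trimesh(primitive)


@pytest.fixture(scope="session")
def unit_cube() -> TriangularMesh:
    return tm(trimesh.creation.box(extents=(1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def icosphere_factory():
    def make(radius: float, subdivisions: int = 4) -> TriangularMesh:
        return tm(trimesh.creation.icosphere(subdivisions, radius))

    return make


@pytest.fixture(scope="session")
def default_bundle():
    """One default phantom, shared across tests (generation ~0.5 s)."""
    return generate_phantom(PhantomSpec())


def ball_mask(radius: float, spacing=(1.0, 1.0, 1.0), pad: float = 2.0) -> StructureMask:
    """Voxelized ball centered at the origin (voxel-center convention)."""
    spacing = np.asarray(spacing, dtype=float)
    half = radius + pad
    shape = tuple(int(2 * np.floor(half / s) + 1) for s in spacing)
    origin = -spacing * ((np.asarray(shape) - 1) // 2)
    mask = StructureMask.empty(origin, spacing, shape)
    centers = mask.centers()
    occ = (np.linalg.norm(centers, axis=1) <= radius).reshape(shape)
    return mask.with_occupancy(occ)
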