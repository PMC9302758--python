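"""Shared fixtures: small synthetic faces, FE models and mask loops.

Session-scoped fixtures keep assembly/condensation costs paid once.
"""

import numpy as np
import pytest

from maskfit import (
    MaskDesign,
    NASAL_LIP_EXTRA_ANGLES,
    ShellMaterial,
    SyntheticFaceSpec,
    assemble_stiffness,
    condense,
    generate_synthetic_face,
    reference_loop_on_face,
    sample_mask_nodes,
    select_master_nodes,
)


@pytest.fixture(scope="session")
def face_spec():
    return SyntheticFaceSpec(target_vertex_count=800, seed=1)


@pytest.fixture(scope="session")
def face_mesh(face_spec):
    return generate_synthetic_face(face_spec)


@pytest.fixture(scope="session")
def face_model(face_mesh):
    return assemble_stiffness(face_mesh, ShellMaterial())


@pytest.fixture(scope="session")
def small_spec():
    # ~300 vertices: small enough for brute-force O(N*M) oracles
    return SyntheticFaceSpec(target_vertex_count=300, seed=3)


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return generate_synthetic_face(small_spec)


@pytest.fixture(scope="session")
def small_model(small_mesh):
    return assemble_stiffness(small_mesh, ShellMaterial())


@pytest.fixture(scope="session")
def loop8(face_spec):
    return reference_loop_on_face(face_spec)


@pytest.fixture(scope="session")
def loop12(face_spec):
    return reference_loop_on_face(face_spec, extra_angles=NASAL_LIP_EXTRA_ANGLES)


@pytest.fixture(scope="session")
def mask_nodes8(loop8):
    return sample_mask_nodes(MaskDesign(loop8))


@pytest.fixture(scope="session")
def reduced8(face_mesh, face_model, mask_nodes8):
    masters = select_master_nodes(face_mesh, [mask_nodes8])
    return condense(face_model, masters)


@pytest.fixture(scope="session")
def study_spec():
    # the resolution used for the qualitative fit studies: fine enough that
    # node-to-node pairing noise does not drown the loop-geometry signal
    return SyntheticFaceSpec(target_vertex_count=2000, seed=1)


@pytest.fixture(scope="session")
def study_mesh(study_spec):
    return generate_synthetic_face(study_spec)


@pytest.fixture(scope="session")
def study_model(study_mesh):
    return assemble_stiffness(study_mesh, ShellMaterial())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
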