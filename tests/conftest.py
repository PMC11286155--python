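"""Shared fixtures.

The default calibrated 48-month surrogate and its bite solutions are
expensive (sparse factorizations of ~60k-element meshes), so they are
built once per session and shared.  Property tests that do not depend on
the calibrated ratios use a coarser, cheaper surrogate.
"""

from __future__ import annotations

import numpy as np
import pytest

from cranioload import (
    CohortParams,
    SkullParams,
    SkullModel,
    build_skull_mesh,
    fit_growth,
    generate_csa_cohort,
    run_bite,
)

#: Published mean per-side forces at 48 months (anchor values).
FORCES_48 = {"temporalis": 87.0, "masseter": 69.6, "medial_pterygoid": 58.9}

#: Cheap surrogate for properties that do not need the calibrated ratios.
COARSE = dict(voxel_pitch=4.2, shell_thickness=8.5, arch_radius=4.0)


@pytest.fixture(scope="session")
def skull48():
    return build_skull_mesh(SkullParams(age_months=48))


@pytest.fixture(scope="session")
def model48(skull48):
    return SkullModel(skull48)


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_skull_mesh(SkullParams(age_months=48, **COARSE))


@pytest.fixture(scope="session")
def coarse_model(coarse_mesh):
    return SkullModel(coarse_mesh)


@pytest.fixture(scope="session")
def bites48(model48):
    """Reference bite solutions on the calibrated default surrogate."""
    out = {}
    for mode, fascia in [(1, False), (1, True), (2, False), (3, False)]:
        out[(mode, fascia)] = run_bite(
            model48, mode, fascia, muscle_forces=FORCES_48, keep_fields=True
        )
    return out


@pytest.fixture(scope="session")
def cohort_noisefree():
    return generate_csa_cohort(CohortParams(cv=0.0))


@pytest.fixture(scope="session")
def cohort_default():
    return generate_csa_cohort(CohortParams())


@pytest.fixture(scope="session")
def growth_default(cohort_default):
    return fit_growth(cohort_default, n_boot=0)


@pytest.fixture(scope="session")
def series_default(growth_default):
    """Full factorial age sweep on the default surrogate (slow; shared)."""
    from cranioload import run_series

    return run_series(growth=growth_default)


def mirror_pairs(mesh):
    return mesh.mirror_node_map()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# small structured meshes for FEM unit tests
# ---------------------------------------------------------------------------

_CUBE_TETS = np.array(
    [[0, 3, 5, 6], [1, 0, 3, 5], [2, 3, 0, 6], [4, 5, 6, 0], [7, 6, 5, 3]]
)


def block_mesh(nx, ny, nz, pitch=1.0, label="facial"):
    """Structured tetrahedral block (5 tets per cube cell), all one label."""
    from cranioload.mesh import REGION_LABELS, LabelledTetMesh

    nodes = np.array(
        [
            (i * pitch, j * pitch, k * pitch)
            for i in range(nx + 1)
            for j in range(ny + 1)
            for k in range(nz + 1)
        ],
        dtype=float,
    )

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    offs = [(c & 1, (c >> 1) & 1, (c >> 2) & 1) for c in range(8)]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corners = [nid(i + dx, j + dy, k + dz) for dx, dy, dz in offs]
                table = _CUBE_TETS if (i + j + k) % 2 == 0 else _CUBE_TETS ^ 1
                for t in table:
                    tet = [corners[c] for c in t]
                    a, b, c_, d = (nodes[n] for n in tet)
                    if np.dot(b - a, np.cross(c_ - a, d - a)) < 0:
                        tet[2], tet[3] = tet[3], tet[2]
                    tets.append(tet)
    tets = np.asarray(tets, dtype=np.int64)
    region = np.full(len(tets), REGION_LABELS.index(label), dtype=np.int32)
    return LabelledTetMesh(nodes=nodes, tets=tets, region=region)
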