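"""Small-strain linear-elastic finite elements on labelled tet meshes.

Four-node constant-strain tetrahedra with isotropic Hooke materials in a
mm / N / MPa unit system.  Each element is either cranial *bone* or a
compliant cranial *joint* (suture / fontanelle / synchondrosis) depending
on its region label; both elastic moduli stiffen linearly with age.
Constraints fix all three translations of selected nodes; the constrained
system is solved by sparse direct factorization and reactions are
recovered from the unmodified operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .errors import DomainError, MeshQualityError, SingularSystemError, SolverError
from .mesh import LabelledTetMesh

# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeMaterialModel:
    """Age-dependent isotropic elasticity of infant cranial bone and joints.

    At 3 months bone has E = 421 MPa and joints E = 30 MPa; the moduli
    stiffen linearly at 125 MPa/month (bone, up to 48 months) and
    100 MPa/month (joints, up to 12 months, frozen after).  Poisson ratios
    are 0.22 (bone) and 0.30 (joints).
    """

    e_bone_base: float = 421.0
    e_joint_base: float = 30.0
    bone_rate: float = 125.0   # MPa / month
    joint_rate: float = 100.0  # MPa / month, up to month 12
    nu_bone: float = 0.22
    nu_joint: float = 0.30
    age_anchor: float = 3.0
    joint_freeze_age: float = 12.0

    def at_age(self, age_months: float) -> tuple[float, float, float, float]:
        if not (3.0 <= age_months <= 48.0):
            raise DomainError(f"age {age_months} outside material domain [3, 48] months")
        e_bone = self.e_bone_base + self.bone_rate * (age_months - self.age_anchor)
        e_joint = self.e_joint_base + self.joint_rate * (
            min(age_months, self.joint_freeze_age) - self.age_anchor
        )
        return e_bone, self.nu_bone, e_joint, self.nu_joint


def material_at_age(
    age_months: float, model: AgeMaterialModel | None = None
) -> tuple[float, float, float, float]:
    """(E_bone MPa, nu_bone, E_joint MPa, nu_joint) at the given age."""
    return (model or AgeMaterialModel()).at_age(age_months)


def element_materials(
    mesh: LabelledTetMesh, age_months: float, model: AgeMaterialModel | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (E, nu) arrays from region labels and age."""
    e_bone, nu_bone, e_joint, nu_joint = material_at_age(age_months, model)
    suture = mesh.is_suture()
    E = np.where(suture, e_joint, e_bone)
    nu = np.where(suture, nu_joint, nu_bone)
    return E, nu


def hooke_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (Voigt order xx,yy,zz,xy,yz,zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _element_b_matrices(mesh: LabelledTetMesh) -> tuple[np.ndarray, np.ndarray]:
    """(m, 6, 12) strain-displacement matrices and (m,) volumes."""
    x = mesh.element_coords()  # (m, 4, 3)
    vol = mesh.volumes()
    if np.any(vol <= 0):
        bad = int(np.argmax(vol <= 0))
        raise MeshQualityError(f"inverted element {bad} (volume {vol[bad]:.3g})")
    # gradients of the four linear shape functions: rows of the inverse
    # Jacobian relation; grad N_i constant per element
    e1 = x[:, 1] - x[:, 0]
    e2 = x[:, 2] - x[:, 0]
    e3 = x[:, 3] - x[:, 0]
    J = np.stack([e1, e2, e3], axis=1)           # (m, 3, 3)
    Jinv = np.linalg.inv(J)                       # d(xi)/d(x)
    grads = np.empty((len(vol), 4, 3))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((len(vol), 6, 12))
    for i in range(4):
        gx, gy, gz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def assemble(
    mesh: LabelledTetMesh, E: np.ndarray, nu: np.ndarray
) -> csr_matrix:
    """Global stiffness operator (3n x 3n, MPa*mm = N/mm) from per-element
    isotropic materials.  Symmetric positive-semidefinite; the six rigid
    modes span its null space before constraints."""
    E = np.broadcast_to(np.asarray(E, float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(nu, float), (mesh.n_elements,))
    B, vol = _element_b_matrices(mesh)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((mesh.n_elements, 6, 6))
    C[:, :3, :3] = lam[:, None, None]
    C[:, [0, 1, 2], [0, 1, 2]] += 2 * mu[:, None]
    C[:, [3, 4, 5], [3, 4, 5]] = mu[:, None]
    Ke = np.einsum("eji,ejk,ekl,e->eil", B, C, B, vol, optimize=True)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


# ---------------------------------------------------------------------------
# constraints and solve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSet:
    """Nodes fixed against displacement in all three directions.

    ``roles`` tags each constrained node as a bite point or a TMJ node so
    reactions can be attributed.
    """

    nodes: np.ndarray
    roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = np.unique(np.asarray(self.nodes, dtype=np.int64))
        if nodes.size != np.asarray(self.nodes).size:
            raise DomainError("a node appears twice in the constraint set")
        object.__setattr__(self, "nodes", nodes)

    def check_well_posed(self, coords: np.ndarray) -> None:
        # three non-collinear fully-fixed nodes remove all six rigid modes
        if self.nodes.size < 3:
            raise SingularSystemError("need >= 3 constrained nodes")
        p = coords[self.nodes]
        if np.linalg.matrix_rank(p - p.mean(axis=0)) < 2:
            raise SingularSystemError("constrained nodes are collinear")

    def dof_mask(self, n_nodes: int) -> np.ndarray:
        m = np.zeros(3 * n_nodes, dtype=bool)
        for ax in range(3):
            m[3 * self.nodes + ax] = True
        return m


@dataclass
class Solution:
    """Displacements (mm), reactions (N) and solver diagnostics."""

    u: np.ndarray          # (n, 3)
    reactions: np.ndarray  # (n, 3), nonzero only at constrained nodes
    residual: float        # ||K u - f|| / ||f|| on free dofs
    diagnostics: dict = field(default_factory=dict)


class FactorizedSystem:
    """LU factorization of the constrained stiffness system, reusable
    across load cases (the temporal-fascia balance needs two solves on the
    same operator)."""

    def __init__(self, K: csr_matrix, constraints: ConstraintSet, coords: np.ndarray):
        constraints.check_well_posed(coords)
        self.K = K
        self.constraints = constraints
        self.n_nodes = coords.shape[0]
        self.fixed = constraints.dof_mask(self.n_nodes)
        self.free = ~self.fixed
        Kff = K[self.free][:, self.free].tocsc()
        try:
            # symmetric minimum-degree ordering: ~2.5x less fill than the
            # default COLAMD on these shell meshes
            self.lu = splu(
                Kff, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True}
            )
        except RuntimeError as exc:  # pragma: no cover - singular factorization
            raise SingularSystemError(f"stiffness factorization failed: {exc}") from exc

    def solve(self, loads: np.ndarray) -> Solution:
        f = np.asarray(loads, dtype=float).reshape(-1)
        if f.size != 3 * self.n_nodes:
            raise DomainError("load vector size mismatch")
        uf = self.lu.solve(f[self.free])
        u = np.zeros_like(f)
        u[self.free] = uf
        r = self.K @ u - f
        fnorm = np.linalg.norm(f)
        residual = float(np.linalg.norm(r[self.free]) / fnorm) if fnorm > 0 else 0.0
        if fnorm > 0 and residual > 1e-8:
            raise SolverError(f"residual {residual:.3e} exceeds 1e-8 bound")
        reactions = np.zeros_like(f)
        reactions[self.fixed] = r[self.fixed]
        return Solution(
            u=u.reshape(-1, 3),
            reactions=reactions.reshape(-1, 3),
            residual=residual,
            diagnostics={"method": "splu", "n_free_dof": int(self.free.sum())},
        )


def solve(K: csr_matrix, loads: np.ndarray, constraints: ConstraintSet,
          coords: np.ndarray) -> Solution:
    """One-shot constrained solve (factorize + solve)."""
    return FactorizedSystem(K, constraints, coords).solve(loads)


# ---------------------------------------------------------------------------
# strain / stress recovery
# ---------------------------------------------------------------------------


@dataclass
class FieldResult:
    """Per-element constant strain/stress tensors and von Mises scalars.

    Voigt component order is (xx, yy, zz, xy, yz, zx); strains are
    dimensionless (engineering shear), stresses MPa.  ``vm_strain`` is the
    von Mises *equivalent* strain reported in microstrain.
    """

    strain: np.ndarray      # (m, 6)
    stress: np.ndarray      # (m, 6)
    vm_stress: np.ndarray   # (m,) MPa
    vm_strain: np.ndarray   # (m,) microstrain


def _principal(tensors: np.ndarray) -> np.ndarray:
    """Principal values of symmetric tensors given in Voigt order."""
    m = tensors.shape[0]
    T = np.empty((m, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = tensors[:, 0], tensors[:, 1], tensors[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = tensors[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = tensors[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = tensors[:, 5]
    return np.linalg.eigvalsh(T)


def von_mises_from_principal(p: np.ndarray) -> np.ndarray:
    d1 = p[:, 0] - p[:, 1]
    d2 = p[:, 1] - p[:, 2]
    d3 = p[:, 2] - p[:, 0]
    return np.sqrt(0.5 * (d1**2 + d2**2 + d3**2))


def strain_stress(
    mesh: LabelledTetMesh,
    E: np.ndarray,
    nu: np.ndarray,
    solution: Solution,
    strain_nu_effective: float | None = None,
) -> FieldResult:
    """Recover element strain/stress tensors and von Mises scalars.

    Strain uses the constant-strain-tet relation eps = B u_e; stress the
    element Hooke matrix.  The von Mises equivalent strain divides by
    (1 + nu'), with nu' the element material Poisson ratio by default
    (``strain_nu_effective`` overrides it, e.g. 0.5).
    """
    E = np.broadcast_to(np.asarray(E, float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(nu, float), (mesh.n_elements,))
    B, _ = _element_b_matrices(mesh)
    ue = solution.u[mesh.tets].reshape(mesh.n_elements, 12)
    strain = np.einsum("eij,ej->ei", B, ue)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = strain[:, :3].sum(axis=1)
    stress = np.empty_like(strain)
    stress[:, :3] = lam[:, None] * tr[:, None] + 2 * mu[:, None] * strain[:, :3]
    stress[:, 3:] = mu[:, None] * strain[:, 3:]  # engineering shear

    vm_stress = von_mises_from_principal(_principal(stress))
    # principal strains: shear components are engineering -> tensor = /2
    eps_t = strain.copy()
    eps_t[:, 3:] *= 0.5
    nu_eff = nu if strain_nu_effective is None else np.full_like(nu, strain_nu_effective)
    vm_eps = von_mises_from_principal(_principal(eps_t)) / (1.0 + nu_eff)
    return FieldResult(
        strain=strain,
        stress=stress,
        vm_stress=vm_stress,
        vm_strain=vm_eps * 1e6,
    )
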