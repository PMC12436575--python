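"""Small-strain linear-elastic FE solver (plane strain, linear triangles).

Constitutive model per element, in Voigt notation with engineering shear:

    sigma_in = D_ps (eps_in - eps*_in) + lambda (eps_z - eps*_z) [1, 1, 0]
    sigma_zz = lambda tr(eps_mech) + 2 mu (eps_z - eps*_z)

where ``eps*`` is a prescribed eigenstrain (hygroscopic swelling, thermal,
...) with an out-of-plane component, and ``eps_z`` is a uniform prescribed
axial strain (generalized plane strain; 0 for ordinary plane strain).  The
out-of-plane coupling matters: a fully constrained isotropic eigenstrain
eps0 produces the hydrostatic stress -E eps0 / (1 - 2 nu), and a prescribed
eps_z with free in-plane relaxation reproduces the apparent axial modulus of
a prismatic body, so axial compression tests reduce to 2D solves.

Units are mm / MPa / N throughout; strain-energy density then comes out in
J/cm^3 numerically equal to (stress x strain)/2 in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .porous_geometry import FEMesh

__all__ = [
    "MaterialState",
    "LoadCase",
    "FieldSolution",
    "assemble_and_solve",
    "element_sed",
    "FEMError",
]


class FEMError(RuntimeError):
    """Singular or non-finite finite-element solve."""


@dataclass
class MaterialState:
    """Per-element apparent density, modulus and Poisson ratio.

    density : g/cm^3 (the remodeling state variable)
    elastic_modulus : MPa
    poisson_ratio : dimensionless, per element
    """

    density: np.ndarray
    elastic_modulus: np.ndarray
    poisson_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.elastic_modulus = np.asarray(self.elastic_modulus, dtype=float)
        self.poisson_ratio = np.asarray(self.poisson_ratio, dtype=float)
        if np.any(self.elastic_modulus <= 0):
            raise ValueError("elastic modulus must be positive")

    def lame(self) -> tuple[np.ndarray, np.ndarray]:
        E, nu = self.elastic_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


@dataclass
class LoadCase:
    """Loading: boundary pressures, eigenstrain field, prescribed axial strain.

    pressure : mapping boundary-set name -> magnitude (MPa); positive values
        push inward along the outward normal of each edge (compression).
    eigenstrain : (M, 4) array [exx, eyy, ezz, exy(tensor)] or None.
    axial_strain : uniform prescribed out-of-plane strain eps_z.
    """

    pressure: dict = field(default_factory=dict)
    eigenstrain: np.ndarray | None = None
    axial_strain: float = 0.0


@dataclass
class FieldSolution:
    """FE solution fields on one mesh.

    stress is (M, 4): [sxx, syy, szz, sxy]; strain is the total in-plane
    strain (M, 3) [exx, eyy, gxy]; mech_strain subtracts the eigenstrain
    (and includes the zz component, (M, 4)); sed is U = 1/2 sigma : eps_mech
    per element in J/cm^3.
    """

    mesh: FEMesh
    displacement: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    mech_strain: np.ndarray
    sed: np.ndarray
    external_work: float


def _b_matrices(mesh: FEMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element CST strain-displacement matrices B (M, 3, 6) and areas."""
    p = mesh.nodes[mesh.elems]  # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    det = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    area = 0.5 * det  # positive for CCW node ordering
    M = mesh.n_elems
    B = np.zeros((M, 3, 6))
    inv2A = 1.0 / det
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i] * inv2A
        B[:, 1, 2 * i + 1] = c[:, i] * inv2A
        B[:, 2, 2 * i] = c[:, i] * inv2A
        B[:, 2, 2 * i + 1] = b[:, i] * inv2A
    return B, np.abs(area)


def _d_matrices(lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    M = len(lam)
    D = np.zeros((M, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = lam + 2 * mu
    D[:, 0, 1] = D[:, 1, 0] = lam
    D[:, 2, 2] = mu
    return D


def _fixed_dofs(mesh: FEMesh, fixed_sets: tuple[str, ...]) -> np.ndarray:
    fixed = np.zeros(2 * mesh.n_nodes, dtype=bool)
    for name in fixed_sets:
        rec = mesh.boundary_sets.get(name)
        if rec is None or len(rec) == 0:
            continue
        nodes = np.unique(np.concatenate([rec.n0, rec.n1]))
        if name == "SYM_X":       # symmetry plane y = 0: u_y = 0
            fixed[2 * nodes + 1] = True
        elif name == "SYM_Y":     # symmetry plane x = 0: u_x = 0
            fixed[2 * nodes] = True
        else:                     # any other named set: fully clamped
            fixed[2 * nodes] = True
            fixed[2 * nodes + 1] = True
    return fixed


def _pressure_forces(mesh: FEMesh, pressure: dict) -> np.ndarray:
    f = np.zeros(2 * mesh.n_nodes)
    cent = mesh.centroids
    t = mesh.thickness
    for name, p in pressure.items():
        if p == 0.0:
            continue
        rec = mesh.boundary_sets[name]
        a = mesh.nodes[rec.n0]
        b = mesh.nodes[rec.n1]
        mid = 0.5 * (a + b)
        tang = b - a
        L = np.hypot(tang[:, 0], tang[:, 1])
        nrm = np.column_stack([tang[:, 1], -tang[:, 0]]) / L[:, None]
        # orient outward (away from the owning element centroid)
        flip = np.einsum("ij,ij->i", nrm, mid - cent[rec.elem]) < 0
        nrm[flip] *= -1
        # pressure acts against the outward normal
        fe = -p * nrm * (L * t / 2.0)[:, None]
        np.add.at(f, 2 * rec.n0, fe[:, 0])
        np.add.at(f, 2 * rec.n0 + 1, fe[:, 1])
        np.add.at(f, 2 * rec.n1, fe[:, 0])
        np.add.at(f, 2 * rec.n1 + 1, fe[:, 1])
    return f


def assemble_and_solve(
    mesh: FEMesh,
    mat: MaterialState,
    load: LoadCase,
    fixed_sets: tuple[str, ...] = ("SYM_X", "SYM_Y"),
) -> FieldSolution:
    """Assemble the plane-strain system, apply loads and BCs, and solve.

    Raises :class:`FEMError` on a singular system (insufficient constraints)
    or non-finite results.
    """
    B, area = _b_matrices(mesh)
    lam, mu = mat.lame()
    D = _d_matrices(lam, mu)
    t = mesh.thickness
    w = (area * t)  # integration weight per element

    Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, w)  # (M, 6, 6)
    dofs = np.empty((mesh.n_elems, 6), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elems
    dofs[:, 1::2] = 2 * mesh.elems + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    K = coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes,) * 2
    ).tocsc()

    f = _pressure_forces(mesh, load.pressure)
    eig = load.eigenstrain
    ez = load.axial_strain
    if eig is not None or ez != 0.0:
        if eig is None:
            eig = np.zeros((mesh.n_elems, 4))
        e_in = np.column_stack([eig[:, 0], eig[:, 1], 2.0 * eig[:, 3]])
        sigma0 = np.einsum("mij,mj->mi", D, e_in)
        sigma0[:, 0] += lam * (eig[:, 2] - ez)
        sigma0[:, 1] += lam * (eig[:, 2] - ez)
        fe = np.einsum("mji,mj,m->mi", B, sigma0, w)
        np.add.at(f, dofs.ravel(), fe.ravel())
    else:
        eig = np.zeros((mesh.n_elems, 4))

    fixed = _fixed_dofs(mesh, fixed_sets)
    free = ~fixed
    try:
        lu = splu(K[free][:, free])
        u_free = lu.solve(f[free])
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise FEMError(f"singular system: {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise FEMError("non-finite displacement solution (ill-conditioned input)")
    resid = np.linalg.norm(K[free][:, free] @ u_free - f[free])
    fnorm = np.linalg.norm(f[free])
    if fnorm > 0 and resid > 1e-6 * fnorm:
        raise FEMError(
            f"singular or ill-conditioned system (relative residual {resid / fnorm:.2e}); "
            "check boundary constraints")
    u = np.zeros(2 * mesh.n_nodes)
    u[free] = u_free

    ue = u[dofs]  # (M, 6)
    strain = np.einsum("mij,mj->mi", B, ue)  # total in-plane, engineering shear
    em_in = strain - np.column_stack([eig[:, 0], eig[:, 1], 2.0 * eig[:, 3]])
    em_zz = ez - eig[:, 2]
    stress = np.empty((mesh.n_elems, 4))
    s_in = np.einsum("mij,mj->mi", D, em_in)
    s_in[:, 0] += lam * em_zz
    s_in[:, 1] += lam * em_zz
    stress[:, 0] = s_in[:, 0]
    stress[:, 1] = s_in[:, 1]
    stress[:, 3] = s_in[:, 2]
    stress[:, 2] = lam * (em_in[:, 0] + em_in[:, 1] + em_zz) + 2 * mu * em_zz

    mech = np.column_stack([em_in[:, 0], em_in[:, 1], em_zz, em_in[:, 2]])
    sed = 0.5 * (
        stress[:, 0] * mech[:, 0]
        + stress[:, 1] * mech[:, 1]
        + stress[:, 2] * mech[:, 2]
        + stress[:, 3] * mech[:, 3]  # tau * gamma
    )
    sed = np.maximum(sed, 0.0)  # clip O(eps) negatives from round-off

    sol = FieldSolution(
        mesh=mesh,
        displacement=u.reshape(-1, 2),
        stress=stress,
        strain=strain,
        mech_strain=mech,
        sed=sed,
        external_work=float(0.5 * (_pressure_forces(mesh, load.pressure) @ u)),
    )
    return sol


def element_sed(solution: FieldSolution) -> np.ndarray:
    """Per-element strain-energy density U (J/cm^3).

    U is computed with the mechanical strain (total minus eigenstrain)
    conjugate to the stress, so a stress-free swollen state stores no energy.
    """
    return solution.sed


def stored_energy(solution: FieldSolution) -> float:
    """Total stored elastic energy  sum(U V)  in mJ (MPa mm^3)."""
    return float(solution.sed @ solution.mesh.volumes)
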