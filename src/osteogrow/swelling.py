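"""Hygro-elastic swelling of the constrained anchor.

Moisture uptake of the MMA/AA co-polymer is modelled as an isotropic
eigenstrain eps_hs = beta_h (alpha_m - alpha_m,ref) imposed on the anchor
matrix (equilibrium moisture content; no diffusion PDE).  Embedded in a
stiffer bone layer the swelling is constrained, which compresses the
bone-anchor interface radially and puts the surrounding bone ring into
hoop tension — the expansion-fit fixation mechanism.  The area-averaged
radial interface stress is the single load handed to the ingrowth stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem_core import FieldSolution, LoadCase, MaterialState, assemble_and_solve
from .porous_geometry import ANCHOR, BONE, VOID, FEMesh

__all__ = [
    "SwellingParams",
    "InterfaceStressResult",
    "hygroscopic_strain",
    "simulate_constrained_swelling",
    "average_radial_stress",
]

#: Table defaults for the 85/15 MMA/AA co-polymer and surrounding bone.
DEFAULT_BONE_E = 1940.48     # MPa
DEFAULT_BONE_NU = 0.34
DEFAULT_DUMMY_E = 0.05       # MPa, initial void (dummy) stiffness
DEFAULT_DUMMY_NU = 0.3


@dataclass
class SwellingParams:
    """Hygroscopic swelling parameters of the anchor co-polymer.

    beta_h : m^3/kg — swelling coefficient (isotropic unless a 3-tuple).
    moisture / moisture_ref : kg/m^3 — equilibrium and reference moisture.
    E_dry / E_wet : MPa — anchor modulus before/after moisture uptake.
    ramp_iterations : time constant (in remodeling iterations) of the
        exponential load ramp used downstream by the ingrowth stage.
    """

    beta_h: float | tuple[float, float, float] = 0.9920
    moisture: float = 0.08672
    moisture_ref: float = 0.0
    E_dry: float = 479.0
    E_wet: float = 433.0
    nu: float = 0.25
    ramp_iterations: int = 10

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta_h, dtype=float))
        if np.any(beta < 0):
            raise ValueError("beta_h must be non-negative")
        if self.moisture < self.moisture_ref or self.moisture_ref < 0:
            raise ValueError("moisture >= moisture_ref >= 0 required")


def hygroscopic_strain(params: SwellingParams) -> np.ndarray:
    """Eigenstrain 4-vector [exx, eyy, ezz, exy] from moisture uptake.

    Isotropic beta gives beta (alpha_m - alpha_ref) on the diagonal and zero
    shear; an anisotropic 3-tuple beta is applied componentwise.
    """
    d_alpha = params.moisture - params.moisture_ref
    beta = np.asarray(params.beta_h, dtype=float)
    if beta.ndim == 0:
        e = float(beta) * d_alpha
        return np.array([e, e, e, 0.0])
    if beta.shape != (3,):
        raise ValueError("beta_h must be a scalar or a 3-tuple")
    exx, eyy, ezz = beta * d_alpha
    return np.array([exx, eyy, ezz, 0.0])


def default_material(mesh: FEMesh, params: SwellingParams, *,
                     wet: bool = True,
                     bone_E: float = DEFAULT_BONE_E,
                     bone_nu: float = DEFAULT_BONE_NU,
                     dummy_E: float = DEFAULT_DUMMY_E,
                     dummy_nu: float = DEFAULT_DUMMY_NU) -> MaterialState:
    """Region-wise material state: wet/dry anchor, dummy voids, bone."""
    E = np.full(mesh.n_elems, params.E_wet if wet else params.E_dry)
    nu = np.full(mesh.n_elems, params.nu)
    rho = np.full(mesh.n_elems, 1.2)  # co-polymer, inert for remodeling
    E[mesh.region == VOID] = dummy_E
    nu[mesh.region == VOID] = dummy_nu
    rho[mesh.region == VOID] = 0.01
    E[mesh.region == BONE] = bone_E
    nu[mesh.region == BONE] = bone_nu
    rho[mesh.region == BONE] = 0.8
    return MaterialState(rho, E, nu)


def simulate_constrained_swelling(
    mesh: FEMesh,
    params: SwellingParams,
    mat: MaterialState | None = None,
    planar: bool = False,
) -> FieldSolution:
    """Solve the constrained-swelling load case on a full (anchor+bone) mesh.

    The hygroscopic eigenstrain is imposed in ANCHOR elements only, with the
    wet modulus; symmetry boundary conditions on the quarter-model axes; the
    outer bone surface is free.  With ``planar=True`` the out-of-plane
    eigenstrain component is dropped (pure in-plane swelling — useful for
    free-swelling verification).
    """
    if mat is None:
        mat = default_material(mesh, params, wet=True)
    e = hygroscopic_strain(params)
    if planar:
        e = e.copy()
        e[2] = 0.0
    eig = np.zeros((mesh.n_elems, 4))
    eig[mesh.region == ANCHOR] = e
    return assemble_and_solve(mesh, mat, LoadCase(eigenstrain=eig))


@dataclass
class InterfaceStressResult:
    """Average radial stress over the bone-anchor interface.

    ``samples``/``face_areas`` hold the per-face radial stress (MPa) and
    face areas (mm^2); ``mean_radial_stress`` is their area-weighted mean
    (negative = compression on the anchor).
    """

    mean_radial_stress: float
    interface_area: float
    samples: np.ndarray
    face_areas: np.ndarray


def average_radial_stress(
    solution: FieldSolution, interface_set: str = "INTERFACE"
) -> InterfaceStressResult:
    """Area-weighted mean of sigma_rr = e_r . sigma . e_r over interface faces.

    Each face sample averages the constant element stresses on its two sides
    (or uses the single owner for a boundary interface) and projects onto the
    radial direction at the face midpoint.
    """
    mesh = solution.mesh
    rec = mesh.boundary_sets.get(interface_set)
    if rec is None or len(rec) == 0:
        raise ValueError(f"empty interface set {interface_set!r}")
    a, b = mesh.nodes[rec.n0], mesh.nodes[rec.n1]
    mid = 0.5 * (a + b)
    L = np.hypot(*(b - a).T)
    r = np.hypot(mid[:, 0], mid[:, 1])
    r = np.where(r < 1e-12, 1e-12, r)
    er = mid / r[:, None]
    s = solution.stress[rec.elem]
    if "elem_out" in (rec.dtype.names or ()):
        s = 0.5 * (s + solution.stress[rec.elem_out])
    srr = (
        s[:, 0] * er[:, 0] ** 2
        + s[:, 1] * er[:, 1] ** 2
        + 2.0 * s[:, 3] * er[:, 0] * er[:, 1]
    )
    areas = L * mesh.thickness
    total = areas.sum()
    return InterfaceStressResult(
        mean_radial_stress=float((srr * areas).sum() / total),
        interface_area=float(total),
        samples=srr,
        face_areas=areas,
    )
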