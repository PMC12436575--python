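"""Post-ingrowth mechanical characterization.

Two assessments mirror the physical testing of swelling bone anchors:

* **Axial compression stiffness** — the apparent modulus of the porous
  (and later, partially bone-filled) anchor under displacement-controlled
  axial compression.  Solved as a generalized-plane-strain problem: a
  uniform axial strain is prescribed on the cross-section, in-plane
  relaxation is free, and the slope is the area-averaged axial stress over
  the applied strain.  A homogeneous prism recovers its modulus E exactly.

* **Push-out** — displacement-controlled axial extraction of the anchor
  from its bone layer.  The anchor translates axially as a rigid body;
  interface faces resist through Coulomb friction (anchor-bone contact
  under the held swelling pressure) and, post-ingrowth, through
  elastic-plastic shear of the newly formed bone bridging the pore throats,
  with Johnson-Cook hardening (sigma_y = A + B eps^n) and erosion of faces
  whose plastic strain exceeds a threshold.  Eroded faces drop out of the
  load path, so after complete interface failure the reaction decays to the
  frictional floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem_core import LoadCase, MaterialState, assemble_and_solve
from .ingrowth import density_to_modulus
from .porous_geometry import ANCHOR, VOID, FEMesh

__all__ = [
    "JCParams",
    "PushoutResult",
    "compression_stiffness",
    "jc_yield_stress",
    "pushout",
]


@dataclass
class JCParams:
    """Quasi-static isothermal Johnson-Cook hardening for newly formed bone.

    A (initial yield strength) and B_h (hardening modulus) are in GPa, as
    conventionally tabulated; n is the hardening exponent.  erosion_strain
    is the equivalent plastic strain at which an element/face is deleted
    from the load-bearing system.
    """

    A: float = 0.05      # GPa
    B_h: float = 0.1     # GPa
    n: float = 0.08
    erosion_strain: float = 0.03  # bone fails at a few percent plastic strain

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B_h < 0:
            raise ValueError("A must be positive and B_h non-negative")
        if not (0 < self.n <= 1):
            raise ValueError("n must lie in (0, 1]")


def jc_yield_stress(plastic_strain, params: JCParams):
    """sigma_y = A + B eps^n in GPa (eps = 0 returns A)."""
    eps = np.asarray(plastic_strain, dtype=float)
    if np.any(eps < 0):
        raise ValueError("plastic strain must be non-negative")
    out = params.A + params.B_h * np.power(eps, params.n)
    return float(out) if np.ndim(plastic_strain) == 0 else out


def compression_stiffness(
    mesh: FEMesh,
    mat: MaterialState,
    strain_level: float = 1e-3,
) -> float:
    """Apparent axial modulus (MPa): mean axial stress / applied axial strain.

    A uniform compressive axial strain is prescribed (generalized plane
    strain); symmetry conditions act on the quarter-model axes and the
    lateral surface is free.
    """
    sol = assemble_and_solve(
        mesh, mat, LoadCase(axial_strain=-abs(strain_level)))
    mean_szz = float((sol.stress[:, 2] * mesh.areas).sum() / mesh.areas.sum())
    return -mean_szz / abs(strain_level)


@dataclass
class PushoutResult:
    """Force-displacement record of a push-out simulation."""

    displacement: np.ndarray   # mm
    force: np.ndarray          # N
    peak_force: float          # N
    friction_floor: float      # N  (Coulomb capacity of the contact faces)
    eroded_face_elems: np.ndarray  # element ids whose bond faces eroded
    n_contact_faces: int
    n_bond_faces: int

    @property
    def dissipated_energy(self) -> float:
        """Area under the force-displacement curve, N mm (mJ)."""
        return float(np.trapezoid(self.force, self.displacement))


def _strength_scale(rho: np.ndarray, rho_bone: float = 0.8) -> np.ndarray:
    """Density-squared strength scaling for immature bone, capped at 1."""
    return np.minimum(1.0, (rho / rho_bone) ** 2)


def pushout(
    mesh: FEMesh,
    rho: np.ndarray,
    interface_pressure: float,
    friction_mu: float = 0.4,
    jc: JCParams | None = None,
    max_displacement: float = 0.5,
    mode: str = "pre",
    rho_initial: np.ndarray | None = None,
    n_steps: int = 500,
    nu_interface: float = 0.3,
    process_zone: float | None = None,
    interface_set: str = "INTERFACE",
) -> PushoutResult:
    """Displacement-controlled push-out of the anchor from the bone layer.

    ``mesh`` is the full (anchor + void + bone) mesh; ``rho`` the per-element
    density state (initial densities for ``mode='pre'``, post-ingrowth
    densities for ``mode='post'``).  The held swelling pressure
    ``interface_pressure`` (magnitude, MPa) acts as the normal contact
    pressure on the anchor-bone contact faces, giving a transmitted normal
    force N = p x A_contact whose Coulomb capacity mu N is mobilised through
    an elastic stick stiffness.  Face areas are rescaled from the rasterised
    staircase to the smooth quarter arc (A = pi/2 R t).  In post mode, interface faces owned by grown
    void elements are bonded: they carry elastic-plastic shear with JC
    hardening, strength scaled by min(1, (rho/0.8)^2), and erode at the JC
    erosion strain, after which they carry nothing (an open pore throat
    transmits no pressure).
    """
    if jc is None:
        jc = JCParams()
    if mode not in ("pre", "post"):
        raise ValueError("mode must be 'pre' or 'post'")
    rec = mesh.boundary_sets[interface_set]
    if len(rec) == 0:
        raise ValueError("mesh has no interface faces")
    if rho_initial is None:
        rho_initial = np.where(mesh.region == VOID, 0.01, rho)
    h = process_zone or mesh.element_size

    a, b = mesh.nodes[rec.n0], mesh.nodes[rec.n1]
    L = np.hypot(*(b - a).T)
    region = mesh.region[rec.elem]
    t = mesh.thickness

    # smooth-geometry interface area; the rasterised staircase length
    # overestimates the true arc length by ~4/pi
    if mesh.anchor_radius is not None:
        A_arc = 0.5 * np.pi * mesh.anchor_radius * t
    else:
        A_arc = float(L.sum() * t)
    scale = A_arc / float(L.sum() * t)

    contact = region == ANCHOR
    A_contact = float((L[contact].sum()) * t * scale)
    # the held swelling pressure acts as the contact pressure on the faces
    # where anchor material actually touches bone; open pore mouths carry none
    N_normal = abs(interface_pressure) * A_contact
    F_slip = friction_mu * N_normal
    # elastic stick stiffness of the contact patch (shear-lag penalty)
    G_anchor = 433.0 / (2 * (1 + 0.25))
    K_stick = G_anchor / h * max(A_contact, 1e-12)

    bond = np.zeros(len(rec), dtype=bool)
    if mode == "post":
        grown = (mesh.region[rec.elem] == VOID) & (
            rho[rec.elem] > rho_initial[rec.elem] + 1e-12)
        bond = grown
    bond_ids = np.where(bond)[0]
    rho_b = rho[rec.elem[bond_ids]]
    A_b = L[bond_ids] * t * scale
    G_b = density_to_modulus(rho_b) / (2 * (1 + nu_interface))
    k_b = G_b / h * A_b                      # N/mm per face
    tau_y0 = 1000.0 * jc.A / np.sqrt(3.0)    # MPa, von Mises shear yield
    s_b = _strength_scale(rho_b)

    disp = np.linspace(0.0, max_displacement, n_steps + 1)
    force = np.zeros_like(disp)
    u_p = np.zeros(len(bond_ids))
    alive = np.ones(len(bond_ids), dtype=bool)

    for i, u in enumerate(disp):
        F_fric = min(K_stick * u, F_slip) if F_slip > 0 else 0.0
        F_bond = 0.0
        if len(bond_ids):
            tau_trial = k_b * (u - u_p) / np.maximum(A_b, 1e-12)
            eps_p = u_p / h
            tau_yield = s_b * 1000.0 * jc_yield_stress(eps_p, jc) / np.sqrt(3.0)
            yielding = alive & (tau_trial > tau_yield)
            # radial return on each yielded face
            du_p = (tau_trial[yielding] - tau_yield[yielding]) * A_b[yielding] / k_b[yielding]
            u_p[yielding] += du_p
            eps_p = u_p / h
            newly_dead = alive & (eps_p >= jc.erosion_strain)
            alive &= ~newly_dead
            tau = np.where(alive, k_b * (u - u_p) / np.maximum(A_b, 1e-12), 0.0)
            F_bond = float((tau * A_b)[alive].sum())
        force[i] = F_fric + F_bond

    return PushoutResult(
        displacement=disp,
        force=force,
        peak_force=float(force.max()),
        friction_floor=float(F_slip),
        eroded_face_elems=rec.elem[bond_ids[~alive]] if len(bond_ids) else np.empty(0, int),
        n_contact_faces=int(contact.sum()),
        n_bond_faces=int(bond.sum()),
    )
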