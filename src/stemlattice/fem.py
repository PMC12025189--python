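"""Linear elasto-static plane-strain FEM on quadrilateral meshes.

Bilinear 4-node quads with full 2x2 Gauss quadrature; the Young's modulus is
supplied per integration point (the remodeling state lives there), Poisson's
ratio is uniform.  The global system K u = f is assembled sparse and solved
by direct factorization.  Out-of-plane strain is zero; sigma_zz is recovered
as nu*(sigma_xx + sigma_yy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import LoadCase, QuadMesh, _GAUSS_XI, _shape_derivs

__all__ = [
    "FemResult",
    "plane_strain_constitutive",
    "von_mises_stress",
    "von_mises_strain",
    "solve",
]


@dataclass
class FemResult:
    """Solution fields of one elasto-static solve.

    Strain stores the tensorial shear component eps_xy (= gamma_xy / 2);
    stress stores (sxx, syy, szz, txy) in MPa.  ``reaction_force`` is the
    total (Rx, Ry) on the fixed node set; ``load_reaction`` the force
    conjugate to the load node (nonzero under imposed displacement).
    """

    displacements: np.ndarray       # (n_nodes, 2) mm
    strain: np.ndarray              # (n_ip, 3): exx, eyy, exy(tensorial)
    stress: np.ndarray              # (n_ip, 4): sxx, syy, szz, txy
    von_mises_stress: np.ndarray    # (n_ip,) MPa
    von_mises_strain: np.ndarray    # (n_ip,)
    reaction_force: tuple[float, float]
    load_reaction: tuple[float, float]
    external_work: float            # f . u (N mm)
    strain_energy: float            # 0.5 u^T K u (N mm)


def plane_strain_constitutive(E: float, nu: float) -> np.ndarray:
    """Isotropic plane-strain constitutive matrix (Voigt: xx, yy, xy)."""
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    if E < 0:
        raise ValueError("Young's modulus must be non-negative")
    c = E / ((1 + nu) * (1 - 2 * nu))
    return c * np.array(
        [[1 - nu, nu, 0.0], [nu, 1 - nu, 0.0], [0.0, 0.0, (1 - 2 * nu) / 2]]
    )


def von_mises_stress(sxx, syy, szz=0.0, txy=0.0, tyz=0.0, tzx=0.0):
    """Equivalent von Mises stress from full stress components."""
    sxx, syy, szz, txy = np.broadcast_arrays(sxx, syy, szz, txy)
    return np.sqrt(
        ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2
         + 6.0 * (np.asarray(txy) ** 2 + np.asarray(tyz) ** 2 + np.asarray(tzx) ** 2)) / 2.0
    )


def von_mises_strain(exx, eyy, ezz=0.0, exy=0.0, eyz=0.0, ezx=0.0):
    """Equivalent (deviatoric) von Mises strain from tensorial components.

    The 2/3 prefactor makes the measure reduce to the axial strain for an
    incompressible uniaxial state (e, -e/2, -e/2).
    """
    exx, eyy, ezz, exy = np.broadcast_arrays(exx, eyy, ezz, exy)
    return (2.0 / 3.0) * np.sqrt(
        ((exx - eyy) ** 2 + (eyy - ezz) ** 2 + (ezz - exx) ** 2
         + 6.0 * (np.asarray(exy) ** 2 + np.asarray(eyz) ** 2 + np.asarray(ezx) ** 2)) / 2.0
    )


def _invert_2x2(J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    invJ = np.empty_like(J)
    invJ[..., 0, 0] = J[..., 1, 1]
    invJ[..., 1, 1] = J[..., 0, 0]
    invJ[..., 0, 1] = -J[..., 0, 1]
    invJ[..., 1, 0] = -J[..., 1, 0]
    invJ /= detJ[..., None, None]
    return invJ, detJ


def _element_matrices(mesh: QuadMesh):
    """Per-ip compatible (B) and incompatible-mode (Ba) strain matrices.

    The incompatible modes are Wilson's quadratic bubbles (1 - xi^2),
    (1 - eta^2) with the Taylor patch-test correction: their gradients are
    mapped with the element-center Jacobian and the volume-weighted mean is
    subtracted so constant-stress states produce no enhanced strain.
    Cached on the mesh.
    """
    cache = mesh.meta.get("_fem_cache")
    if cache is not None:
        return cache
    xy = mesh.nodes[mesh.elements]           # (n_e, 4, 2)
    n_e = len(xy)
    J0 = np.einsum("ak,nkb->nab", _shape_derivs(0.0, 0.0), xy)
    invJ0, _ = _invert_2x2(J0)
    B_all, Ba_all, detJ_all = [], [], []
    for xi, eta in _GAUSS_XI:
        dN = _shape_derivs(xi, eta)          # (2, 4)
        J = np.einsum("ak,nkb->nab", dN, xy)  # (n_e, 2, 2)
        invJ, detJ = _invert_2x2(J)
        dNdx = np.einsum("nab,bk->nak", invJ, dN)  # (n_e, 2, 4)
        B = np.zeros((n_e, 3, 8))
        B[:, 0, 0::2] = dNdx[:, 0, :]
        B[:, 1, 1::2] = dNdx[:, 1, :]
        B[:, 2, 0::2] = dNdx[:, 1, :]
        B[:, 2, 1::2] = dNdx[:, 0, :]
        # bubble gradients via the center Jacobian: d/dxi(1-xi^2) = -2 xi
        dM = np.array([[-2.0 * xi, 0.0], [0.0, -2.0 * eta]])  # (mode, xi/eta)
        dMdx = np.einsum("nab,mb->nma", invJ0, dM)            # (n_e, 2modes, 2)
        Ba = np.zeros((n_e, 3, 4))
        Ba[:, 0, 0] = dMdx[:, 0, 0]
        Ba[:, 1, 1] = dMdx[:, 0, 1]
        Ba[:, 2, 0] = dMdx[:, 0, 1]
        Ba[:, 2, 1] = dMdx[:, 0, 0]
        Ba[:, 0, 2] = dMdx[:, 1, 0]
        Ba[:, 1, 3] = dMdx[:, 1, 1]
        Ba[:, 2, 2] = dMdx[:, 1, 1]
        Ba[:, 2, 3] = dMdx[:, 1, 0]
        B_all.append(B)
        Ba_all.append(Ba)
        detJ_all.append(detJ)
    B = np.stack(B_all, axis=1)              # (n_e, 4, 3, 8)
    Ba = np.stack(Ba_all, axis=1)            # (n_e, 4, 3, 4)
    detJ = np.stack(detJ_all, axis=1)        # (n_e, 4)
    mean = np.einsum("ngia,ng->nia", Ba, detJ) / detJ.sum(axis=1)[:, None, None]
    Ba = Ba - mean[:, None, :, :]
    cache = (B, Ba, detJ)
    mesh.meta["_fem_cache"] = cache
    return cache


def solve(
    mesh: QuadMesh,
    load: LoadCase,
    youngs_ip: np.ndarray,
    nu: float = 0.3,
    thickness: float = 35.0,
    element: str = "incompatible",
) -> FemResult:
    """Solve the plane-strain problem with per-integration-point modulus.

    Parameters
    ----------
    youngs_ip : array (n_ip,) or scalar
        Young's modulus at each integration point, MPa.
    thickness : float
        Plane-strain thickness, mm (scales stiffness and forces alike).
    element : {"incompatible", "bilinear"}
        "incompatible" (default) augments the bilinear quad with Wilson/
        Taylor incompatible bending modes (statically condensed), removing
        the parasitic shear stiffness that makes plain Q4 elements lock in
        bending; "bilinear" is the bare displacement element.
    """
    if element not in ("incompatible", "bilinear"):
        raise ValueError("element must be 'incompatible' or 'bilinear'")
    n_dof = 2 * mesh.n_nodes
    E_ip = np.broadcast_to(np.asarray(youngs_ip, dtype=float), (mesh.n_ip,))
    E_eg = E_ip.reshape(mesh.n_elements, 4)

    B, Ba, detJ = _element_matrices(mesh)
    D0 = plane_strain_constitutive(1.0, nu)  # modulus factored out (uniform nu)
    w = E_eg * detJ * thickness              # (n_e, 4)
    ke = np.einsum("ngia,ij,ngjb->nab", B, D0, B * w[:, :, None, None])
    if element == "incompatible":
        Kua = np.einsum("ngia,ij,ngjb->nab", B, D0, Ba * w[:, :, None, None])
        Kaa = np.einsum("ngia,ij,ngjb->nab", Ba, D0, Ba * w[:, :, None, None])
        Kaa_inv = np.linalg.inv(Kaa)
        ke = ke - np.einsum("nab,nbc,ndc->nad", Kua, Kaa_inv, Kua)

    edof = np.empty((mesh.n_elements, 8), dtype=np.int64)
    edof[:, 0::2] = 2 * mesh.elements
    edof[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(edof, 8, axis=1).ravel()
    cols = np.tile(edof, (1, 8)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    f = np.zeros(n_dof)
    u = np.zeros(n_dof)
    fixed_dofs = np.concatenate([2 * load.fixed_nodes, 2 * load.fixed_nodes + 1])
    load_nodes = np.atleast_1d(np.asarray(load.load_node, dtype=np.int64))
    vals = np.broadcast_to(np.asarray(load.value, dtype=float),
                           (len(load_nodes), 2))
    load_dofs = np.column_stack([2 * load_nodes, 2 * load_nodes + 1])
    if load.mode == "force":
        np.add.at(f, load_dofs.ravel(), vals.ravel())
        constrained = fixed_dofs
    elif load.mode == "displacement":
        u[load_dofs.ravel()] = vals.ravel()
        constrained = np.concatenate([fixed_dofs, load_dofs.ravel()])
    else:
        raise ValueError(f"unknown load mode {load.mode!r}")

    free = np.setdiff1d(np.arange(n_dof), constrained)
    if free.size:
        Kff = K[np.ix_(free, free)].tocsc()
        rhs = f[free] - K[np.ix_(free, constrained)] @ u[constrained]
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", spla.MatrixRankWarning)
            u_free = spla.spsolve(Kff, rhs)
        res = np.linalg.norm(Kff @ u_free - rhs) if np.all(np.isfinite(u_free)) \
            else np.inf
        if res > 1e-6 * max(1.0, np.linalg.norm(rhs)):
            raise np.linalg.LinAlgError(
                "singular stiffness system: insufficient constraints "
                "(rigid-body or disconnected modes present)"
            )
        u[free] = u_free

    residual = K @ u - f
    Rfix = residual[fixed_dofs].reshape(2, -1).sum(axis=1)
    Rload = residual[load_dofs].sum(axis=0)

    # strain/stress recovery at integration points (including the condensed
    # incompatible-mode contribution a = -Kaa^-1 Kau u)
    u_e = u.reshape(-1, 2)[mesh.elements].reshape(mesh.n_elements, 8)
    eps_voigt = np.einsum("ngia,na->ngi", B, u_e)
    if element == "incompatible":
        a_e = -np.einsum("nmk,nuk,nu->nm", Kaa_inv, Kua, u_e)
        eps_voigt = eps_voigt + np.einsum("ngia,na->ngi", Ba, a_e)
    eps_voigt = eps_voigt.reshape(mesh.n_ip, 3)
    D_ip = D0[None, :, :] * E_ip[:, None, None]
    sig = np.einsum("nij,nj->ni", D_ip, eps_voigt)
    szz = nu * (sig[:, 0] + sig[:, 1])
    stress = np.column_stack([sig[:, 0], sig[:, 1], szz, sig[:, 2]])
    strain = np.column_stack([eps_voigt[:, 0], eps_voigt[:, 1], 0.5 * eps_voigt[:, 2]])

    svm = von_mises_stress(stress[:, 0], stress[:, 1], stress[:, 2], stress[:, 3])
    evm = von_mises_strain(strain[:, 0], strain[:, 1], 0.0, strain[:, 2])

    return FemResult(
        displacements=u.reshape(-1, 2),
        strain=strain,
        stress=stress,
        von_mises_stress=svm,
        von_mises_strain=evm,
        reaction_force=(float(Rfix[0]), float(Rfix[1])),
        load_reaction=(float(Rload[0]), float(Rload[1])),
        external_work=float(f @ u + residual[constrained] @ u[constrained]),
        strain_energy=float(0.5 * u @ (K @ u)),
    )
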