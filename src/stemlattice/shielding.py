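"""Strain-shielding and strength evaluation of implanted femur models.

A stiff stem carries load past the surrounding bone, depressing the bone's
mechanical stimulus; understressed bone resorbs and the implant loosens.
The shielding measure compares the equivalent von Mises strain at matched
bone material points of the intact and implanted models,

    phi_bar = (phi_intact - phi_implanted) / phi_intact,

and classifies each point against a reference stimulus ``s`` (0.6 for the
proximal femur): phi_bar > s -> resorption, phi_bar < -s -> formation, and
the closed band [-s, s] is the "lazy zone" where formation and decay
balance.  Three implant variants are compared under a 2300 N axial load:
fully solid, uniformly porous at the graded design's average density, and
the graded (remodeled or network-predicted) density field.

Strength is the load at first yield onset when a 10 mm vertical displacement
is imposed at the load point: the material is elastic-perfectly-plastic with
apparent yield g1(vf)*sigma_s, so within the linear pre-yield regime the
first-yield load is the elastic reaction scaled by the worst-point yield
margin.  The graded-vs-uniform strength gain is
F_bar = (F_uniform - F_graded)/F_uniform (negative = graded stronger).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import fem
from .geometry import DesignVariables, FemurConfig, LoadCase, QuadMesh, Region, \
    build_conventional, build_femur
from .materials import SolidMaterial, TI6AL4V, apparent_modulus, yield_ratio
from .remodeling import DensityField

__all__ = ["BoneResponse", "ShieldingReport", "BONE_MODULI", "phi_bar", "classify",
           "modulus_field", "evaluate_variants", "yield_load", "f_bar",
           "cohort_summary"]

#: Young's moduli of the bone phases, MPa.
BONE_MODULI = {Region.CORTICAL: 17_500.0, Region.TRABECULAR: 5_000.0}

_IMPLANT_REGIONS = (Region.SOLID_TAPER, Region.SOLID_DISTAL, Region.REMODEL)


class BoneResponse(enum.IntEnum):
    FORMATION = 0
    LAZY = 1
    RESORPTION = 2
    MASKED = 3


@dataclass
class ShieldingReport:
    """Per-point phi_bar values and zone area fractions over the bone region.

    ``phi`` is NaN at masked points (near-zero intact stimulus); the three
    fractions are area-weighted over classified bone points and sum to 1.
    """

    phi: np.ndarray
    response: np.ndarray            # BoneResponse codes per bone point
    resorption_frac: float
    lazy_frac: float
    formation_frac: float
    s: float
    n_masked: int


def phi_bar(intact_measure, implanted_measure, eps: float = 1e-9):
    """Relative stimulus drop at matched points; NaN where intact < eps."""
    intact = np.asarray(intact_measure, dtype=float)
    implanted = np.asarray(implanted_measure, dtype=float)
    out = np.full(np.broadcast(intact, implanted).shape, np.nan)
    ok = intact > eps
    out[ok] = (intact[ok] - implanted[ok]) / intact[ok]
    if out.ndim == 0:
        return float(out)
    return out


def classify(phi, s: float = 0.6):
    """Bone response from phi_bar: resorption above s, formation below -s,
    lazy on the closed interval [-s, s]; NaN -> MASKED."""
    if s <= 0:
        raise ValueError("reference stimulus s must be positive")
    phi_arr = np.asarray(phi, dtype=float)
    out = np.full(phi_arr.shape, int(BoneResponse.LAZY))
    out[phi_arr > s] = int(BoneResponse.RESORPTION)
    out[phi_arr < -s] = int(BoneResponse.FORMATION)
    out[np.isnan(phi_arr)] = int(BoneResponse.MASKED)
    if out.ndim == 0:
        return BoneResponse(int(out))
    return out


def modulus_field(mesh: QuadMesh, solid: SolidMaterial = TI6AL4V) -> np.ndarray:
    """Per-integration-point Young's modulus of a femur model (MPa).

    Bone phases take the cortical/trabecular moduli; implant regions follow
    the gyroid stiffness law at the density stored in ``mesh.meta['ip_vf']``.
    """
    reg = mesh.ip_region
    E = np.empty(mesh.n_ip)
    E[reg == Region.CORTICAL] = BONE_MODULI[Region.CORTICAL]
    E[reg == Region.TRABECULAR] = BONE_MODULI[Region.TRABECULAR]
    imp = np.isin(reg, _IMPLANT_REGIONS)
    if imp.any():
        vf = mesh.meta.get("ip_vf")
        if vf is None:
            raise ValueError("implanted mesh lacks meta['ip_vf']")
        E[imp] = apparent_modulus(vf[imp], solid)
    return E


def _report(evm_intact: np.ndarray, evm_implanted: np.ndarray,
            weights: np.ndarray, s: float) -> ShieldingReport:
    phi = phi_bar(evm_intact, evm_implanted)
    resp = classify(phi, s)
    ok = resp != BoneResponse.MASKED
    area = float(weights[ok].sum())
    frac = {
        r: float(weights[ok & (resp == r)].sum() / area)
        for r in (BoneResponse.RESORPTION, BoneResponse.LAZY, BoneResponse.FORMATION)
    }
    return ShieldingReport(
        phi=phi, response=resp,
        resorption_frac=frac[BoneResponse.RESORPTION],
        lazy_frac=frac[BoneResponse.LAZY],
        formation_frac=frac[BoneResponse.FORMATION],
        s=s, n_masked=int((~ok).sum()),
    )


def yield_load(mesh: QuadMesh, load: LoadCase, vf_ip: Optional[np.ndarray] = None,
               solid: SolidMaterial = TI6AL4V, displacement: float = 10.0,
               thickness: float = 35.0) -> float:
    """Load magnitude (N) at first yield onset in the implant.

    A vertical displacement (default 10 mm) is imposed at the load node; the
    pre-yield response is linear and the material perfectly plastic, so the
    first-yield load is |R_y| * min_p( g1(vf_p)*sigma_s / sigma_vm_p ) over
    implant integration points, capped at the full-displacement reaction.
    """
    disp_case = LoadCase(fixed_nodes=load.fixed_nodes, load_node=load.load_node,
                         value=(0.0, -abs(displacement)), mode="displacement")
    if vf_ip is None:
        vf_ip = mesh.meta.get("ip_vf")
    if vf_ip is None:
        vf_ip = np.ones(mesh.n_ip)
    vf_ip = np.asarray(vf_ip, dtype=float)
    vf_clean = np.where(np.isnan(vf_ip), 1.0, vf_ip)
    reg = mesh.ip_region
    E_ip = np.empty(mesh.n_ip)
    E_ip[reg == Region.CORTICAL] = BONE_MODULI[Region.CORTICAL]
    E_ip[reg == Region.TRABECULAR] = BONE_MODULI[Region.TRABECULAR]
    imp_mask = np.isin(reg, _IMPLANT_REGIONS)
    E_ip[imp_mask] = apparent_modulus(vf_clean[imp_mask], solid)
    result = fem.solve(mesh, disp_case, E_ip, nu=solid.poisson_ratio,
                       thickness=thickness)
    R = abs(result.load_reaction[1])
    if R <= 0:
        raise ValueError("zero reaction under imposed displacement")
    imp = np.isin(mesh.ip_region, _IMPLANT_REGIONS)
    if not imp.any():
        raise ValueError("mesh contains no implant region")
    svm = result.von_mises_stress[imp]
    cap = yield_ratio(np.where(np.isnan(vf_ip[imp]), 1.0, vf_ip[imp])) * solid.yield_stress
    with np.errstate(divide="ignore"):
        margin = np.where(svm > 0, cap / svm, np.inf)
    return float(min(float(np.min(margin)), 1.0) * R)


def f_bar(F_uniform: float, F_graded: float) -> float:
    """Relative strength difference (F_uniform - F_graded)/F_uniform."""
    if F_uniform <= 0:
        raise ValueError("F_uniform must be positive")
    return (F_uniform - F_graded) / F_uniform


def evaluate_variants(
    dv: DesignVariables,
    density: Union[DensityField, "object"],
    elem_size: float = 2.5,
    femur: FemurConfig = FemurConfig(),
    solid: SolidMaterial = TI6AL4V,
    s: float = 0.6,
    with_strength: bool = True,
) -> dict:
    """Shielding (and optionally strength) of the three implant variants.

    ``density`` supplies the graded field: either a :class:`DensityField` on
    the design's conventional implant mesh, or a trained surrogate (anything
    with ``scalers_``; its pointwise prediction is used).  The uniform
    variant carries the area-weighted mean band density of the graded field;
    the solid variant is fully dense.  All variants and the intact model
    share one grid, so phi_bar is evaluated at matched points.
    """
    implant_mesh = build_conventional(dv, elem_size=elem_size)
    if implant_mesh is None:
        raise ValueError("infeasible design variables")

    if isinstance(density, DensityField):
        graded = density
        if graded.mesh is not implant_mesh and graded.vf.size != implant_mesh.n_ip:
            raise ValueError("density field does not match the implant mesh")
    else:
        from .surrogate import predict_field
        graded = predict_field(density, dv, implant_mesh)

    band = implant_mesh.ip_region == Region.REMODEL
    w = implant_mesh.ip_weights[band]
    mean_vf = float(np.sum(w * graded.vf[band]) / np.sum(w))
    uniform_vf = np.where(band, mean_vf, 1.0)

    variants = {
        "solid": None,
        "uniform": uniform_vf,
        "graded": graded.vf,
    }

    intact_mesh, load = build_femur(dv, "intact", implant_mesh=implant_mesh,
                                    config=femur)
    res_intact = fem.solve(intact_mesh, load, modulus_field(intact_mesh, solid),
                           nu=solid.poisson_ratio)

    out: dict = {"mean_vf": mean_vf, "reports": {}, "yield_loads": {}}
    for name, vf in variants.items():
        mesh_i, load_i = build_femur(dv, "implanted", implant_mesh=implant_mesh,
                                     implant_vf=vf, config=femur)
        res_i = fem.solve(mesh_i, load_i, modulus_field(mesh_i, solid),
                          nu=solid.poisson_ratio)
        bone = np.isin(mesh_i.ip_region, (Region.CORTICAL, Region.TRABECULAR))
        out["reports"][name] = _report(res_intact.von_mises_strain[bone],
                                       res_i.von_mises_strain[bone],
                                       mesh_i.ip_weights[bone], s)
        if with_strength and name in ("uniform", "graded"):
            out["yield_loads"][name] = yield_load(mesh_i, load_i, solid=solid)
    if with_strength:
        out["f_bar"] = f_bar(out["yield_loads"]["uniform"],
                             out["yield_loads"]["graded"])
    return out


def cohort_summary(results: list[dict]) -> dict:
    """Aggregate a cohort of per-design variant evaluations.

    Returns a table with one row per design (zone fractions per variant,
    yield loads, F_bar) and, per porous variant, the share of designs with
    less resorption / more formation than their solid control.
    """
    if not results:
        raise ValueError("empty cohort")
    rows = []
    for i, r in enumerate(results):
        row = {"design": i, "mean_vf": r.get("mean_vf", np.nan),
               "f_bar": r.get("f_bar", np.nan)}
        for name, rep in r["reports"].items():
            row[f"{name}_resorption"] = rep.resorption_frac
            row[f"{name}_lazy"] = rep.lazy_frac
            row[f"{name}_formation"] = rep.formation_frac
        for name, F in r.get("yield_loads", {}).items():
            row[f"{name}_yield_load"] = F
        rows.append(row)
    table = pd.DataFrame(rows)
    shares = {}
    for name in ("uniform", "graded"):
        if f"{name}_resorption" in table:
            shares[f"{name}_less_resorption"] = float(
                (table[f"{name}_resorption"] < table["solid_resorption"]).mean())
            shares[f"{name}_more_formation"] = float(
                (table[f"{name}_formation"] > table["solid_formation"]).mean())
    if "f_bar" in table and table["f_bar"].notna().any():
        shares["graded_stronger"] = float((table["f_bar"] < 0).mean())
    return {"table": table, "shares": shares}
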