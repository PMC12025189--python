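"""Bio-inspired density remodeling of the porous implant band.

Mimicking load-adaptive bone remodeling, the loop repeatedly (1) solves the
linear elasto-static problem with the current density field, (2) ranks the
remodeling-band integration points by equivalent von Mises stress, and
(3) moves the density of the most-stressed fraction ``alpha_frac`` of points
up and of the least-stressed fraction ``beta_frac`` down, through the
inverse apparent-yield law vf = g1^-1(sigma_vm / sigma_s).  Solid regions
never remodel.  The loop stops when the area-weighted mean density of the
band reaches ``target_mean_vf``, when the largest per-point change falls
below ``tol``, or after ``max_iters`` iterations.  Starting from a fully
solid domain, mass is progressively shed where stress is low, reducing
stiffness while preserving the highly stressed load paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem
from .geometry import LoadCase, QuadMesh, Region
from .materials import SolidMaterial, TI6AL4V, apparent_modulus, vf_from_stress_ratio

__all__ = ["DensityField", "RemodelParams", "select_points", "update_density", "run"]


@dataclass
class DensityField:
    """Gyroid volume fraction per integration point of an implant mesh.

    Invariant: vf = 1 in SOLID_* regions at all times; vf in [vf_min, 1]
    inside the remodeling band.
    """

    vf: np.ndarray
    mesh: QuadMesh
    vf_min: float = 0.1

    @classmethod
    def solid(cls, mesh: QuadMesh, vf_min: float = 0.1) -> "DensityField":
        return cls(vf=np.ones(mesh.n_ip), mesh=mesh, vf_min=vf_min)

    @property
    def remodel_mask(self) -> np.ndarray:
        return self.mesh.ip_region == Region.REMODEL

    def mean_remodel_vf(self) -> float:
        """Area-weighted mean volume fraction over the remodeling band."""
        m = self.remodel_mask
        w = self.mesh.ip_weights[m]
        return float(np.sum(w * self.vf[m]) / np.sum(w))

    def copy(self) -> "DensityField":
        return DensityField(vf=self.vf.copy(), mesh=self.mesh, vf_min=self.vf_min)


@dataclass(frozen=True)
class RemodelParams:
    """Remodeling-loop controls.

    ``alpha_frac``/``beta_frac`` are the per-iteration shares of band points
    whose density is raised/lowered (defaults 0.05 each: small steps that
    approximate the continuous adaptation the rule mimics).
    ``target_mean_vf`` is the control average density of the band (default
    0.6); ``tol`` the stagnation threshold on the max per-point change.
    """

    alpha_frac: float = 0.05
    beta_frac: float = 0.05
    target_mean_vf: float = 0.6
    max_iters: int = 100
    tol: float = 1e-4
    vf_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_frac <= 1 or not 0 <= self.beta_frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.alpha_frac + self.beta_frac > 1:
            raise ValueError("alpha_frac + beta_frac must not exceed 1")
        if not 0 < self.target_mean_vf <= 1:
            raise ValueError("target_mean_vf must lie in (0, 1]")
        if not 0 < self.vf_min < 1:
            raise ValueError("vf_min must lie in (0, 1)")


def select_points(sigma_vm: np.ndarray, alpha_frac: float, beta_frac: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the most- and least-stressed points.

    Returns (raise_set, lower_set): the floor(alpha_frac*n) largest and
    floor(beta_frac*n) smallest entries of ``sigma_vm``.  Ties break by
    ascending index (stable), and the two sets are guaranteed disjoint.
    """
    sigma_vm = np.asarray(sigma_vm, dtype=float)
    n = sigma_vm.size
    if n == 0:
        raise ValueError("empty stress vector")
    if not 0 <= alpha_frac <= 1 or not 0 <= beta_frac <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    n_inc = int(np.floor(alpha_frac * n))
    n_red = int(np.floor(beta_frac * n))
    if n_inc + n_red > n:
        raise ValueError("selection sets would overlap (fractions too large)")
    order = np.argsort(sigma_vm, kind="stable")  # ascending; stable tie-break
    lower = np.sort(order[:n_red])
    # for the raise set, stability by *ascending index* among ties of the
    # largest values requires a stable descending sort
    order_desc = np.argsort(-sigma_vm, kind="stable")
    raise_ = np.sort(order_desc[:n_inc])
    return raise_, lower


def update_density(
    field: DensityField,
    sigma_vm: np.ndarray,
    raise_set: np.ndarray,
    lower_set: np.ndarray,
    solid: SolidMaterial = TI6AL4V,
) -> DensityField:
    """Apply one remodeling step; returns a new field.

    ``raise_set``/``lower_set`` index into the full integration-point table
    and must address REMODEL points only.  Raised points take
    max(current, g1^-1(sigma/sigma_s)) — density never drops on a "raise" —
    and lowered points take min(current, g1^-1(sigma/sigma_s)); everything
    is clamped to [vf_min, 1].  Points outside both sets, and all solid
    regions, are untouched.
    """
    new = field.copy()
    rem = field.remodel_mask
    for s in (raise_set, lower_set):
        if len(s) and not rem[np.asarray(s)].all():
            raise ValueError("selection sets must contain remodeling-band points only")
    law = lambda idx: vf_from_stress_ratio(
        np.asarray(sigma_vm, dtype=float)[idx] / solid.yield_stress
    )
    if len(raise_set):
        idx = np.asarray(raise_set)
        new.vf[idx] = np.maximum(new.vf[idx], law(idx))
    if len(lower_set):
        idx = np.asarray(lower_set)
        new.vf[idx] = np.minimum(new.vf[idx], law(idx))
    new.vf[rem] = np.clip(new.vf[rem], field.vf_min, 1.0)
    return new


def run(
    mesh: QuadMesh,
    load: LoadCase,
    params: RemodelParams = RemodelParams(),
    solid: SolidMaterial = TI6AL4V,
    thickness: float = 35.0,
) -> tuple[DensityField, pd.DataFrame]:
    """Run the remodeling loop from a fully solid start.

    Returns the final density field and a history DataFrame with one row per
    completed iteration: mean band density, compliance (external work), the
    max per-point density change, and the stop reason on the last row.
    """
    if not np.any(mesh.region == Region.REMODEL):
        raise ValueError("mesh has no remodeling band")
    field = DensityField.solid(mesh, vf_min=params.vf_min)
    rem_idx = np.flatnonzero(field.remodel_mask)
    rows = []
    reason = "max_iters"
    if field.mean_remodel_vf() <= params.target_mean_vf:
        reason = "target_reached"
        history = pd.DataFrame(
            [dict(iteration=0, mean_vf=field.mean_remodel_vf(), compliance=np.nan,
                  max_change=0.0, stop=reason)]
        )
        return field, history

    n_band = rem_idx.size
    for it in range(params.max_iters):
        E_ip = apparent_modulus(field.vf, solid)
        try:
            result = fem.solve(mesh, load, E_ip, nu=solid.poisson_ratio,
                               thickness=thickness)
        except Exception as exc:  # surface the failing iteration
            raise RuntimeError(f"FEM solve failed at remodeling iteration {it}") from exc
        svm = result.von_mises_stress

        # points clamped at a bound cannot move further in that direction and
        # are not selection candidates, so remodeling spreads to fresh points
        can_raise = rem_idx[field.vf[rem_idx] < 1.0 - 1e-12]
        can_lower = rem_idx[field.vf[rem_idx] > params.vf_min + 1e-12]
        n_inc = min(int(np.floor(params.alpha_frac * n_band)), can_raise.size)
        n_red = min(int(np.floor(params.beta_frac * n_band)), can_lower.size)
        raise_set = can_raise[np.sort(np.argsort(-svm[can_raise], kind="stable")[:n_inc])]
        # ascending stress rank among lowerable points
        low_rank = can_lower[np.argsort(svm[can_lower], kind="stable")[:n_red]]

        def step(k: int) -> DensityField:
            return update_density(field, svm, raise_set, low_rank[:k], solid)

        new = step(n_red)
        if new.mean_remodel_vf() < params.target_mean_vf:
            # truncate the last reduction so the control average density is
            # met, not overshot: smallest k whose mean is <= target
            lo, hi = 0, n_red
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if step(mid).mean_remodel_vf() <= params.target_mean_vf:
                    hi = mid
                else:
                    lo = mid
            new = step(hi)
        change = float(np.max(np.abs(new.vf - field.vf))) if mesh.n_ip else 0.0
        field = new
        mean_vf = field.mean_remodel_vf()
        rows.append(dict(iteration=it, mean_vf=mean_vf,
                         compliance=result.external_work, max_change=change, stop=""))
        if mean_vf <= params.target_mean_vf:
            reason = "target_reached"
            break
        if change < params.tol:
            reason = "converged"
            break
    history = pd.DataFrame(rows)
    if len(history):
        history.loc[history.index[-1], "stop"] = reason
    return field, history
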