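"""Surrogate training corpus: remodeled density fields as pointwise records.

Each sampled implant design is remodeled to its optimal density field; every
integration point of its porous band contributes one row with the nine
design variables, the point's Cartesian coordinates, and the optimal volume
fraction as target.  Rows are split into train/validation at the *instance*
level (whole implants held out, so geometry cannot leak across the split),
and min-max scalers for the eleven features are fitted on training rows
only.  The target needs no scaling: it is a volume fraction in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .geometry import DesignVariables, QuadMesh, Region, build_conventional, \
    build_extended, implant_load_case, sample_designs
from .materials import SolidMaterial, TI6AL4V
from .remodeling import RemodelParams, run as run_remodeling

__all__ = ["ScalerParams", "Corpus", "scale_minmax", "build_corpus",
           "FEATURE_COLUMNS", "TARGET_COLUMN"]

FEATURE_COLUMNS = DesignVariables.names() + ["x", "y"]
TARGET_COLUMN = "vf"


def scale_minmax(x, lo: float, hi: float):
    """Min-max scale ``x`` to [0, 1] over the training range [lo, hi]."""
    if hi <= lo:
        raise ValueError("scaling requires hi > lo")
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


@dataclass
class ScalerParams:
    """Per-feature (min, max) fitted on training rows only."""

    minima: dict[str, float]
    maxima: dict[str, float]

    @classmethod
    def fit(cls, frame: pd.DataFrame, columns: list[str],
            range_fallback: dict | None = None) -> "ScalerParams":
        """Fit per-feature bounds on the given (training) rows.

        A column that is constant on the sample cannot be min-max scaled
        from data alone; for design variables the published range is known a
        priori, so ``range_fallback`` (feature -> (lo, hi)) substitutes it.
        A degenerate column without fallback is an error.
        """
        lo = {c: float(frame[c].min()) for c in columns}
        hi = {c: float(frame[c].max()) for c in columns}
        for c in columns:
            if hi[c] <= lo[c]:
                if range_fallback and c in range_fallback:
                    lo[c], hi[c] = map(float, range_fallback[c])
                else:
                    raise ValueError(
                        f"degenerate feature {c!r}: min == max on training rows")
        return cls(minima=lo, maxima=hi)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        cols = [scale_minmax(frame[c].to_numpy(), self.minima[c], self.maxima[c])
                for c in self.minima]
        return np.column_stack(cols)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"minima": self.minima, "maxima": self.maxima}, indent=1))

    @classmethod
    def from_json(cls, path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(minima=d["minima"], maxima=d["maxima"])


@dataclass
class Corpus:
    """Pointwise records plus the instance-level split and fitted scalers."""

    records: pd.DataFrame          # columns: instance, 9 dv, x, y, vf
    scalers: ScalerParams
    train_instances: np.ndarray
    val_instances: np.ndarray
    designs: dict[int, DesignVariables] = dc_field(default_factory=dict)

    def _rows(self, instances) -> pd.DataFrame:
        return self.records[self.records["instance"].isin(instances)]

    def xy(self, subset: str = "train") -> tuple[np.ndarray, np.ndarray]:
        """Scaled features and raw targets for 'train' or 'val' rows."""
        inst = {"train": self.train_instances, "val": self.val_instances}[subset]
        rows = self._rows(inst)
        return self.scalers.transform(rows), rows[TARGET_COLUMN].to_numpy()

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out["split"] = np.where(out["instance"].isin(self.train_instances),
                                "train", "val")
        out.to_csv(path, index=False, float_format="%.10g")


def build_corpus(
    n_instances: int,
    model: str = "conventional",
    seed: int = 0,
    params: RemodelParams = RemodelParams(),
    elem_size: float = 2.5,
    solid: SolidMaterial = TI6AL4V,
    val_fraction: float = 0.15,
    skip_designs: Optional[set] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> Corpus:
    """Remodel ``n_instances`` feasible sampled designs into a corpus.

    Infeasible designs (self-intersecting outlines) are skipped and replaced
    by further draws so exactly ``n_instances`` unique feasible instances are
    produced; ``skip_designs`` (a set of design tuples) lets a test corpus
    stay disjoint from a training corpus.  The 85/15 split is by instance;
    scalers are fitted on the training rows only, before any validation row
    is seen.  Deterministic for a fixed seed.
    """
    if n_instances < 2:
        raise ValueError("need at least two instances to split")
    builder = {"conventional": build_conventional, "extended": build_extended}[model]
    skip = {tuple(d) for d in (skip_designs or set())}

    rows: list[pd.DataFrame] = []
    designs: dict[int, DesignVariables] = {}
    draw, accepted = 256, 0
    while accepted < n_instances and draw <= 480000:
        pool = sample_designs(min(draw, 480000), seed)
        for dv in pool:
            key = tuple(dv.to_array())
            if key in skip:
                continue
            skip.add(key)
            mesh = builder(dv, elem_size)
            if mesh is None:
                continue
            load = implant_load_case(mesh)
            field, _ = run_remodeling(mesh, load, params, solid)
            band = mesh.ip_region == Region.REMODEL
            frame = pd.DataFrame({
                "instance": accepted,
                **{k: getattr(dv, k) for k in DesignVariables.names()},
                "x": mesh.ip_coords[band, 0],
                "y": mesh.ip_coords[band, 1],
                TARGET_COLUMN: field.vf[band],
            })
            rows.append(frame)
            designs[accepted] = dv
            accepted += 1
            if progress is not None:
                progress(accepted, n_instances)
            if accepted == n_instances:
                break
        draw *= 4
    if accepted < n_instances:
        raise RuntimeError("design grid exhausted before enough feasible instances")

    records = pd.concat(rows, ignore_index=True)
    n_val = max(1, int(round(val_fraction * n_instances)))
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n_instances)
    val_inst = np.sort(perm[:n_val])
    train_inst = np.sort(perm[n_val:])
    from .geometry import DESIGN_RANGES

    train_rows = records[records["instance"].isin(train_inst)]
    scalers = ScalerParams.fit(train_rows, FEATURE_COLUMNS,
                               range_fallback=DESIGN_RANGES)
    return Corpus(records=records, scalers=scalers,
                  train_instances=train_inst, val_instances=val_inst,
                  designs=designs)
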