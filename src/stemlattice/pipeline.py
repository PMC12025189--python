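"""End-to-end orchestration: sample -> remodel -> corpus -> tune -> train ->
test prediction -> shielding cohort -> optional lattice render.

A :class:`RunConfig` is fully serializable (YAML); a persisted config re-runs
to identical artifacts because one global seed fans out deterministically to
per-stage seeds.  Every produced file is listed in a manifest with its
SHA-256 hash."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataset, io, remodeling, shielding, surrogate
from .geometry import DesignVariables, FemurConfig, build_conventional, \
    build_extended, implant_load_case, sample_designs
from .gyroid import GyroidConfig, render
from .materials import TI6AL4V

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

_STAGE_OFFSETS = {"sample": 1, "remodel": 2, "corpus": 3, "tune": 4,
                  "train": 5, "test": 6, "shield": 7, "render": 8}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed * 1_000_003 + 7919 * _STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    model_type: str = "conventional"
    seed: int = 0
    n_instances: int = 60
    n_test_instances: int = 15
    elem_size: float = 2.5
    remodel: dict = field(default_factory=lambda: asdict(remodeling.RemodelParams()))
    search_budget: int = 0          # 0 -> skip tuning, use default spec
    mlp: dict = field(default_factory=lambda: surrogate.MlpSpec().__dict__.copy())
    femur: dict = field(default_factory=lambda: asdict(FemurConfig()))
    cohort_size: int = 0            # designs evaluated for shielding (0 -> skip)
    render_cell: float = 0.0        # unit-cell mm for a demo render (0 -> skip)
    outdir: str = "runs/default"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured pipeline; returns the artifact manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "files": {}}

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    def persist(name: str, path: Path) -> None:
        manifest["files"][name] = _sha256(path)

    try:
        params = remodeling.RemodelParams(**cfg.remodel)

        t0 = time.time()
        corpus = dataset.build_corpus(
            cfg.n_instances, model=cfg.model_type,
            seed=stage_seed(cfg.seed, "corpus"), params=params,
            elem_size=cfg.elem_size)
        corpus.to_csv(out / "corpus.csv")
        corpus.scalers.to_json(out / "scalers.json")
        io.designs_to_csv(out / "designs.csv", list(corpus.designs.values()))
        persist("corpus.csv", out / "corpus.csv")
        persist("scalers.json", out / "scalers.json")
        persist("designs.csv", out / "designs.csv")
        record("corpus", t0, n_instances=cfg.n_instances,
               n_rows=len(corpus.records))

        t0 = time.time()
        if cfg.search_budget > 0:
            spec, trials = surrogate.tune(corpus, cfg.search_budget,
                                          seed=stage_seed(cfg.seed, "tune"))
            trials.to_csv(out / "tuning.csv", index=False)
            persist("tuning.csv", out / "tuning.csv")
        else:
            spec = surrogate.MlpSpec(**cfg.mlp)
        record("tune", t0, spec=spec.__dict__)

        t0 = time.time()
        model = surrogate.train_final(corpus, spec,
                                      seed=stage_seed(cfg.seed, "train"))
        surrogate.save_model(model, out / "model")
        persist("model.json", out / "model.json")
        record("train", t0, epochs=model.n_epochs_, best_epoch=model.best_epoch_)

        t0 = time.time()
        test_corpus = dataset.build_corpus(
            cfg.n_test_instances, model=cfg.model_type,
            seed=stage_seed(cfg.seed, "test"), params=params,
            elem_size=cfg.elem_size,
            skip_designs={tuple(d.to_array()) for d in corpus.designs.values()})
        # evaluate with TRAINING scalers, not the test corpus's own
        X_all = corpus.scalers.transform(test_corpus.records)
        err = np.abs(np.clip(model.predict(X_all), params.vf_min, 1.0)
                     - test_corpus.records[dataset.TARGET_COLUMN].to_numpy())
        np.savetxt(out / "test_abs_error.csv", err, fmt="%.6g",
                   header="abs_error", comments="")
        persist("test_abs_error.csv", out / "test_abs_error.csv")
        record("test", t0, median_abs_error=float(np.median(err)),
               frac_below_0p1=float(np.mean(err < 0.1)))

        if cfg.cohort_size > 0:
            t0 = time.time()
            femur = FemurConfig(**cfg.femur)
            results = []
            for inst, dv in list(test_corpus.designs.items())[: cfg.cohort_size]:
                mesh = build_conventional(dv, cfg.elem_size)
                results.append(shielding.evaluate_variants(
                    dv, surrogate.predict_field(model, dv, mesh),
                    elem_size=cfg.elem_size, femur=femur))
            summary = shielding.cohort_summary(results)
            summary["table"].to_csv(out / "cohort.csv", index=False)
            (out / "cohort_shares.json").write_text(
                json.dumps(summary["shares"], indent=1))
            persist("cohort.csv", out / "cohort.csv")
            persist("cohort_shares.json", out / "cohort_shares.json")
            record("shield", t0, **summary["shares"])

        if cfg.render_cell > 0:
            t0 = time.time()
            dv = list(corpus.designs.values())[0]
            mesh = build_conventional(dv, cfg.elem_size)
            fld = surrogate.predict_field(model, dv, mesh)
            lattice = render(fld, mesh, GyroidConfig(cell_size=cfg.render_cell))
            io.write_stl_ascii(out / "implant.stl", lattice.vertices, lattice.faces)
            persist("implant.stl", out / "implant.stl")
            record("render", t0, n_faces=int(len(lattice.faces)),
                   watertight=lattice.is_watertight())
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
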