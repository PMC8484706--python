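"""End-to-end orchestration: generate → simulate → extract → split → train → evaluate.

A single :class:`RunConfig` (YAML-loadable) drives every stage; a single
master seed is split into per-stage seeds with ``numpy.random.SeedSequence``
so a rerun with the same config reproduces the data exactly and the metrics
within training-stochasticity tolerance.  Three scale presets:

* ``ci``    — smoke scale: 20 models, a few hundred points, 3 epochs;
* ``desk``  — the package's scaled-down study: 50 models per variant
  (10 type 1, 40 type 2), ~2,000 query points each, 9:1 stratified split;
* ``full`` — the full-size configuration (500 models at CFD-node-like
  densities); documented, not intended for a laptop run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .clouds import VARIANTS, HemoDataset, build_datasets, split_dataset, write_dataset
from .metrics import ErrorReport, evaluate
from .network import DualPointNetRegressor, save_model
from .porous import FluidProps, PorousLayerSpec

__all__ = ["RunConfig", "PRESETS", "run_experiment", "run"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.  Lengths mm-scale where noted."""

    seed: int = 0
    scale: str = "desk"
    n_type1: int = 10
    n_type2: int = 40
    surface_density: float = 0.10    # points / mm^2 (model cloud)
    interior_density: float = 0.105  # points / mm^3 (query cloud)
    noise_fraction: float = 0.02
    split_ratio: float = 0.9
    inlet_mass_flow: float = 0.004375  # kg/s
    rho: float = 1050.0
    mu: float = 0.0035
    stent_thickness_um: float = 150.0
    stent_K_mm2: float = 0.001489
    stent_C_per_m: float = 7665.0
    offset_side: str = "outer"
    ranges: Optional[Dict[str, Tuple[float, float]]] = None  # morphological overrides
    max_epochs: int = 250            # velocity networks (the harder regression)
    max_epochs_pressure: Optional[int] = 120
    patience: int = 60
    max_query_points: int = 800
    max_model_points: int = 400
    target_scale_velocity: float = 2.0   # v_mean ~ R^-2 at fixed mass flow
    target_scale_pressure: float = 3.0   # axial pressure drop ~ R^-3
    variants: Optional[List[Tuple[str, str]]] = None
    out_dir: Optional[str] = None

    def bc(self):
        from .flow import BoundaryConditions
        return BoundaryConditions(inlet_mass_flow=self.inlet_mass_flow)

    def props(self) -> FluidProps:
        return FluidProps(rho=self.rho, mu=self.mu)

    def layer(self) -> PorousLayerSpec:
        return PorousLayerSpec.from_stent_units(
            thickness_um=self.stent_thickness_um, K_mm2=self.stent_K_mm2,
            C_per_m=self.stent_C_per_m)

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        kwargs = {**PRESETS[name], "scale": name, **overrides}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        preset = raw.pop("scale", None)
        if "variants" in raw and raw["variants"] is not None:
            raw["variants"] = [tuple(v) for v in raw["variants"]]
        if preset:
            return cls.preset(preset, **raw)
        return cls(**raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        if d["variants"] is not None:
            d["variants"] = [list(v) for v in d["variants"]]
        return d


PRESETS: Dict[str, Dict] = {
    # smoke scale: everything runs in seconds
    "ci": dict(n_type1=10, n_type2=10, surface_density=0.02,
               interior_density=0.012, split_ratio=0.9,
               max_epochs=3, max_epochs_pressure=3, patience=3,
               max_query_points=300, max_model_points=150),
    # the package's scaled-down study conditions
    "desk": dict(n_type1=10, n_type2=40, surface_density=0.10,
                 interior_density=0.105, split_ratio=0.9,
                 max_epochs=250, max_epochs_pressure=120, patience=60),
    # full-size configuration: a mid-range type-2 model reaches ~0.05 M model
    # and ~0.26 M query points at these densities; for reference
    "full": dict(n_type1=100, n_type2=400, surface_density=9.3,
                  interior_density=14.8, split_ratio=0.9,
                  max_epochs=500, max_epochs_pressure=250, patience=60,
                  max_query_points=4000, max_model_points=2000),
}


def _stage_seeds(master: int) -> Dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ["data", "split", "train_pre_vel", "train_pre_pres",
             "train_post_vel", "train_post_pres"]
    vals = ss.generate_state(len(names)) % (2 ** 31)
    return {n: int(v) for n, v in zip(names, vals)}


def _train_seed_name(variant: Tuple[str, str]) -> str:
    state, qty = variant
    return f"train_{'pre' if state == 'preop' else 'post'}_{'vel' if qty == 'velocity' else 'pres'}"


def run_experiment(config: RunConfig, seed: Optional[int] = None,
                   variants: Optional[List[Tuple[str, str]]] = None,
                   datasets: Optional[Dict] = None,
                   split_seed: Optional[int] = None,
                   verbose: int = 0) -> Dict:
    """Run generate → split → train → evaluate and return everything in memory.

    Returns a dict with the four (or requested) variants' trained models,
    train/test splits, :class:`ErrorReport` objects and per-stage timings.
    ``datasets`` / ``split_seed`` allow reusing generated data across splits.
    """
    seed = config.seed if seed is None else seed
    seeds = _stage_seeds(seed)
    variants = variants or config.variants or VARIANTS
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    if datasets is None:
        datasets = build_datasets(
            config.n_type1, config.n_type2, seed=seeds["data"],
            surface_density=config.surface_density,
            interior_density=config.interior_density,
            noise_fraction=config.noise_fraction,
            bc=config.bc(), props=config.props(), layer=config.layer(),
            ranges=config.ranges, offset_side=config.offset_side)
    timings["data"] = time.perf_counter() - t0

    results: Dict[Tuple[str, str], Dict] = {}
    for variant in variants:
        ds = datasets[variant]
        train_ds, test_ds = split_dataset(
            ds, ratio=config.split_ratio,
            seed=seeds["split"] if split_seed is None else split_seed)
        t0 = time.perf_counter()
        is_velocity = variant[1] == "velocity"
        epochs = config.max_epochs if is_velocity else (
            config.max_epochs_pressure or config.max_epochs)
        est = DualPointNetRegressor(
            output_dim=3 if is_velocity else 1,
            max_epochs=epochs, patience=config.patience,
            max_query_points=config.max_query_points,
            max_model_points=config.max_model_points,
            target_scale_exponent=(config.target_scale_velocity if is_velocity
                                   else config.target_scale_pressure),
            random_state=seeds[_train_seed_name(variant)], verbose=verbose)
        X, y = train_ds.to_xy()
        est.fit(X, y)
        timings[f"train_{variant[0]}_{variant[1]}"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        report = evaluate(est, test_ds)
        timings[f"eval_{variant[0]}_{variant[1]}"] = time.perf_counter() - t0
        results[variant] = {"model": est, "train": train_ds, "test": test_ds,
                            "report": report}

    return {"config": config, "seed": seed, "seeds": seeds,
            "datasets": datasets, "results": results, "timings": timings}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, out_dir=None, verbose: int = 0) -> Path:
    """Full pipeline with artifacts on disk; returns the run directory.

    Writes the four data sets (compressed archives), one checkpoint and one
    JSON + text error report per variant, and a manifest recording the
    config, every derived seed, per-model parameter draws, stage timings and
    file checksums.
    """
    out = Path(out_dir or config.out_dir or "aneuflow_run")
    out.mkdir(parents=True, exist_ok=True)
    res = run_experiment(config, verbose=verbose)

    files: Dict[str, str] = {}
    for variant, payload in res["results"].items():
        tag = f"{variant[0]}_{variant[1]}"
        ds_path = out / f"dataset_{tag}.npz"
        write_dataset(res["datasets"][variant], ds_path, fmt="archive")
        ckpt = out / f"model_{tag}.ckpt.npz"
        save_model(payload["model"], ckpt)
        report: ErrorReport = payload["report"]
        report.to_json(out / f"report_{tag}.json")
        (out / f"report_{tag}.txt").write_text(report.format_table() + "\n")
        for p in (ds_path, ckpt, out / f"report_{tag}.json"):
            files[p.name] = _sha256(p)

    manifest = {
        "config": res["config"].to_dict(),
        "master_seed": res["seed"],
        "stage_seeds": res["seeds"],
        "variants": [list(v) for v in res["results"]],
        "models": [
            {"params": dataclasses.asdict(pair.params), "seed": pair.seed}
            for pair in res["datasets"][VARIANTS[0]].pairs
        ],
        "timings_s": {k: round(v, 3) for k, v in res["timings"].items()},
        "checksums": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
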