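"""Hemodynamic point-cloud data sets.

Each aneurysm model contributes two clouds, mirroring how CFD results are
harvested from mesh nodes:

* **model point cloud** — boundary-only coordinates (the outermost nodes),
  encoding the overall geometry; the network's global channel input;
* **query point cloud** — interior coordinates carrying the per-point
  velocity and pressure values; the network's local channel input and the
  regression target.

Four data-set variants are built from every model: {preop, postop} x
{velocity, pressure}.  Post-operative query clouds include points in the
stent-layer region without any special label — the learning stack never
distinguishes the FD domain from the fluid domain.  Splitting is stratified
9:1 by model type; serialization is legacy-VTK, PLY or a compressed archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as cloud_io
from .flow import BoundaryConditions, NoiseSpec, generate_flow
from .geometry import AneurysmGeometry, AneurysmParams, build_geometry, sample_params
from .porous import FluidProps, PorousLayerSpec

__all__ = [
    "ModelPointCloud",
    "QueryPointCloud",
    "HemoPair",
    "HemoDataset",
    "VARIANTS",
    "extract_clouds",
    "build_datasets",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]

VARIANTS: List[Tuple[str, str]] = [
    ("preop", "velocity"),
    ("preop", "pressure"),
    ("postop", "velocity"),
    ("postop", "pressure"),
]


@dataclass
class ModelPointCloud:
    """Boundary coordinates only, (N1, 3) in meters."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("model point cloud is empty")


@dataclass
class QueryPointCloud:
    """Interior coordinates (N2, 3) with optional per-point targets.

    ``velocity`` (N2, 3) m/s and/or ``pressure`` (N2,) Pa are present in
    training samples and absent in prediction-only clouds
    (``has_targets`` is False then).  ``region`` labels every point as
    parent artery (0) or aneurysm sac (1).
    """

    points: np.ndarray
    velocity: Optional[np.ndarray] = None
    pressure: Optional[np.ndarray] = None
    region: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("query point cloud is empty")
        n = len(self.points)
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float).reshape(n, 3)
        if self.pressure is not None:
            self.pressure = np.asarray(self.pressure, dtype=float).reshape(n)
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=int).reshape(n)

    @property
    def has_targets(self) -> bool:
        return self.velocity is not None or self.pressure is not None

    def target(self, quantity: str) -> np.ndarray:
        """Target array for ``quantity`` in {'velocity', 'pressure'}, shape (N2, 3) or (N2, 1)."""
        if quantity == "velocity":
            if self.velocity is None:
                raise ValueError("cloud carries no velocity target")
            return self.velocity
        if quantity == "pressure":
            if self.pressure is None:
                raise ValueError("cloud carries no pressure target")
            return self.pressure[:, None]
        raise ValueError(f"unknown quantity {quantity!r}")


@dataclass
class HemoPair:
    """One model's (model cloud, query cloud) pair plus provenance."""

    model_cloud: ModelPointCloud
    query_cloud: QueryPointCloud
    params: AneurysmParams
    seed: int = 0


@dataclass
class HemoDataset:
    """A list of pairs sharing one variant = (operative state, quantity)."""

    variant: Tuple[str, str]
    pairs: List[HemoPair] = field(default_factory=list)
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        state, quantity = self.variant
        if state not in ("preop", "postop") or quantity not in ("velocity", "pressure"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_xy(self):
        """(X, y) in estimator form: pairs of coordinate arrays and target arrays."""
        X = [(p.model_cloud.points, p.query_cloud.points) for p in self.pairs]
        y = [p.query_cloud.target(self.variant[1]) for p in self.pairs]
        return X, y


def extract_clouds(
    geometry: AneurysmGeometry,
    surface_density: float,
    interior_density: float,
    bc: BoundaryConditions = BoundaryConditions(),
    props: FluidProps = FluidProps(),
    operative_state: str = "preop",
    layer: Optional[PorousLayerSpec] = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    include_layer_points: bool = True,
) -> Tuple[ModelPointCloud, QueryPointCloud]:
    """Sample both clouds and attach the surrogate field to the query cloud.

    The query cloud carries *both* velocity and pressure (variant-specific
    views pick one); the model cloud carries coordinates only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    surf = geometry.sample_surface_points(surface_density, rng)
    interior = geometry.sample_interior_points(
        interior_density, rng, include_layer=include_layer_points,
        layer_thickness=layer.thickness if layer is not None else 150e-6)
    if len(surf) == 0 or len(interior) == 0:
        raise ValueError("empty sampling: increase the configured densities")
    ff = generate_flow(geometry, interior, bc, props, operative_state, layer,
                       noise, seed=seed)
    query = QueryPointCloud(points=interior, velocity=ff.velocity,
                            pressure=ff.pressure, region=geometry.region(interior))
    return ModelPointCloud(points=surf), query


def build_datasets(
    n_type1: int,
    n_type2: int,
    seed: int = 0,
    surface_density: float = 0.03,
    interior_density: float = 0.02,
    noise_fraction: float = 0.02,
    bc: BoundaryConditions = BoundaryConditions(),
    props: FluidProps = FluidProps(),
    layer: PorousLayerSpec = PorousLayerSpec(),
    ranges: Optional[Dict] = None,
    offset_side: str = "outer",
) -> Dict[Tuple[str, str], HemoDataset]:
    """Generate all four hemodynamic data-set variants, fully seeded.

    Every model contributes one pair to each variant; pre/post-operative
    variants share the same geometry and point sampling, velocity/pressure
    variants share the same field.
    """
    if n_type1 < 1 or n_type2 < 1:
        raise ValueError("need at least one model per type")
    noise = NoiseSpec(fraction=noise_fraction)
    datasets = {v: HemoDataset(variant=v) for v in VARIANTS}
    ss = np.random.SeedSequence(seed)
    model_seeds = [int(s) for s in ss.generate_state(n_type1 + n_type2) % (2 ** 31)]
    types = ["type1"] * n_type1 + ["type2"] * n_type2
    for model_seed, model_type in zip(model_seeds, types):
        params = sample_params(model_type, np.random.default_rng(model_seed), ranges=ranges)
        geometry = build_geometry(params, offset_side=offset_side)
        per_state: Dict[str, Tuple[ModelPointCloud, QueryPointCloud]] = {}
        for state in ("preop", "postop"):
            per_state[state] = extract_clouds(
                geometry, surface_density, interior_density, bc, props,
                operative_state=state, layer=layer if state == "postop" else None,
                noise=noise, seed=model_seed)
        for state, quantity in VARIANTS:
            mpc, qpc = per_state[state]
            view = QueryPointCloud(
                points=qpc.points,
                velocity=qpc.velocity if quantity == "velocity" else None,
                pressure=qpc.pressure if quantity == "pressure" else None,
                region=qpc.region)
            datasets[(state, quantity)].pairs.append(
                HemoPair(model_cloud=mpc, query_cloud=view, params=params,
                         seed=model_seed))
    for ds in datasets.values():
        ds.meta = {"seed": seed, "n_type1": n_type1, "n_type2": n_type2,
                   "surface_density": surface_density,
                   "interior_density": interior_density,
                   "noise_fraction": noise_fraction}
    return datasets


def split_dataset(dataset: HemoDataset, ratio: float = 0.9,
                  seed: int = 0) -> Tuple[HemoDataset, HemoDataset]:
    """Stratified train/test partition by model type.

    Per stratum the test count is ``floor(n * (1 - ratio))`` with the
    remainder going to training, so 500 models (100/400) at ratio 0.9 give
    exactly 450 training and 50 test models.  Same seed reproduces the split.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for model_type in ("type1", "type2"):
        idx = [i for i, p in enumerate(dataset.pairs) if p.params.model_type == model_type]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        # epsilon guards against 10 * (1 - 0.9) = 0.999...97 flooring to 0
        n_test = int(np.floor(len(idx) * (1.0 - ratio) + 1e-9))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train = HemoDataset(variant=dataset.variant,
                        pairs=[dataset.pairs[i] for i in sorted(train_idx)],
                        meta={**dataset.meta, "split": "train", "ratio": ratio})
    test = HemoDataset(variant=dataset.variant,
                       pairs=[dataset.pairs[i] for i in sorted(test_idx)],
                       meta={**dataset.meta, "split": "test", "ratio": ratio})
    return train, test


# -- serialization ---------------------------------------------------------

def _pair_manifest(pair: HemoPair) -> Dict:
    return {"params": {"model_type": pair.params.model_type,
                       "DA": pair.params.DA, "CC": pair.params.CC,
                       "DP": pair.params.DP, "CP": pair.params.CP,
                       "LA": pair.params.LA},
            "seed": pair.seed,
            "n_model": len(pair.model_cloud.points),
            "n_query": len(pair.query_cloud.points)}


def write_dataset(dataset: HemoDataset, path, fmt: str = "archive") -> None:
    """Serialize a data set.

    ``fmt='archive'`` writes one compressed ``.npz`` plus a JSON manifest
    sidecar; ``fmt='vtk'``/``'ply'`` write a directory of per-pair cloud
    files plus the manifest.
    """
    path = Path(path)
    manifest = {"variant": list(dataset.variant), "n_pairs": len(dataset),
                "meta": dataset.meta, "pairs": [_pair_manifest(p) for p in dataset.pairs]}
    if fmt == "archive":
        arrays = {}
        for i, pair in enumerate(dataset.pairs):
            arrays[f"pair{i}_model"] = pair.model_cloud.points
            arrays[f"pair{i}_query"] = pair.query_cloud.points
            if pair.query_cloud.velocity is not None:
                arrays[f"pair{i}_velocity"] = pair.query_cloud.velocity
            if pair.query_cloud.pressure is not None:
                arrays[f"pair{i}_pressure"] = pair.query_cloud.pressure
            if pair.query_cloud.region is not None:
                arrays[f"pair{i}_region"] = pair.query_cloud.region
        np.savez_compressed(path, **arrays)
        manifest_path = path.with_suffix(path.suffix + ".manifest.json") \
            if path.suffix == ".npz" else Path(str(path) + ".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=1))
    elif fmt in ("vtk", "ply"):
        path.mkdir(parents=True, exist_ok=True)
        write = cloud_io.write_vtk_cloud if fmt == "vtk" else cloud_io.write_ply_cloud
        for i, pair in enumerate(dataset.pairs):
            write(path / f"pair{i:04d}_model.{fmt}", pair.model_cloud.points)
            write(path / f"pair{i:04d}_query.{fmt}", pair.query_cloud.points,
                  velocity=pair.query_cloud.velocity,
                  pressure=pair.query_cloud.pressure,
                  region=pair.query_cloud.region)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_dataset(path) -> HemoDataset:
    """Round-trip counterpart of :func:`write_dataset` (all three formats)."""
    path = Path(path)
    if path.is_dir():
        manifest = json.loads((path / "manifest.json").read_text())
        pairs = []
        for i, pm in enumerate(manifest["pairs"]):
            stem = f"pair{i:04d}"
            files = sorted(path.glob(f"{stem}_model.*"))
            if not files:
                raise FileNotFoundError(f"{path}: missing {stem}_model cloud")
            ext = files[0].suffix[1:]
            read = cloud_io.read_vtk_cloud if ext == "vtk" else cloud_io.read_ply_cloud
            model = read(path / f"{stem}_model.{ext}")
            query = read(path / f"{stem}_query.{ext}")
            pairs.append(HemoPair(
                model_cloud=ModelPointCloud(points=model["points"]),
                query_cloud=QueryPointCloud(
                    points=query["points"], velocity=query.get("velocity"),
                    pressure=query.get("pressure"), region=query.get("region")),
                params=AneurysmParams(**pm["params"]), seed=pm["seed"]))
    else:
        manifest_path = path.with_suffix(path.suffix + ".manifest.json") \
            if path.suffix == ".npz" else Path(str(path) + ".manifest.json")
        manifest = json.loads(manifest_path.read_text())
        with np.load(path) as npz:
            pairs = []
            for i, pm in enumerate(manifest["pairs"]):
                pairs.append(HemoPair(
                    model_cloud=ModelPointCloud(points=npz[f"pair{i}_model"]),
                    query_cloud=QueryPointCloud(
                        points=npz[f"pair{i}_query"],
                        velocity=npz.get(f"pair{i}_velocity"),
                        pressure=npz.get(f"pair{i}_pressure"),
                        region=npz.get(f"pair{i}_region")),
                    params=AneurysmParams(**pm["params"]), seed=pm["seed"]))
    return HemoDataset(variant=tuple(manifest["variant"]), pairs=pairs,
                       meta=manifest.get("meta", {}))
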