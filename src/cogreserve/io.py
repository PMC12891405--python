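"""CSV/TSV/YAML plumbing and the end-to-end pipeline runner.

Feature tables are plain CSV with a header row, first column ``subject_id``
and numeric feature columns.  Subject alignment across blocks and target is
checked by id, never by row order alone.  Every run writes a JSON manifest
(seed, config hash, package versions) from which outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cogreserve.partition import (
    ReliabilityEstimate,
    VariancePartition,
    incremental_partition,
    reserve_score,
)
from cogreserve.prediction import CVConfig, fit_block_model
from cogreserve.synthetic import FeatureBlock, GenConfig, MultimodalDataset, generate_dataset
from cogreserve.trajectories import TrajectoryParams, compose_cognition, simulate_trajectories

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "DataValidationError",
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_target",
    "write_target",
    "write_dataset",
    "read_dataset",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataValidationError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


def read_feature_table(path, block_name: str) -> tuple[FeatureBlock, tuple]:
    """Read one modality's subjects-by-features CSV.

    Returns the block and the subject ids, preserving file order.  Missing
    or non-numeric cells are rejected with the offending subject and column
    named.
    """
    path = Path(path)
    try:
        # round_trip parsing so written datasets read back bit-exactly
        df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"{path}: empty file") from None
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: need subject_id plus at least one feature column")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataValidationError(f"{path}: duplicate subject_id {dup!r}")
    feats = df.iloc[:, 1:]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row, col = np.argwhere(bad.values)[0]
        raise DataValidationError(
            f"{path}: missing or non-numeric value for subject "
            f"{ids.iloc[row]!r}, column {feats.columns[col]!r}"
        )
    return (
        FeatureBlock(
            name=block_name,
            matrix=numeric.to_numpy(dtype=float),
            feature_names=tuple(feats.columns),
        ),
        tuple(ids),
    )


def write_feature_table(path, block: FeatureBlock, subject_id) -> None:
    df = pd.DataFrame(block.matrix, columns=list(block.feature_names))
    df.insert(0, "subject_id", list(subject_id))
    df.to_csv(path, index=False)


def read_target(path) -> tuple[np.ndarray, tuple, np.ndarray | None]:
    """Read the target CSV (subject_id, score[, age])."""
    block, ids = read_feature_table(path, "target")
    age = None
    cols = [c.lower() for c in block.feature_names]
    if "age" in cols:
        age = block.matrix[:, cols.index("age")]
    score_col = 0 if cols[0] != "age" else 1
    return block.matrix[:, score_col], ids, age


def write_target(path, target, subject_id, age=None) -> None:
    df = pd.DataFrame({"subject_id": list(subject_id), "score": np.asarray(target)})
    if age is not None:
        df["age"] = np.asarray(age)
    df.to_csv(path, index=False)


def write_dataset(outdir, data: MultimodalDataset) -> None:
    """Write target + one CSV per block into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_target(outdir / "target.csv", data.target, data.subject_id, age=data.age)
    for b in data.blocks:
        write_feature_table(outdir / f"{b.name}.csv", b, data.subject_id)


def read_dataset(outdir, block_names) -> MultimodalDataset:
    """Read a dataset previously written with :func:`write_dataset`,
    aligning every block to the target's subject order by id."""
    outdir = Path(outdir)
    target, ids, age = read_target(outdir / "target.csv")
    blocks = []
    for name in block_names:
        block, block_ids = read_feature_table(outdir / f"{name}.csv", name)
        block = _align_block(block, block_ids, ids)
        blocks.append(block)
    if age is None:
        age = np.full(len(ids), np.nan)
    return MultimodalDataset(target=target, blocks=tuple(blocks), age=age, subject_id=ids)


def _align_block(block: FeatureBlock, block_ids: tuple, target_ids: tuple) -> FeatureBlock:
    if block_ids == target_ids:
        return block
    missing = set(target_ids) - set(block_ids)
    extra = set(block_ids) - set(target_ids)
    if missing or extra:
        raise DataValidationError(
            f"block {block.name!r} subject ids do not match the target: "
            f"missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}"
        )
    pos = {sid: i for i, sid in enumerate(block_ids)}
    order = [pos[sid] for sid in target_ids]
    return FeatureBlock(
        name=block.name, matrix=block.matrix[order], feature_names=block.feature_names
    )


@dataclass
class RunConfig:
    """End-to-end run configuration (loadable from YAML)."""

    mode: str
    seed: int
    outdir: str = "out"
    generator: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    order: tuple | None = None
    reliability: float | None = None
    ceiling_convention: str = "r"
    clinical_block: str = "GMV"
    target_path: str | None = None
    block_paths: dict = field(default_factory=dict)

    MODES = ("simulate_trajectories", "generate_synthetic", "partition", "full_recovery")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ConfigError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.mode == "partition" and not (self.target_path and self.block_paths):
            raise ConfigError("partition mode requires target_path and block_paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_cv(cfg: RunConfig) -> CVConfig:
    kwargs = dict(cfg.cv)
    kwargs.setdefault("seed", cfg.seed)
    try:
        return CVConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid cv config: {exc}") from None


def _write_manifest(outdir: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    import sklearn
    import scipy

    import cogreserve

    manifest = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "versions": {
            "cogreserve": cogreserve.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    manifest.update(extra or {})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _write_partition(outdir: Path, part: VariancePartition) -> None:
    part.to_frame().to_csv(outdir / "partition.tsv", sep="\t", index=False)
    long = pd.DataFrame(
        [
            {
                "block_set": "+".join(bs),
                "repeat": rep,
                "r2_pct": part.per_repeat_r2[j, rep],
            }
            for j, bs in enumerate(part.block_sets)
            for rep in range(part.n_repeats)
        ]
    )
    long.to_csv(outdir / "per_repeat_r2.tsv", sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run one end-to-end mode; returns the output directory.

    Modes: ``simulate_trajectories`` (lifespan trajectories + cognition),
    ``generate_synthetic`` (multimodal dataset CSVs), ``partition``
    (staircase from CSV inputs), ``full_recovery`` (generate, partition, and
    compare against the generator's closed-form oracle).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "simulate_trajectories":
        try:
            params = TrajectoryParams(seed=cfg.seed, **cfg.trajectory)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid trajectory config: {exc}") from None
        traj = simulate_trajectories(params)
        cognition = compose_cognition(traj)
        ages = traj.ages
        rows = {"subject_id": [f"sub-{i:04d}" for i in range(params.n_individuals)]}
        for p in range(params.n_properties):
            rows[f"intercept_p{p + 1}"] = traj.intercepts[:, p]
            rows[f"slope_p{p + 1}"] = traj.slopes[:, p]
        pd.DataFrame(rows).to_csv(outdir / "individuals.csv", index=False)
        cog = pd.DataFrame(cognition, columns=[f"age_{a:g}" for a in ages])
        cog.insert(0, "subject_id", rows["subject_id"])
        cog.to_csv(outdir / "cognition.csv", index=False)
        _write_manifest(outdir, cfg)
        return outdir

    if cfg.mode == "generate_synthetic":
        gen = _build_gen(cfg)
        data, _ = generate_dataset(gen)
        write_dataset(outdir, data)
        _write_manifest(outdir, cfg)
        return outdir

    cv = _build_cv(cfg)

    if cfg.mode == "partition":
        target, ids, age = read_target(cfg.target_path)
        if np.ptp(target) == 0:
            raise DataValidationError("constant target score")
        blocks = []
        for name, path in cfg.block_paths.items():
            block, block_ids = read_feature_table(path, name)
            blocks.append(_align_block(block, block_ids, ids))
        data = MultimodalDataset(
            target=target,
            blocks=tuple(blocks),
            age=age if age is not None else np.full(len(ids), np.nan),
            subject_id=ids,
        )
        oracle = None
    else:  # full_recovery
        gen = _build_gen(cfg)
        data, truth = generate_dataset(gen)
        write_dataset(outdir / "synthetic", data)
        oracle = truth
        if cfg.reliability is None:
            cfg.reliability = gen.reliability

    order = tuple(cfg.order) if cfg.order else data.block_names
    rel = ReliabilityEstimate(cfg.reliability) if cfg.reliability else None
    for b in data.blocks:
        logger.info("block %s: %d subjects x %d features", b.name, b.n_subjects, b.n_features)
    part = incremental_partition(
        data, order, cv, reliability=rel, ceiling_convention=cfg.ceiling_convention
    )
    _write_partition(outdir, part)

    # residual reserve scores from the clinical block's out-of-fold prediction
    if cfg.clinical_block in data.block_names:
        bp = fit_block_model(data.block(cfg.clinical_block), data.target, cv, repeat=0)
        scores = reserve_score(data.target, bp.oof_pred)
        pd.DataFrame(
            {"subject_id": data.subject_id, "reserve_score": scores}
        ).to_csv(outdir / "reserve_scores.csv", index=False)

    extra = {}
    if oracle is not None:
        prefixes = [order[: j + 1] for j in range(len(order))]
        extra["oracle_r2_pct"] = {
            "+".join(pfx): 100.0 * oracle.oracle_r2(pfx) for pfx in prefixes
        }
        extra["recovery_error_pct"] = {
            "+".join(pfx): float(part.r2_mean[j] - 100.0 * oracle.oracle_r2(pfx))
            for j, pfx in enumerate(prefixes)
        }
    _write_manifest(outdir, cfg, extra)
    return outdir


def _build_gen(cfg: RunConfig) -> GenConfig:
    kwargs = dict(cfg.generator)
    kwargs.setdefault("seed", cfg.seed)
    if "block_schema" in kwargs:
        kwargs["block_schema"] = tuple(tuple(item) for item in kwargs["block_schema"])
    try:
        return GenConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid generator config: {exc}") from None
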