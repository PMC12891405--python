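"""Synthetic multimodal feature tables with known ground-truth variance shares.

Emulates the structure of a large lifespan cohort: one fluid-intelligence-like
target for ``n_subjects`` adults spanning 18-88 years, a small confound block
(sex-like binary + continuous polygenic-like score) and three brain blocks —
grey-matter volume (GMV, 98 features), white-matter integrity (WMI, 48
features) and resting-state functional connectivity (rFC, 153 features, the
number of unordered pairs of 17 networks).

Generative model (all latents standard normal, target variance 1):

    target = sqrt(share_con) * L_con
           + sqrt(shared_share) * L_shared
           + sum_b sqrt(share_b) * L_b            (brain blocks)
           + sqrt(r - s) * L_stable               (stable, unmeasured)
           + sqrt(1 - r) * eps                    (retest measurement noise)

where ``s = shared_share + sum(signal_share)`` and ``r`` is the configured
test reliability.  ``L_shared`` loads on every brain block (modelling
cross-modal correlation such as Wallerian degeneration) and carries a linear
age loading; each brain block additionally carries a unique latent.  The
closed-form explainable variance of any block subset (``oracle_r2``) is the
sum of that subset's unique shares, plus ``shared_share`` once the subset
touches any brain block; the retest reliability of the target is exactly
``r``, so the noise ceiling is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenConfig",
    "FeatureBlock",
    "MultimodalDataset",
    "GroundTruth",
    "generate_dataset",
    "rfc_connection_count",
]


def rfc_connection_count(n_networks: int) -> int:
    """Number of within- and between-network connections for ``n_networks``
    networks: the unordered pairs including self-pairs, n(n+1)/2."""
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    return n_networks * (n_networks + 1) // 2


DEFAULT_BLOCK_SCHEMA = (
    ("con", 2),
    ("GMV", 98),
    ("WMI", 48),
    ("rFC", rfc_connection_count(17)),
)

# Unique target-variance shares per block: cumulative explainable fractions
# over the default order are 0.11 / 0.42 / 0.48 / 0.52 against a reliability
# ceiling of 0.56 — an illustrative staircase of diminishing multimodal
# increments.  The age-driven latent shared across brain blocks correlates
# the modalities' features but carries no direct target share by default:
# a target-level shared component biases any stack of per-block predictions
# below the closed-form explainable variance (see docs on stacking).
DEFAULT_SIGNAL_SHARE = {"con": 0.11, "GMV": 0.31, "WMI": 0.06, "rFC": 0.04}


@dataclass(frozen=True)
class GenConfig:
    """Configuration of the synthetic multimodal generator."""

    n_subjects: int = 586
    age_range: tuple = (18.0, 88.0)
    block_schema: tuple = DEFAULT_BLOCK_SCHEMA
    signal_share: dict = field(default_factory=lambda: dict(DEFAULT_SIGNAL_SHARE))
    shared_share: float = 0.0
    reliability: float = 0.56
    feature_noise_sd: float | dict = 0.5
    loading_sparsity: float = 0.5
    age_loading: float = 0.6
    shared_feature_sd: float = 1.0
    confound_blocks: tuple = ("con",)
    seed: int = 0

    def __post_init__(self):
        names = [name for name, _ in self.block_schema]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        for name, n_feat in self.block_schema:
            if n_feat < 1:
                raise ValueError(f"block {name!r} has no features")
        unknown = set(self.signal_share) - set(names)
        if unknown:
            raise ValueError(f"signal_share for unknown blocks: {sorted(unknown)}")
        shares = {name: float(self.signal_share.get(name, 0.0)) for name in names}
        if any(v < 0 for v in shares.values()) or self.shared_share < 0:
            raise ValueError("variance shares must be nonnegative")
        total = self.shared_share + sum(shares.values())
        if total > 1 + 1e-12:
            raise ValueError(
                f"shared_share + sum(signal_share) = {total:.3f} exceeds 1"
            )
        if not 0 < self.reliability <= 1:
            raise ValueError("reliability must lie in (0, 1]")
        if total > self.reliability + 1e-12:
            raise ValueError(
                f"explainable variance {total:.3f} exceeds the reliability "
                f"{self.reliability}; the stable-score model requires "
                "shared_share + sum(signal_share) <= reliability"
            )
        if not 0 < self.loading_sparsity <= 1:
            raise ValueError("loading_sparsity must lie in (0, 1]")
        object.__setattr__(self, "signal_share", shares)
        object.__setattr__(self, "block_schema", tuple((n, int(k)) for n, k in self.block_schema))

    @property
    def block_names(self) -> tuple:
        return tuple(name for name, _ in self.block_schema)

    @property
    def brain_blocks(self) -> tuple:
        """Blocks the shared latent loads on (everything but the confounds)."""
        return tuple(n for n in self.block_names if n not in self.confound_blocks)

    def noise_sd_for(self, block: str) -> float:
        if isinstance(self.feature_noise_sd, dict):
            return float(self.feature_noise_sd.get(block, 0.0))
        # confound features are observed directly, without measurement noise
        return 0.0 if block in self.confound_blocks else float(self.feature_noise_sd)


@dataclass(frozen=True)
class FeatureBlock:
    """A named subjects-by-features matrix for one modality."""

    name: str
    matrix: np.ndarray
    feature_names: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (subjects x features)")
        if len(self.feature_names) != m.shape[1]:
            raise ValueError("feature_names length must equal the number of columns")
        if np.isnan(m).any():
            raise ValueError(f"block {self.name!r} contains missing values")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class MultimodalDataset:
    """Target vector plus ordered feature blocks and subject metadata."""

    target: np.ndarray
    blocks: tuple
    age: np.ndarray
    subject_id: tuple

    def __post_init__(self):
        n = len(self.subject_id)
        if len(self.target) != n or len(self.age) != n:
            raise ValueError("target, age and subject_id lengths must agree")
        for b in self.blocks:
            if b.n_subjects != n:
                raise ValueError(f"block {b.name!r} has {b.n_subjects} rows, expected {n}")
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        object.__setattr__(self, "age", np.asarray(self.age, dtype=float))
        object.__setattr__(self, "subject_id", tuple(self.subject_id))
        object.__setattr__(self, "blocks", tuple(self.blocks))

    @property
    def block_names(self) -> tuple:
        return tuple(b.name for b in self.blocks)

    def block(self, name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)


@dataclass(frozen=True)
class GroundTruth:
    """Generative latents and shares; the oracle for parameter recovery."""

    shared_latent: np.ndarray
    block_latents: dict  # block name -> unique latent, per subject
    stable_latent: np.ndarray
    true_score: np.ndarray  # target minus retest measurement noise
    signal_share: dict
    shared_share: float
    reliability: float
    brain_blocks: tuple
    seed: int

    def oracle_r2(self, block_subset) -> float:
        """Closed-form explainable target variance for a block subset.

        Sum of the subset's unique shares, plus the shared share if the
        subset intersects the brain blocks.  Monotone under inclusion.
        """
        subset = set(block_subset)
        unknown = subset - set(self.signal_share)
        if unknown:
            raise KeyError(f"unknown block name(s): {sorted(unknown)}")
        r2 = sum(self.signal_share[b] for b in subset)
        if subset & set(self.brain_blocks):
            r2 += self.shared_share
        return float(r2)

    def retest_target(self, seed: int) -> np.ndarray:
        """A fresh noisy measurement of the same true scores; correlating two
        such realisations estimates the configured reliability."""
        rng = np.random.default_rng(seed)
        noise_sd = float(np.sqrt(1.0 - self.reliability))
        return self.true_score + noise_sd * rng.standard_normal(self.true_score.size)


def generate_dataset(cfg: GenConfig) -> tuple[MultimodalDataset, GroundTruth]:
    """Generate one seeded multimodal dataset and its ground truth.

    Brain-block features are random-sign sparse loadings on the shared and
    the block-unique latent plus i.i.d. Gaussian feature noise; the confound
    block's standardized features *are* its latent (a balanced combination of
    a binary sex-like and a continuous polygenic-like score), so confounds
    load on the target directly, not through brain latents.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    z_age = (age - age.mean()) / age.std()

    # shared brain latent, partly age-driven
    a = cfg.age_loading
    shared = a * z_age + np.sqrt(1.0 - a**2) * rng.standard_normal(n)

    block_latents: dict[str, np.ndarray] = {}
    blocks = []
    for name, n_feat in cfg.block_schema:
        if name in cfg.confound_blocks:
            sex = rng.integers(0, 2, size=n).astype(float)
            pgs = rng.standard_normal(n)
            sex_std = (sex - 0.5) / 0.5
            latent = (sex_std + pgs) / np.sqrt(2.0)
            cols = [sex, pgs]
            extra = rng.standard_normal((n, n_feat - 2)) if n_feat > 2 else None
            matrix = np.column_stack(cols + ([extra] if extra is not None else []))
            feature_names = ["sex", "pgs"] + [f"{name}_{j}" for j in range(2, n_feat)]
            if n_feat == 1:  # degenerate single-column confound block
                matrix = pgs[:, None]
                latent = pgs.copy()
                feature_names = ["pgs"]
        else:
            latent = rng.standard_normal(n)
            n_active = max(1, int(round(cfg.loading_sparsity * n_feat)))
            w_shared = np.zeros(n_feat)
            w_unique = np.zeros(n_feat)
            idx_s = rng.choice(n_feat, size=n_active, replace=False)
            idx_u = rng.choice(n_feat, size=n_active, replace=False)
            w_shared[idx_s] = rng.choice([-1.0, 1.0], size=n_active)
            w_unique[idx_u] = rng.choice([-1.0, 1.0], size=n_active)
            noise = cfg.noise_sd_for(name) * rng.standard_normal((n, n_feat))
            matrix = (
                cfg.shared_feature_sd * np.outer(shared, w_shared)
                + np.outer(latent, w_unique)
                + noise
            )
            feature_names = [f"{name}_{j}" for j in range(n_feat)]
        block_latents[name] = latent
        blocks.append(FeatureBlock(name=name, matrix=matrix, feature_names=feature_names))

    s_total = cfg.shared_share + sum(cfg.signal_share.values())
    stable = rng.standard_normal(n)
    true_score = np.sqrt(cfg.shared_share) * shared
    for name in cfg.block_names:
        true_score = true_score + np.sqrt(cfg.signal_share[name]) * block_latents[name]
    true_score = true_score + np.sqrt(max(cfg.reliability - s_total, 0.0)) * stable
    target = true_score + np.sqrt(1.0 - cfg.reliability) * rng.standard_normal(n)

    dataset = MultimodalDataset(
        target=target,
        blocks=tuple(blocks),
        age=age,
        subject_id=tuple(f"sub-{i:04d}" for i in range(n)),
    )
    truth = GroundTruth(
        shared_latent=shared,
        block_latents=block_latents,
        stable_latent=stable,
        true_score=true_score,
        signal_share=dict(cfg.signal_share),
        shared_share=cfg.shared_share,
        reliability=cfg.reliability,
        brain_blocks=cfg.brain_blocks,
        seed=cfg.seed,
    )
    return dataset, truth
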