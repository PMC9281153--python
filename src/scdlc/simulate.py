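"""Synthetic scRNA-seq count generation.

A minimal gamma-Poisson generator in the style of Splatter: per-gene base
means are gamma distributed, a seeded subset of genes receives per-class
log-normal fold changes (random up/down direction), per-cell library sizes
are log-normal, counts are Poisson, and an independent Bernoulli mask adds
excess ("dropout") zeros at probability ``p_zero``.

The generator is parameterized by the quantities the simulation studies
vary — number of classes ``K``, per-class sample sizes, gene count ``g``,
proportion of differentially expressed genes ``DE`` and the excess-zero
probability ``p_zero`` — plus nuisance hyperparameters fixed at Splatter's
documented defaults.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "CountMatrix",
    "ClassLabels",
    "simulate_counts",
    "make_study_grid",
    "split_train_test",
]

# Fixed identifiers for independent random streams; adding genes must not
# perturb cell-level draws, so each model component owns a stream.
_STREAMS = {
    "gene_means": 1,
    "de_genes": 2,
    "de_factors": 3,
    "library_sizes": 4,
    "counts": 5,
    "zero_mask": 6,
    "split": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Seeded generator for a named substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


class ConfigurationError(ValueError):
    """Raised for invalid simulation or training configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic scRNA-seq generator.

    ``n_classes``/``n_per_class``/``n_genes``/``de_proportion``/``p_zero``
    are the study design quantities; the remaining fields are nuisance
    hyperparameters (gamma prior on gene means, log-normal DE fold-change
    and library-size distributions) defaulting to Splatter's documented
    values.
    """

    n_classes: int
    n_per_class: tuple[int, ...]
    n_genes: int
    de_proportion: float
    p_zero: float
    base_mean_shape: float = 0.6
    base_mean_rate: float = 0.3
    # median DE fold change e^1 ~ 2.7: a moderate, clearly differential
    # effect; Splatter's own 0.1 describes near-undetectable DE and leaves
    # every classifier at chance under the excess-zero mask
    de_factor_location: float = 1.0
    de_factor_scale: float = 0.4
    library_size_location: float = 11.0
    library_size_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.n_per_class) != self.n_classes:
            raise ConfigurationError(
                f"n_per_class has {len(self.n_per_class)} entries for "
                f"{self.n_classes} classes"
            )
        if any(n < 1 for n in self.n_per_class):
            raise ConfigurationError(f"all n_per_class must be >= 1, got {self.n_per_class}")
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be positive, got {self.n_genes}")
        if not 0.0 <= self.de_proportion <= 1.0:
            raise ConfigurationError(f"de_proportion must be in [0,1], got {self.de_proportion}")
        if not 0.0 <= self.p_zero <= 1.0:
            raise ConfigurationError(f"p_zero must be in [0,1], got {self.p_zero}")
        if self.base_mean_shape <= 0 or self.base_mean_rate <= 0:
            raise ConfigurationError("gamma prior parameters must be positive")

    @property
    def n_cells(self) -> int:
        return sum(self.n_per_class)

    @property
    def n_de_genes(self) -> int:
        return math.ceil(self.de_proportion * self.n_genes)


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer expression counts."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {self.counts.shape}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        g, n = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} columns")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class ClassLabels:
    """Per-cell class assignment.

    ``labels`` holds 0-based class codes internally; user-facing IO and the
    CLI use 1-based indices / class names.
    """

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        k = len(self.class_names)
        present = np.unique(self.labels)
        if self.labels.size and (present.min() < 0 or present.max() >= k):
            raise ValueError(f"label codes outside 0..{k - 1}")
        if len(present) != k:
            missing = sorted(set(range(k)) - set(present.tolist()))
            names = [self.class_names[m] for m in missing]
            raise ValueError(f"classes never observed: {names}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_cells(self) -> int:
        return self.labels.size

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, ClassLabels]:
    """Draw a synthetic count matrix and labels from the generative model.

    Hierarchy: lambda_j ~ Gamma(shape, rate); a seeded subset of
    ceil(DE*g) genes receives per-class fold changes exp(N(loc, scale))
    with a fair-coin up/down direction (class 1 is the reference);
    s_i ~ LogNormal(lib_loc, lib_scale); x_ij ~ Poisson(s_i * lambda_j *
    factor_{class(i), j}); finally an independent Bernoulli(p_zero) mask
    forces excess zeros.

    Identical config (including seed) gives bit-identical output. True DE
    gene indices and the zero mask fraction are recorded in
    ``CountMatrix.metadata``.
    """
    g, n, k = config.n_genes, config.n_cells, config.n_classes
    seed = config.seed

    lam = _rng(seed, "gene_means").gamma(
        shape=config.base_mean_shape, scale=1.0 / config.base_mean_rate, size=g
    )

    n_de = config.n_de_genes
    if config.de_proportion > 0 and n_de == 0:
        warnings.warn("DE*g rounds to 0; no genes are differentially expressed", stacklevel=2)
    de_genes = np.sort(_rng(seed, "de_genes").choice(g, size=n_de, replace=False))

    # Per-class multiplicative factors; class 0 is the reference (all ones).
    factors = np.ones((k, g))
    frng = _rng(seed, "de_factors")
    for cls in range(1, k):
        raw = np.exp(
            frng.normal(config.de_factor_location, config.de_factor_scale, size=n_de)
        )
        down = frng.random(n_de) < 0.5
        factors[cls, de_genes] = np.where(down, 1.0 / raw, raw)

    labels = np.repeat(np.arange(k), config.n_per_class)
    size_factors = np.exp(
        _rng(seed, "library_sizes").normal(
            config.library_size_location, config.library_size_scale, size=n
        )
    )

    mean = size_factors[None, :] * lam[:, None] * factors[labels, :].T
    counts = _rng(seed, "counts").poisson(mean).astype(np.int64)
    zero_mask = _rng(seed, "zero_mask").random((g, n)) < config.p_zero
    counts[zero_mask] = 0

    matrix = CountMatrix(
        counts=counts,
        gene_ids=[f"gene{j + 1}" for j in range(g)],
        cell_ids=[f"cell{i + 1}" for i in range(n)],
        metadata={
            "de_genes": de_genes.tolist(),
            "n_de_genes": int(n_de),
            "zero_mask_fraction": float(zero_mask.mean()),
            "config": config_to_dict(config),
        },
    )
    label_obj = ClassLabels(labels=labels, class_names=[f"class{c + 1}" for c in range(k)])
    return matrix, label_obj


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_classes": config.n_classes,
        "n_per_class": list(config.n_per_class),
        "n_genes": config.n_genes,
        "de_proportion": config.de_proportion,
        "p_zero": config.p_zero,
        "base_mean_shape": config.base_mean_shape,
        "base_mean_rate": config.base_mean_rate,
        "de_factor_location": config.de_factor_location,
        "de_factor_scale": config.de_factor_scale,
        "library_size_location": config.library_size_location,
        "library_size_scale": config.library_size_scale,
        "seed": config.seed,
    }


# Simulation-study factorial designs. ``n`` is the training-set size; each
# replicate simulates 2n cells (n train + n test) split evenly over classes.
_STUDY_N = {
    1: (100, 200, 300, 400, 500, 600, 700, 800, 900),
    2: (200, 300, 400, 500),
    3: (200, 300, 400, 500),
    4: (300, 400, 500, 600),
    5: (300, 400, 500, 600),
    6: (300, 400, 500, 600),
}
_DE_LEVELS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
_PZERO_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def make_study_grid(study_id: int, scale_factor: float = 1.0) -> list[SimulationConfig]:
    """Full factorial grid of configs for simulation studies 1-6.

    Studies 1-3 are binary (K=2); 4-6 repeat the designs with K=3.
    Study 1/4 varies sample size and gene count at DE=0.5, p_zero=0.2;
    study 2/5 varies DE in {0.2..0.7}; study 3/6 varies p_zero in
    {0.1..0.6} at DE=0.4. ``scale_factor`` (0 < f <= 1) scales the
    recommended replication count (1000 at full scale), not the grid.
    """
    if study_id not in _STUDY_N:
        raise ValueError(f"unknown study_id {study_id}; expected 1..6")
    if not 0 < scale_factor <= 1:
        raise ValueError(f"scale_factor must be in (0, 1], got {scale_factor}")
    k = 2 if study_id <= 3 else 3
    base = study_id if study_id <= 3 else study_id - 3

    points: list[tuple[int, float, float]] = []  # (g, DE, p_zero) per n
    if base == 1:
        points = [(g, 0.5, 0.2) for g in (100, 200, 300, 400)]
    elif base == 2:
        points = [(100, de, 0.2) for de in _DE_LEVELS]
    else:
        points = [(100, 0.4, pz) for pz in _PZERO_LEVELS]

    configs = []
    for g, de, pz in points:
        for n in _STUDY_N[study_id]:
            total = 2 * n  # train + test
            per_class = total // k
            sizes = [per_class] * k
            sizes[0] += total - per_class * k  # remainder to first class
            configs.append(
                SimulationConfig(
                    n_classes=k,
                    n_per_class=tuple(sizes),
                    n_genes=g,
                    de_proportion=de,
                    p_zero=pz,
                )
            )
    return configs


def recommended_replicates(scale_factor: float) -> int:
    """Replicate count at a given scale of the full 1000-replicate design."""
    if not 0 < scale_factor <= 1:
        raise ValueError(f"scale_factor must be in (0, 1], got {scale_factor}")
    return max(1, round(1000 * scale_factor))


def split_train_test(
    matrix: CountMatrix,
    labels: ClassLabels,
    n_train: int,
    seed: int,
) -> tuple[tuple[CountMatrix, ClassLabels], tuple[CountMatrix, ClassLabels]]:
    """Stratified, seeded, disjoint and exhaustive train/test partition.

    The training set draws from each class proportionally to its size
    (largest-remainder rounding); every class must keep at least one cell
    in the training portion.
    """
    n = matrix.n_cells
    if labels.n_cells != n:
        raise ValueError(f"labels cover {labels.n_cells} cells, matrix has {n}")
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")

    counts_per_class = labels.class_counts()
    quota = n_train * counts_per_class / n
    take = np.floor(quota).astype(np.int64)
    remainder = n_train - take.sum()
    if remainder > 0:
        order = np.argsort(-(quota - take), kind="stable")
        take[order[:remainder]] += 1
    for cls, (t, avail) in enumerate(zip(take, counts_per_class)):
        if t < 1:
            raise ValueError(
                f"n_train={n_train} leaves class '{labels.class_names[cls]}' "
                "empty in the training set"
            )
        if t >= avail:
            raise ValueError(
                f"n_train={n_train} leaves class '{labels.class_names[cls]}' "
                "empty in the test set"
            )

    rng = _rng(seed, "split")
    train_idx: list[np.ndarray] = []
    for cls in range(labels.n_classes):
        members = np.flatnonzero(labels.labels == cls)
        chosen = rng.choice(members, size=take[cls], replace=False)
        train_idx.append(chosen)
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(n), train)

    def _subset(idx: np.ndarray) -> tuple[CountMatrix, ClassLabels]:
        sub = CountMatrix(
            counts=matrix.counts[:, idx],
            gene_ids=list(matrix.gene_ids),
            cell_ids=[matrix.cell_ids[i] for i in idx],
            metadata=dict(matrix.metadata),
        )
        lab = ClassLabels(labels=labels.labels[idx], class_names=list(labels.class_names))
        return sub, lab

    return _subset(train), _subset(test)


def subset_config(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Copy a config with field overrides (convenience for harnesses)."""
    return replace(config, **overrides)
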