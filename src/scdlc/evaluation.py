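"""Evaluation: misclassification rate, AUC, and experiment harnesses.

AUC is the rank (Mann-Whitney) formulation with ties counting 1/2; the
multiclass score is macro one-vs-rest (unweighted mean over classes).
``run_simulation_study`` reproduces the factorial simulation designs at a
configurable replication count; ``run_repeated_splits`` is the repeated
random train/test subsampling protocol used on real datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .features import FeatureRanking, select_top_genes
from .network import ScdlcParams, forward_batch, prepare_inputs
from .simulate import (
    ClassLabels,
    CountMatrix,
    SimulationConfig,
    make_study_grid,
    recommended_replicates,
    simulate_counts,
    split_train_test,
)
from .training import TrainConfig, train_model

__all__ = [
    "EvalReport",
    "StudyResult",
    "misclassification_rate",
    "auc_score",
    "evaluate_model",
    "run_simulation_study",
    "run_repeated_splits",
]


@dataclass
class EvalReport:
    """Test-set performance of a fitted classifier."""

    misclassification_rate: float
    auc_macro: float
    per_class_auc: list[float]
    confusion: np.ndarray  # (K, K); rows = true class, columns = predicted
    n_test: int

    def to_dict(self) -> dict:
        return {
            "misclassification_rate": self.misclassification_rate,
            "auc_macro": self.auc_macro,
            "per_class_auc": list(self.per_class_auc),
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
        }


@dataclass
class StudyResult:
    """Replicate-level results at one grid point of a simulation study."""

    study_id: int
    n_classes: int
    n_genes: int
    n_train: int
    de_proportion: float
    p_zero: float
    replicate_seeds: list[int]
    misclassification_rates: list[float]
    auc_macro: list[float]
    method: str = "scDLC"

    @property
    def mean_misclassification(self) -> float:
        return float(np.mean(self.misclassification_rates))

    @property
    def sd_misclassification(self) -> float:
        return float(np.std(self.misclassification_rates, ddof=1)) if len(
            self.misclassification_rates
        ) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id, "method": self.method,
            "n_classes": self.n_classes, "n_genes": self.n_genes,
            "n_train": self.n_train, "de_proportion": self.de_proportion,
            "p_zero": self.p_zero,
            "replicate_seeds": self.replicate_seeds,
            "misclassification_rates": self.misclassification_rates,
            "auc_macro": self.auc_macro,
            "mean_misclassification": self.mean_misclassification,
            "sd_misclassification": self.sd_misclassification,
        }


def misclassification_rate(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of test samples assigned the wrong class."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.ndim != 1:
        raise ValueError(f"shape mismatch: {predictions.shape} vs {truth.shape}")
    if predictions.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean(predictions != truth))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC of `scores` for the boolean positive mask; ties 1/2."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    ranks = rankdata(scores)  # average ranks handle ties -> 1/2 contribution
    rank_sum = ranks[positive].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_score(probabilities: np.ndarray, truth: np.ndarray) -> tuple[float, list[float]]:
    """Macro one-vs-rest AUC and the per-class AUC list.

    Class c's score is its predicted probability; classes absent from
    ``truth`` are skipped with a warning. For two classes this equals the
    usual binary AUC of the positive-class probability.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    truth = np.asarray(truth, dtype=np.int64)
    n, m = probs.shape
    if truth.shape != (n,):
        raise ValueError(f"{truth.size} labels for {n} probability rows")
    present = np.unique(truth)
    if present.size < 2:
        raise ValueError("AUC requires at least two classes in truth")
    per_class: list[float] = []
    for c in range(m):
        mask = truth == c
        if not mask.any() or mask.all():
            warnings.warn(f"class {c} absent from truth (or is all of it); skipped", stacklevel=2)
            per_class.append(float("nan"))
            continue
        per_class.append(_binary_auc(probs[:, c], mask))
    valid = [a for a in per_class if np.isfinite(a)]
    return float(np.mean(valid)), per_class


def evaluate_model(
    params: ScdlcParams,
    counts: CountMatrix,
    labels: ClassLabels,
    ranking: FeatureRanking,
) -> EvalReport:
    """Score a fitted model on held-out data using the training ranking."""
    X = prepare_inputs(counts, ranking.selected)
    probs = forward_batch(X, params)
    preds = np.argmax(probs, axis=1)
    truth = labels.labels
    k = labels.n_classes
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (truth, preds), 1)
    auc_macro, per_class = auc_score(probs, truth)
    return EvalReport(
        misclassification_rate=misclassification_rate(preds, truth),
        auc_macro=auc_macro,
        per_class_auc=per_class,
        confusion=confusion,
        n_test=truth.size,
    )


def _derive_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2^31 from structured components."""
    ss = np.random.SeedSequence(entropy=list(int(p) for p in parts))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def run_study_point(
    sim: SimulationConfig,
    study_id: int,
    point_idx: int,
    replicates: int,
    p_features: int,
    config: TrainConfig,
    base_seed: int,
    dtype=np.float32,
) -> StudyResult:
    """All replicates of one grid point, trained replicate-parallel.

    Per replicate: simulate 2n cells, stratified split into n train /
    n test, BW ranking on the training half only, train, score on the
    test half. The replicates share shapes and hyperparameters, so they
    are trained simultaneously (see ``scdlc.parallel``); results equal
    training them one at a time with ``train_model``.
    """
    from .network import prepare_inputs
    from .parallel import _stack_params, predict_parallel, train_models_parallel

    n_train = sim.n_cells // 2
    seeds = [_derive_seed(base_seed, study_id, point_idx, rep) for rep in range(replicates)]
    Xtr, ytr, Xte, yte = [], [], [], []
    for rep, seed in enumerate(seeds):
        sim_rep = SimulationConfig(**{**_sim_dict(sim), "seed": seed})
        try:
            matrix, labels = simulate_counts(sim_rep)
            (tr_m, tr_l), (te_m, te_l) = split_train_test(matrix, labels, n_train,
                                                          seed=seed + 1)
            ranking = select_top_genes(tr_m, tr_l, p=min(p_features, tr_m.n_genes))
            Xtr.append(prepare_inputs(tr_m, ranking.selected))
            ytr.append(tr_l.labels)
            Xte.append(prepare_inputs(te_m, ranking.selected))
            yte.append(te_l.labels)
        except Exception as exc:
            raise RuntimeError(
                f"study {study_id}, grid point {point_idx} "
                f"(g={sim.n_genes}, n={n_train}, DE={sim.de_proportion}, "
                f"p_zero={sim.p_zero}), replicate {rep}: {exc}"
            ) from exc

    params_list, _ = train_models_parallel(
        np.stack(Xtr), np.stack(ytr), config, seeds=[s + 7 for s in seeds],
        dtype=dtype,
    )
    eval_stack = {k: v.astype(dtype) for k, v in _stack_params(params_list).items()}
    probs = predict_parallel(np.stack(Xte).astype(dtype), eval_stack)
    yte = np.stack(yte)
    rates, aucs = [], []
    for r in range(replicates):
        preds = np.argmax(probs[r], axis=1)
        rates.append(misclassification_rate(preds, yte[r]))
        aucs.append(auc_score(probs[r], yte[r])[0])
    return StudyResult(
        study_id=study_id,
        n_classes=sim.n_classes,
        n_genes=sim.n_genes,
        n_train=n_train,
        de_proportion=sim.de_proportion,
        p_zero=sim.p_zero,
        replicate_seeds=seeds,
        misclassification_rates=rates,
        auc_macro=aucs,
    )


def run_simulation_study(
    study_id: int,
    replicates: int | None = 20,
    p_features: int = 100,
    config: TrainConfig | None = None,
    base_seed: int = 0,
    grid: list[SimulationConfig] | None = None,
    scale_factor: float | None = None,
    dtype=np.float32,
) -> list[StudyResult]:
    """Run one simulation study: simulate, split, rank, train, evaluate.

    For each grid point and replicate, 2n cells are simulated, n go to
    training and n to test (stratified), the top ``p_features`` genes are
    ranked on the training half only, the model is trained and scored on
    the test half. Replicate seeds derive deterministically from
    ``base_seed``, the grid-point index and the replicate index. ``grid``
    overrides the full factorial design (e.g. for a sub-grid);
    ``scale_factor`` sets ``replicates`` to round(1000 * scale_factor)
    when ``replicates`` is None.
    """
    if replicates is None:
        replicates = recommended_replicates(scale_factor if scale_factor is not None else 0.02)
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if config is None:
        config = TrainConfig()
    if grid is None:
        grid = make_study_grid(study_id)
    return [
        run_study_point(sim, study_id, point_idx, replicates, p_features,
                        config, base_seed, dtype=dtype)
        for point_idx, sim in enumerate(grid)
    ]


def _sim_dict(c: SimulationConfig) -> dict:
    from .simulate import config_to_dict

    d = config_to_dict(c)
    d["n_per_class"] = tuple(d["n_per_class"])
    return d


def _cfg_dict(c: TrainConfig) -> dict:
    return {
        "hidden_size": c.hidden_size, "batch_size": c.batch_size,
        "grad_clip": c.grad_clip, "keep_prob": c.keep_prob,
        "max_lr": c.max_lr, "min_lr": c.min_lr,
        "epochs": c.epochs, "seed": c.seed, "embed_dim": c.embed_dim,
    }


def run_repeated_splits(
    counts: CountMatrix,
    labels: ClassLabels,
    n_train: int,
    repetitions: int,
    p_features: int,
    config: TrainConfig | None = None,
    base_seed: int = 0,
) -> list[EvalReport]:
    """Repeated random stratified train/test subsampling on one dataset.

    Per repetition: stratified split, BW ranking on the training portion,
    training, evaluation on the held-out portion. The per-repetition AUCs
    are suitable for boxplot summaries.
    """
    if repetitions < 1:
        raise ValueError(f"repetitions must be >= 1, got {repetitions}")
    if config is None:
        config = TrainConfig()
    reports: list[EvalReport] = []
    for rep in range(repetitions):
        seed = _derive_seed(base_seed, 999, rep)
        (tr_m, tr_l), (te_m, te_l) = split_train_test(counts, labels, n_train, seed=seed)
        ranking = select_top_genes(tr_m, tr_l, p=min(p_features, tr_m.n_genes))
        rep_cfg = TrainConfig(**{**_cfg_dict(config), "seed": seed + 7})
        params, _ = train_model(tr_m, tr_l, ranking, rep_cfg)
        reports.append(evaluate_model(params, te_m, te_l, ranking))
    return reports
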