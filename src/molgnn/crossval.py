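"""Nested cross-validation with combined-rank selection, seed
reinitialisation, sequential warm starts and statistical stopping.

The protocol, for each of ``outer_k`` stratified outer folds (the outer test
fold is 25% of the data at the default 4):

1. *Grid search* — every hyperparameter combination is trained on each of the
   ``inner_k`` stratified inner splits of the outer-training portion with
   early stopping; the winning combination minimises the sum of its rank by
   median and its rank by minimum validation AUC across inner folds.
2. *Seed reinitialisation* — the winning configuration is retrained from
   fresh Xavier initialisations under several seeds (20 by default); the
   winning seed is chosen by the same combined rank.
3. *Sequential warm starts* — starting from the winning seed's
   initialisation, repeated runs train sequentially through inner folds
   1..k, parameters persisting across folds and runs. After each run the
   pooled validation AUCs (inner_k per outer fold, across all outer folds)
   are compared to each of the two previous runs with a one-sided Wilcoxon
   rank-sum test; once at least three runs are complete, warm starts halt
   when both p-values exceed the Sidak-corrected level.
4. *Outer evaluation* — the final warm-started model of each outer fold is
   scored on its held-out test fold (AUC/ACC/F1/MCC), aggregated as mean and
   standard deviation over outer folds. An index tracker audits that no test
   index was touched by any training or selection step of its fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from molgnn.featurize import GraphDataset, MolecularGraph
from molgnn.metrics import (
    MetricReport,
    roc_auc,
    scores_to_report,
    sidak_alpha,
    wilcoxon_rank_sum,
)
from molgnn.nn.model import (
    GNNModel,
    GraphBatch,
    ModelConfig,
    logit_loss,
    make_batch,
    predict_scores,
    xavier_init,
)
from molgnn.nn.optim import Adam


# --- fold plan --------------------------------------------------------------


@dataclass
class FoldPlan:
    """Stratified nested-CV index structure over one dataset."""

    outer_folds: list[np.ndarray]  # disjoint test-index sets covering all data
    inner_folds: list[list[np.ndarray]]  # per outer fold: validation-index sets
    seed: int

    @property
    def outer_k(self) -> int:
        return len(self.outer_folds)

    @property
    def inner_k(self) -> int:
        return len(self.inner_folds[0])

    def outer_train_indices(self, outer_index: int) -> np.ndarray:
        return np.sort(np.concatenate(self.inner_folds[outer_index]))

    def inner_split(
        self, outer_index: int, inner_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) indices for one inner fold of one outer fold."""
        val = self.inner_folds[outer_index][inner_index]
        train = np.concatenate(
            [
                f
                for k, f in enumerate(self.inner_folds[outer_index])
                if k != inner_index
            ]
        )
        return np.sort(train), np.sort(val)


def make_fold_plan(
    labels: Sequence[int], outer_k: int = 4, inner_k: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified outer/inner partitions (defaults induce 60/15/25 splits).

    Requires each class to have at least ``outer_k * inner_k`` members so all
    folds contain both classes.
    """
    labels = np.asarray(labels, dtype=int)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < outer_k * inner_k:
            raise ValueError(
                f"class {cls} has fewer than outer_k*inner_k={outer_k * inner_k} members"
            )
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    outer_folds = []
    inner_folds = []
    all_idx = np.arange(labels.size)
    for oi, (train_idx, test_idx) in enumerate(outer.split(all_idx, labels)):
        outer_folds.append(np.sort(test_idx))
        inner = StratifiedKFold(
            n_splits=inner_k, shuffle=True, random_state=seed * 131 + oi + 1
        )
        folds = [
            np.sort(train_idx[val_local])
            for _, val_local in inner.split(train_idx, labels[train_idx])
        ]
        inner_folds.append(folds)
    return FoldPlan(outer_folds=outer_folds, inner_folds=inner_folds, seed=seed)


# --- hyperparameter grid ----------------------------------------------------


@dataclass(frozen=True)
class HyperparamGrid:
    """Candidate lists; enumeration order is the cartesian product in field
    order (batch_size, hidden_channels, dropout, learning_rate)."""

    batch_size: tuple[int, ...] = (16, 32, 64)
    hidden_channels: tuple[int, ...] = (32, 64, 128)
    dropout: tuple[float, ...] = (0.1, 0.3, 0.5)
    learning_rate: tuple[float, ...] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2)

    def __len__(self) -> int:
        return (
            len(self.batch_size)
            * len(self.hidden_channels)
            * len(self.dropout)
            * len(self.learning_rate)
        )


def enumerate_grid(grid: HyperparamGrid) -> list[dict]:
    """Deterministic cartesian product of the candidate lists."""
    for name in ("batch_size", "hidden_channels", "dropout", "learning_rate"):
        if len(getattr(grid, name)) == 0:
            raise ValueError(f"empty candidate list {name!r}")
    return [
        {
            "batch_size": bs,
            "hidden_channels": hc,
            "dropout": dr,
            "learning_rate": lr,
        }
        for bs, hc, dr, lr in itertools.product(
            grid.batch_size, grid.hidden_channels, grid.dropout, grid.learning_rate
        )
    ]


@dataclass
class TrialScores:
    """Validation AUCs of one candidate (config or seed) across inner folds."""

    trial_id: str
    aucs: list[float]


def combined_rank_select(trials: Sequence[TrialScores]) -> int:
    """Index of the trial minimising rank-by-median + rank-by-minimum AUC.

    Both rankings are descending (higher AUC ranks better, rank 1 best) with
    mid-ranks for ties; exact rank-sum ties go to the earliest enumeration
    index.
    """
    if len(trials) == 0:
        raise ValueError("no trials to select from")
    medians = np.array([np.median(t.aucs) for t in trials])
    minima = np.array([np.min(t.aucs) for t in trials])
    rank_sum = rankdata(-medians) + rankdata(-minima)
    return int(np.argmin(rank_sum))  # argmin takes the first minimum


# --- training with early stopping -------------------------------------------


@dataclass
class EarlyStopOutcome:
    best_score: float
    best_epoch: int
    epochs_run: int
    history: list[float]


def run_early_stopping(
    epoch_fn: Callable[[int], float],
    patience: int = 50,
    max_epochs: int = 500,
    restore_fn: Callable[[int], None] | None = None,
) -> EarlyStopOutcome:
    """Generic patience loop: call ``epoch_fn(epoch)`` (train one epoch,
    return the validation score) until no improvement for ``patience`` epochs
    or ``max_epochs``; ``restore_fn(best_epoch)`` restores the best state."""
    best = -np.inf
    best_epoch = -1
    history: list[float] = []
    for epoch in range(max_epochs):
        score = epoch_fn(epoch)
        history.append(score)
        if score > best:
            best = score
            best_epoch = epoch
        elif epoch - best_epoch >= patience:
            break
    if restore_fn is not None:
        restore_fn(best_epoch)
    return EarlyStopOutcome(
        best_score=best,
        best_epoch=best_epoch,
        epochs_run=len(history),
        history=history,
    )


def train_with_early_stopping(
    model: GNNModel,
    train_graphs: Sequence[MolecularGraph],
    val_graphs: Sequence[MolecularGraph],
    config: ModelConfig,
    rng: np.random.Generator,
    label_task: int | None = None,
) -> tuple[GNNModel, float]:
    """Adam mini-batch training monitored by validation AUC.

    Halts after ``config.patience`` epochs without AUC improvement or at
    ``config.max_epochs``; the model is restored to its best-AUC epoch and
    that AUC returned. Non-finite loss aborts with a diagnostic.
    """
    optimizer = Adam(model.parameters(), learning_rate=config.learning_rate)
    val_batch = make_batch(val_graphs, label_task=label_task)
    mode = "binary" if config.n_output_logits == 1 else "two_class"
    train_graphs = list(train_graphs)
    n = len(train_graphs)
    best_state: list[np.ndarray] = model.state_dict()
    best_auc = -np.inf

    def epoch_fn(epoch: int) -> float:
        nonlocal best_state, best_auc
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch_graphs = [train_graphs[i] for i in order[start : start + config.batch_size]]
            batch = make_batch(batch_graphs, label_task=label_task)
            loss = logit_loss(model.forward(batch, rng=rng), batch.labels, mode=mode)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        auc = roc_auc(predict_scores(model, val_batch), val_batch.labels)
        if auc > best_auc:
            best_auc = auc
            best_state = model.state_dict()
        return auc

    outcome = run_early_stopping(
        epoch_fn, patience=config.patience, max_epochs=config.max_epochs
    )
    model.load_state(best_state)
    return model, float(outcome.best_score)


# --- index tracking (leakage audit) ------------------------------------------


class IndexTracker:
    """Records every dataset index touched per outer fold during selection or
    training, so outer evaluation can prove leakage freedom."""

    def __init__(self, outer_k: int):
        self.touched: list[set[int]] = [set() for _ in range(outer_k)]

    def record(self, outer_index: int, indices: Sequence[int]) -> None:
        self.touched[outer_index].update(int(i) for i in np.asarray(indices).ravel())

    def assert_disjoint(self, outer_index: int, test_indices: Sequence[int]) -> None:
        overlap = self.touched[outer_index] & {int(i) for i in test_indices}
        if overlap:
            raise RuntimeError(
                f"leakage: outer fold {outer_index} test indices {sorted(overlap)[:5]} "
                "were touched during training/selection"
            )


# --- protocol stages ---------------------------------------------------------


def _fit_on_inner_folds(
    dataset: GraphDataset,
    plan: FoldPlan,
    outer_index: int,
    config: ModelConfig,
    tracker: IndexTracker | None,
    label_task: int | None,
) -> list[float]:
    """Train a fresh model per inner fold; return the validation AUCs."""
    aucs = []
    for inner_index in range(plan.inner_k):
        train_idx, val_idx = plan.inner_split(outer_index, inner_index)
        if tracker is not None:
            tracker.record(outer_index, train_idx)
            tracker.record(outer_index, val_idx)
        model = xavier_init(GNNModel(config), config.seed)
        rng = np.random.default_rng([config.seed, outer_index, inner_index])
        try:
            _, auc = train_with_early_stopping(
                model,
                dataset.subset(train_idx),
                dataset.subset(val_idx),
                config,
                rng,
                label_task=label_task,
            )
        except (FloatingPointError, ValueError):
            auc = 0.0  # invalid trial, logged by caller
        aucs.append(auc)
    return aucs


def inner_grid_search(
    dataset: GraphDataset,
    plan: FoldPlan,
    outer_index: int,
    grid: HyperparamGrid,
    base_config: ModelConfig,
    tracker: IndexTracker | None = None,
    label_task: int | None = None,
) -> tuple[dict, list[TrialScores]]:
    """Grid search on one outer fold's inner splits; combined-rank winner."""
    trials = []
    configs = enumerate_grid(grid)
    for k, params in enumerate(configs):
        config = ModelConfig(
            **{
                **_config_dict(base_config),
                **params,
            }
        )
        aucs = _fit_on_inner_folds(
            dataset, plan, outer_index, config, tracker, label_task
        )
        trials.append(TrialScores(trial_id=f"config{k}", aucs=aucs))
    winner = combined_rank_select(trials)
    return configs[winner], trials


def seed_reinit_search(
    dataset: GraphDataset,
    plan: FoldPlan,
    outer_index: int,
    config: ModelConfig,
    seeds: Sequence[int],
    tracker: IndexTracker | None = None,
    label_task: int | None = None,
) -> tuple[int, list[TrialScores]]:
    """Retrain the fixed config under each seed; combined-rank winning seed."""
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    trials = []
    for seed in seeds:
        cfg = ModelConfig(**{**_config_dict(config), "seed": int(seed)})
        aucs = _fit_on_inner_folds(
            dataset, plan, outer_index, cfg, tracker, label_task
        )
        trials.append(TrialScores(trial_id=f"seed{seed}", aucs=aucs))
    winner = combined_rank_select(trials)
    return int(seeds[winner]), trials


def warm_start_run(
    model: GNNModel,
    dataset: GraphDataset,
    plan: FoldPlan,
    outer_index: int,
    config: ModelConfig,
    rng: np.random.Generator,
    tracker: IndexTracker | None = None,
    label_task: int | None = None,
) -> tuple[GNNModel, list[float]]:
    """One warm-start run: train through inner folds 1..k sequentially,
    parameters persisting between folds; returns the per-fold val AUCs."""
    aucs = []
    for inner_index in range(plan.inner_k):
        train_idx, val_idx = plan.inner_split(outer_index, inner_index)
        if tracker is not None:
            tracker.record(outer_index, train_idx)
            tracker.record(outer_index, val_idx)
        model, auc = train_with_early_stopping(
            model,
            dataset.subset(train_idx),
            dataset.subset(val_idx),
            config,
            rng,
            label_task=label_task,
        )
        aucs.append(auc)
    return model, aucs


@dataclass
class WarmStartTrace:
    """Pooled validation-AUC history of the warm-start stage.

    ``runs[r]`` holds, per outer fold, that run's inner-fold validation AUCs
    (inner_k values per fold; pooled they form the sample the stopping rule
    tests)."""

    runs: list[list[list[float]]] = field(default_factory=list)
    p_values: list[tuple[float, float] | None] = field(default_factory=list)

    def pooled(self, run_index: int) -> np.ndarray:
        return np.concatenate([np.asarray(a) for a in self.runs[run_index]])

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def stopping_decision(
    trace: WarmStartTrace, alpha: float = 0.05
) -> Literal["continue", "halt"]:
    """Continue before 3 completed runs; afterwards halt iff the one-sided
    rank-sum p-values of the current run against each of the two previous
    runs both exceed the Sidak-corrected level (no significant improvement)."""
    if trace.n_runs < 3:
        return "continue"
    corrected = sidak_alpha(alpha, 2)
    current = trace.pooled(trace.n_runs - 1)
    ps = []
    for back in (2, 1):
        previous = trace.pooled(trace.n_runs - 1 - back)
        ps.append(
            wilcoxon_rank_sum(current, previous, "one_sided", "greater").p_value
        )
    trace.p_values.append((ps[0], ps[1]))
    return "halt" if all(p > corrected for p in ps) else "continue"


# --- outer evaluation ---------------------------------------------------------


@dataclass
class OuterEvaluation:
    folds: list[MetricReport]
    mean: dict[str, float]
    std: dict[str, float]


def evaluate_outer(
    models: Sequence[GNNModel],
    dataset: GraphDataset,
    plan: FoldPlan,
    tracker: IndexTracker | None = None,
    label_task: int | None = None,
) -> OuterEvaluation:
    """Score one final model per outer fold on its held-out test fold.

    The tracker audit raises if any test index was seen during that fold's
    training or selection. Aggregates are population mean and std (ddof=0)
    over the outer folds.
    """
    if len(models) != plan.outer_k:
        raise ValueError("need exactly one model per outer fold")
    reports = []
    for outer_index, model in enumerate(models):
        test_idx = plan.outer_folds[outer_index]
        if tracker is not None:
            tracker.assert_disjoint(outer_index, test_idx)
        batch = make_batch(dataset.subset(test_idx), label_task=label_task)
        reports.append(scores_to_report(predict_scores(model, batch), batch.labels))
    metric_names = ("auc", "acc", "f1", "mcc")
    values = {m: np.array([getattr(r, m) for r in reports]) for m in metric_names}
    return OuterEvaluation(
        folds=reports,
        mean={m: float(v.mean()) for m, v in values.items()},
        std={m: float(v.std()) for m, v in values.items()},
    )


# --- full protocol ------------------------------------------------------------


@dataclass
class ProtocolResult:
    plan: FoldPlan
    best_configs: list[dict]
    best_seeds: list[int]
    grid_trials: list[list[TrialScores]]
    seed_trials: list[list[TrialScores]]
    trace: WarmStartTrace
    evaluation: OuterEvaluation


def _config_dict(config: ModelConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def run_protocol(
    dataset: GraphDataset,
    base_config: ModelConfig,
    grid: HyperparamGrid,
    *,
    outer_k: int = 4,
    inner_k: int = 5,
    n_seeds: int = 20,
    alpha: float = 0.05,
    max_warm_runs: int = 10,
    seed: int = 0,
    label_task: int | None = None,
) -> ProtocolResult:
    """The full nested-CV + warm-start protocol on one featurised dataset.

    ``max_warm_runs`` caps the warm-start stage so pathological data cannot
    loop forever; the model evaluated on each outer test fold is the final
    warm-started state after the last completed run.
    """
    labels = np.array(
        [
            g.label[label_task] if isinstance(g.label, tuple) else g.label
            for g in dataset.graphs
        ],
        dtype=int,
    )
    plan = make_fold_plan(labels, outer_k=outer_k, inner_k=inner_k, seed=seed)
    tracker = IndexTracker(outer_k)

    best_configs: list[dict] = []
    best_seeds: list[int] = []
    grid_trials = []
    seed_trials = []
    fold_configs: list[ModelConfig] = []
    models: list[GNNModel] = []
    rngs: list[np.random.Generator] = []

    seeds = [seed * 1009 + 7 * s for s in range(n_seeds)]
    for outer_index in range(outer_k):
        params, trials = inner_grid_search(
            dataset, plan, outer_index, grid, base_config, tracker, label_task
        )
        grid_trials.append(trials)
        best_configs.append(params)
        config = ModelConfig(**{**_config_dict(base_config), **params})
        best_seed, strials = seed_reinit_search(
            dataset, plan, outer_index, config, seeds, tracker, label_task
        )
        seed_trials.append(strials)
        best_seeds.append(best_seed)
        config = ModelConfig(**{**_config_dict(config), "seed": best_seed})
        fold_configs.append(config)
        models.append(xavier_init(GNNModel(config), best_seed))
        rngs.append(np.random.default_rng([best_seed, outer_index, 9999]))

    trace = WarmStartTrace()
    for run_index in range(max_warm_runs):
        run_aucs: list[list[float]] = []
        for outer_index in range(outer_k):
            models[outer_index], aucs = warm_start_run(
                models[outer_index],
                dataset,
                plan,
                outer_index,
                fold_configs[outer_index],
                rngs[outer_index],
                tracker,
                label_task,
            )
            run_aucs.append(aucs)
        trace.runs.append(run_aucs)
        if stopping_decision(trace, alpha) == "halt":
            break

    evaluation = evaluate_outer(models, dataset, plan, tracker, label_task)
    return ProtocolResult(
        plan=plan,
        best_configs=best_configs,
        best_seeds=best_seeds,
        grid_trials=grid_trials,
        seed_trials=seed_trials,
        trace=trace,
        evaluation=evaluation,
    )
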