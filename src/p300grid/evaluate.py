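"""Train/test protocol, the multiplicative balanced accuracy, and the grid run.

The split shuffles target and nontarget trials separately and puts half of
each class in each set, so a full simulated subject (2160 trials, 360
targets) yields ~180 targets and ~900 nontargets per set. Because the
classes are this imbalanced, performance is scored as

    accuracy = (TP / P) * (TN / N)

the product of the per-class recalls: a classifier that writes off either
class entirely scores 0, where plain accuracy would still report 0.83 for
an all-nontarget predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnn
from .input_builder import build_tensor_stack, load_layout
from .preprocess import Epoch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalCounts:
    """Confusion counts for one evaluation: TP of P targets, TN of N nontargets."""

    TP: int
    TN: int
    P: int
    N: int

    def __post_init__(self) -> None:
        if self.P <= 0 or self.N <= 0:
            raise ValueError("both classes must be present (P > 0 and N > 0)")
        if not (0 <= self.TP <= self.P and 0 <= self.TN <= self.N):
            raise ValueError("need 0 <= TP <= P and 0 <= TN <= N")


def balanced_accuracy(counts: EvalCounts) -> float:
    """(TP/P) * (TN/N) — the product of target and nontarget recalls."""
    return (counts.TP / counts.P) * (counts.TN / counts.N)


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return EvalCounts(
        TP=int((y_true & y_pred).sum()),
        TN=int((~y_true & ~y_pred).sum()),
        P=int(y_true.sum()),
        N=int((~y_true).sum()),
    )


def split_train_test(
    epochs: list[Epoch], seed: int = 0
) -> tuple[list[Epoch], list[Epoch]]:
    """Class-stratified 50/50 split, shuffled within each class.

    Odd class counts put the extra example in the training set. Disjoint,
    exhaustive, reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    targets = [i for i, ep in enumerate(epochs) if ep.is_target]
    nontargets = [i for i, ep in enumerate(epochs) if not ep.is_target]
    if len(targets) < 2 or len(nontargets) < 2:
        raise ValueError("each class needs >= 2 examples to split in half")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for pool in (targets, nontargets):
        perm = rng.permutation(len(pool))
        half = (len(pool) + 1) // 2  # extra example goes to training
        train_idx += [pool[j] for j in perm[:half]]
        test_idx += [pool[j] for j in perm[half:]]
    return [epochs[i] for i in sorted(train_idx)], [epochs[i] for i in sorted(test_idx)]


def cell_seed(master_seed: int, subject: int, trial_length_ms: float,
              patch_code: str, stride: str) -> int:
    """Deterministic per-cell seed (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence(
        [master_seed, subject, int(trial_length_ms),
         int(patch_code), cnn.POOL_STRIDES.index(stride)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_cell(
    train_epochs: list[Epoch],
    test_epochs: list[Epoch],
    patch_code: str,
    stride: str = "default",
    input_kind: str = "3d",
    cfg: cnn.TrainConfig | None = None,
    layout=None,
) -> tuple[float, EvalCounts]:
    """Train one model on the train set, score it on the test set."""
    layout = layout if layout is not None else load_layout()
    spec = cnn.ModelSpec(
        patches=cnn.decode_patch_code(patch_code, stride), input_kind=input_kind
    )
    Xtr, ytr = build_tensor_stack(train_epochs, layout, kind=input_kind)
    Xte, yte = build_tensor_stack(test_epochs, layout, kind=input_kind)
    net = cnn.train(spec, Xtr, ytr, cfg)
    counts = counts_from_predictions(yte, net.predict(Xte))
    return balanced_accuracy(counts), counts


def run_grid(
    epochs_by_subject: dict[tuple[int, float], list[Epoch]],
    grid: list[dict],
    cfg: cnn.TrainConfig | None = None,
    master_seed: int = 0,
    input_kind: str = "3d",
) -> pd.DataFrame:
    """Run every grid cell -> tidy results table (one row per trained model).

    ``epochs_by_subject`` maps (subject, trial_length_ms) to that subject's
    epochs. Each cell gets its own split and training seed derived from the
    master seed, so any single cell reproduces independently. Failed cells
    are recorded with accuracy NaN and the failure reason; the run continues.
    """
    base = cfg if cfg is not None else cnn.TrainConfig()
    layout = load_layout()
    split_cache: dict[tuple[int, float], tuple[list[Epoch], list[Epoch]]] = {}
    rows = []
    for cell in grid:
        subj, tl = cell["subject"], cell["trial_length_ms"]
        code, stride = cell["patch_code"], cell["pool_stride"]
        key = (subj, tl)
        if key not in split_cache:
            split_cache[key] = split_train_test(
                epochs_by_subject[key], seed=cell_seed(master_seed, subj, tl, "00", "default")
            )
        tr, te = split_cache[key]
        seed = cell_seed(master_seed, subj, tl, code, stride)
        try:
            acc, counts = evaluate_cell(
                tr, te, code, stride, input_kind=input_kind,
                cfg=cnn.TrainConfig(
                    learning_rate=base.learning_rate,
                    batch_size=base.batch_size,
                    n_epochs=base.n_epochs,
                    hidden_units=base.hidden_units,
                    seed=seed,
                ),
                layout=layout,
            )
            rows.append({**cell, "accuracy": acc, "TP": counts.TP, "TN": counts.TN,
                         "P": counts.P, "N": counts.N, "error": ""})
        except Exception as exc:  # noqa: BLE001 - a cell failure must not kill the run
            logger.warning("cell %s failed: %s", cell, exc)
            rows.append({**cell, "accuracy": np.nan, "TP": -1, "TN": -1,
                         "P": -1, "N": -1, "error": str(exc)})
        logger.info("cell %s done", cell)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Highest / lowest / average accuracy per trial length (subject-averaged)."""
    mean_tbl = (
        results.groupby(["trial_length_ms", "patch_code", "pool_stride"])["accuracy"]
        .mean()
        .reset_index()
    )
    out = (
        mean_tbl.groupby("trial_length_ms")["accuracy"]
        .agg(highest="max", lowest="min", average="mean")
        .reset_index()
    )
    return out.sort_values("trial_length_ms", ascending=False).reset_index(drop=True)
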