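"""End-to-end detection: filter -> segment -> TFR -> features -> classify.

`run_detection` slides fixed-length windows over a recording, scores each
with the trained classifier and merges adjacent above-threshold windows
into detected events.  `score_events` matches detected against true
events one-to-one by onset distance and reports event-level
precision/recall/F1.  `sweep` is the architecture-sweep harness (hidden
layers x neurons per layer x activation) that reproduces the
model-selection protocol grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .core import KCOMPLEX, Event, EventList, Signal
from .features import TFRFeatureExtractor
from .mlp import MLPNetClassifier, TrainConfig, _set_metrics, _one_hot
from .preprocess import segment

SWEEP_LAYERS = tuple(range(1, 8))
SWEEP_NEURONS = (8, 16, 32, 64, 128, 256)
SWEEP_ACTIVATIONS = ("tanh", "sigmoid", "arctan")


@dataclass
class DetectionConfig:
    win_s: float = 2.0
    hop_s: float = 0.5
    threshold: float = 0.5
    merge_gap_s: float = 0.25
    event_duration_s: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class DetectionResult:
    probabilities: np.ndarray
    window_starts_s: np.ndarray
    events: EventList
    config: DetectionConfig

    def __post_init__(self) -> None:
        if self.probabilities.size and (
            self.probabilities.min() < 0 or self.probabilities.max() > 1
        ):
            raise ValueError("probabilities must lie in [0, 1]")


def run_detection(
    record: Signal,
    clf: MLPNetClassifier,
    featurizer: TFRFeatureExtractor,
    cfg: DetectionConfig | None = None,
) -> DetectionResult:
    """Detect K-complexes in a recording with a trained classifier.

    Windows whose positive-class probability exceeds the threshold are
    merged (while consecutive positive windows are separated by at most
    ``merge_gap_s``) into one event; the reported onset centers the
    nominal event duration on the merged span.  Deterministic given its
    inputs.
    """
    cfg = cfg or DetectionConfig()
    if record.fs != featurizer.fs:
        raise ValueError(
            f"record fs {record.fs} != featurizer fs {featurizer.fs}"
        )
    ds = segment(record, None, win_s=cfg.win_s, hop_s=cfg.hop_s)
    if len(ds) == 0:
        return DetectionResult(
            np.empty(0), np.empty(0), EventList([]), cfg
        )
    feats = featurizer.transform(np.real(ds.X))
    proba = clf.predict_proba(feats)[:, 1]
    starts = ds.meta["start_s"].to_numpy()
    events: list[Event] = []
    pos = np.flatnonzero(proba > cfg.threshold)
    if pos.size:
        group = [pos[0]]
        groups = []
        for i in pos[1:]:
            # merge while positive windows abut within the gap tolerance
            if starts[i] - (starts[group[-1]] + cfg.win_s) <= cfg.merge_gap_s:
                group.append(i)
            else:
                groups.append(group)
                group = [i]
        groups.append(group)
        for grp in groups:
            span0 = starts[grp[0]]
            span1 = starts[grp[-1]] + cfg.win_s
            center = 0.5 * (span0 + span1)
            onset = max(0.0, center - cfg.event_duration_s / 2)
            events.append(
                Event(onset, cfg.event_duration_s, KCOMPLEX)
            )
    result_events = EventList(sorted(events, key=lambda e: e.onset_s))
    return DetectionResult(proba, starts, result_events, cfg)


@dataclass
class EventScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True


def score_events(
    pred: EventList, truth: EventList, tol_s: float = 0.5
) -> EventScore:
    """Greedy one-to-one event matching by onset distance <= tol_s."""
    p_onsets = list(pred.onsets())
    t_onsets = list(truth.onsets())
    pairs = sorted(
        (
            (abs(po - to), i, j)
            for i, po in enumerate(p_onsets)
            for j, to in enumerate(t_onsets)
        ),
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for d, i, j in pairs:
        if d > tol_s:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = len(p_onsets) - tp
    fn = len(t_onsets) - tp
    if len(p_onsets) > 0:
        precision = tp / len(p_onsets)
        precision_defined = True
    else:
        precision = 0.0
        precision_defined = False
    recall = tp / len(t_onsets) if t_onsets else (1.0 if not p_onsets else 0.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EventScore(tp, fp, fn, precision, recall, f1, precision_defined)


def sweep_grid(
    layers=SWEEP_LAYERS, neurons=SWEEP_NEURONS, activations=SWEEP_ACTIVATIONS
) -> list[tuple[int, int, str]]:
    """Enumerate the (n_layers, n_neurons, activation) sweep grid."""
    return list(product(layers, neurons, activations))


def sweep(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    *,
    grid: list[tuple[int, int, str]] | None = None,
    epochs: int = 100,
    lr: float = 1e-5,
    seed: int | None = None,
    fast: bool = False,
) -> pd.DataFrame:
    """Train one classifier per grid point; tabulate costs and accuracies.

    ``fast=True`` caps epochs at 10 (a smoke-test mode).  Rows mirror the
    protocol tables: per-configuration training/testing cost and accuracy
    of the selected snapshot, plus the selected epoch.
    """
    grid = grid if grid is not None else sweep_grid()
    epochs_eff = min(epochs, 10) if fast else epochs
    rows = []
    for n_layers, n_neurons, act in grid:
        clf = MLPNetClassifier(
            hidden_layer_sizes=(n_neurons,) * n_layers,
            activation=act,
            learning_rate=lr,
            epochs=epochs_eff,
            random_state=seed,
        )
        clf.fit(X_train, y_train, eval_set=(X_test, y_test))
        y01 = np.searchsorted(clf.classes_, y_train)
        tr_cost, tr_acc = _set_metrics(clf.model_, np.asarray(X_train, float), _one_hot(y01))
        y01t = np.searchsorted(clf.classes_, y_test)
        te_cost, te_acc = _set_metrics(clf.model_, np.asarray(X_test, float), _one_hot(y01t))
        rows.append(
            {
                "n_layers": n_layers,
                "n_neurons": n_neurons,
                "activation": act,
                "train_cost": tr_cost,
                "train_accuracy": 100.0 * tr_acc,
                "test_cost": te_cost,
                "test_accuracy": 100.0 * te_acc,
                "selected_epoch": clf.history_.selected_epoch,
            }
        )
    return pd.DataFrame(rows)


def best_of_sweep(table: pd.DataFrame) -> pd.Series:
    """Row with the minimal test cost (the sweep's selection rule)."""
    return table.loc[table["test_cost"].idxmin()]
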