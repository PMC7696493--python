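"""Classifier evaluation metrics and the four-way model comparison.

All metrics are on the percent scale.  Per-node precision and recall treat
each tree node as its own binary problem on the samples that reach it
(node 1 sees everything; node 2 the samples node 1 rejected; node 3 the
rest).  F1 is the harmonic mean of precision and recall, the G index their
geometric mean sqrt(P*R); harmonic <= geometric, with equality iff P = R.
The precision summary reports the arithmetic mean and the *population*
standard deviation (divisor 3) of the three per-node precisions.

``compare_models`` trains BP, SVM, PSO-BP and PSO-SVM on one identical
train split and scores them on one identical test split, producing a
metrics report per model plus actual-vs-predicted plot data.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines, pso
from .denoise import ShrinkageSpec, denoise_recording
from .features import (
    LabeledDataset,
    extract,
    group_representatives,
    apply_standardization,
    split_cycles,
    standardize,
)
from .sim import SimConfig, generate_recording
from .svm import PEEL_ORDER, train_tree, predict_tree

__all__ = [
    "MetricsReport",
    "recognition_rate",
    "precision_recall",
    "f1_score",
    "g_index",
    "precision_summary",
    "node_confusions",
    "build_report",
    "compare_models",
    "default_benchmark",
    "round_half_up",
]

log = logging.getLogger("cyclephase")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for displayed table cells."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def recognition_rate(per_phase_correct: Sequence[int], n_total: int) -> float:
    """Overall recognition rate (%): 100 * sum(correct) / n_total."""
    counts = np.asarray(per_phase_correct)
    if n_total == 0:
        raise ValueError("n_total must be positive")
    if (counts < 0).any() or counts.sum() > n_total:
        raise ValueError("invalid per-phase correct counts")
    return 100.0 * float(counts.sum()) / float(n_total)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision and recall (%) from binary confusion counts.

    An empty denominator yields 0 with a warning.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    if tp == fp == fn == 0:
        raise ValueError("all-zero confusion: nothing to score")
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive samples; recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = 100.0 * tp / (tp + fn)
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) on the percent scale."""
    _check_pct(precision, recall)
    if precision == recall == 0:
        warnings.warn("precision and recall both 0; F1 set to 0", stacklevel=2)
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def g_index(precision: float, recall: float) -> float:
    """Geometric mean sqrt(P*R) on the percent scale; always >= F1."""
    _check_pct(precision, recall)
    return float(np.sqrt(precision * recall))


def _check_pct(*values: float) -> None:
    for v in values:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percent value out of [0, 100]: {v}")


def precision_summary(precisions: Sequence[float]) -> tuple[float, float]:
    """Mean and population standard deviation (divisor 3) of the three
    per-node precisions (%)."""
    p = np.asarray(precisions, dtype=float)
    if p.shape != (3,):
        raise ValueError("exactly three per-node precisions expected")
    return float(p.mean()), float(p.std())  # np.std: population by default


def node_confusions(y_true: np.ndarray, y_pred: np.ndarray) -> list[dict]:
    """Binary confusion counts for the three peel nodes.

    Node i scores phase ``PEEL_ORDER[i]`` as the positive class on the
    samples whose predicted path reaches it (i.e. not claimed by an earlier
    node's prediction).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = []
    reach = np.ones(len(y_true), dtype=bool)
    for phase in PEEL_ORDER:
        t = y_true[reach] == phase
        p = y_pred[reach] == phase
        out.append(
            {
                "tp": int(np.sum(t & p)),
                "fp": int(np.sum(~t & p)),
                "fn": int(np.sum(t & ~p)),
                "tn": int(np.sum(~t & ~p)),
            }
        )
        reach = reach & (y_pred != phase)
    return out


@dataclass
class MetricsReport:
    """Per-node and overall recognition metrics of one classifier (%)."""

    precision: list[float]  # per node
    recall: list[float]
    f1: list[float]
    g: list[float]
    per_phase_correct: list[int]  # phases 1..4
    n_test: int
    rate: float
    precision_avg: float
    precision_std: float

    def to_dict(self) -> dict:
        return {
            "recognition_rate": self.rate,
            "per_phase_correct": self.per_phase_correct,
            "n_test": self.n_test,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "g_index": self.g,
            "precision_avg": self.precision_avg,
            "precision_std": self.precision_std,
        }


def build_report(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Full metrics report from true and predicted phase labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    per_phase = [int(np.sum((y_true == p) & (y_pred == p))) for p in (1, 2, 3, 4)]
    rate = recognition_rate(per_phase, len(y_true))
    prec, rec, f1s, gs = [], [], [], []
    for conf in node_confusions(y_true, y_pred):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision_recall(conf["tp"], conf["fp"], conf["fn"])
            f1s.append(f1_score(p, r))
        prec.append(p)
        rec.append(r)
        gs.append(g_index(p, r))
    avg, std = precision_summary(prec)
    return MetricsReport(
        precision=prec, recall=rec, f1=f1s, g=gs, per_phase_correct=per_phase,
        n_test=len(y_true), rate=rate, precision_avg=avg, precision_std=std,
    )


@dataclass
class ComparisonResult:
    """Reports and predictions of the four-way comparison."""

    reports: dict  # model name -> MetricsReport
    predictions: pd.DataFrame  # columns: index, actual, one column per model

    def tables(self) -> dict[str, pd.DataFrame]:
        """Five tabular views (counts, precision, recall, F1, G index)."""
        names = list(self.reports)
        counts = pd.DataFrame(
            [r.per_phase_correct + [sum(r.per_phase_correct), round_half_up(r.rate)]
             for r in self.reports.values()],
            index=names,
            columns=["pedaling", "lower_buffer", "relaxation", "upper_buffer",
                     "sum", "recognition_rate_pct"],
        )
        def node_table(attr, extra=None):
            rows = []
            for r in self.reports.values():
                row = [round_half_up(v) for v in getattr(r, attr)]
                if extra:
                    row += [round_half_up(getattr(r, e)) for e in extra]
                rows.append(row)
            cols = ["classifier_1", "classifier_2", "classifier_3"]
            if extra:
                cols += list(extra)
            return pd.DataFrame(rows, index=names, columns=cols)

        return {
            "counts": counts,
            "precision": node_table("precision", extra=("precision_avg",
                                                        "precision_std")),
            "recall": node_table("recall"),
            "f1": node_table("f1"),
            "g_index": node_table("g"),
        }


MODEL_NAMES = ("BP", "SVM", "PSO-BP", "PSO-SVM")


def compare_models(
    train: LabeledDataset,
    test: LabeledDataset,
    seed: int = 0,
    svm_params: tuple[float, float] = (2.0, 1.0),
    n_folds: int = 10,
    pso_svm_swarm: pso.SwarmConfig | None = None,
    pso_bp_swarm: pso.SwarmConfig | None = None,
) -> ComparisonResult:
    """Train BP, SVM, PSO-BP and PSO-SVM on one split and score them on the
    other.

    Features are standardized with training-set statistics only.  The plain
    SVM uses ``svm_params`` (default C = 2, gamma = 1); PSO-SVM tunes
    (C, gamma) by swarm search on the K-fold CV recognition rate.  The
    swarm settings default to desk-scale runs (10 particles x 30 iterations
    for the 2-D kernel search, 20 x 60 for the weight search) with early
    stopping.
    """
    train_std, (mean, scale) = standardize(train)
    test_std = apply_standardization(test, mean, scale)

    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, *exc):
                timings[name] = time.perf_counter() - self_.t0
                log.info("%s: %.2f s", name, timings[name])

        return _T()

    preds: dict[str, np.ndarray] = {}

    with timed("BP"):
        bp_spec = baselines.MlpSpec(seed=seed)
        bp = baselines.train_bp(train_std, bp_spec)
        preds["BP"] = baselines.predict_mlp(bp, test_std.X)

    with timed("SVM"):
        tree = train_tree(train_std, svm_params)
        preds["SVM"] = predict_tree(tree, test_std.X)

    with timed("PSO-BP"):
        # the weight search keeps the full iteration budget (its CV-accuracy
        # fitness is quantized in 1/n steps, so the stagnation-based early
        # stop would fire long before the swarm has settled) and the
        # exploratory raw-fitness inertia reading, which suits the
        # multimodal 64-dimensional weight landscape
        bp_swarm = pso_bp_swarm or pso.SwarmConfig(
            n_particles=20, max_iter=200, seed=seed, patience=200,
            literal_inertia=True,
            bounds=(np.full(bp_spec.n_weights, -5.0), np.full(bp_spec.n_weights, 5.0)),
        )
        psobp = baselines.train_pso_bp(train_std, bp_spec, swarm=bp_swarm,
                                       n_folds=n_folds)
        preds["PSO-BP"] = baselines.predict_mlp(psobp, test_std.X)

    with timed("PSO-SVM"):
        svm_swarm = pso_svm_swarm or pso.SwarmConfig(
            n_particles=10, max_iter=30, seed=seed, patience=10
        )
        params, _, _ = pso.tune_tree_params(train_std, swarm=svm_swarm,
                                            n_folds=n_folds)
        tuned = train_tree(train_std, params)
        preds["PSO-SVM"] = predict_tree(tuned, test_std.X)

    reports = {name: build_report(test.y, preds[name]) for name in MODEL_NAMES}
    frame = pd.DataFrame({"index": np.arange(len(test)), "actual": test.y})
    for name in MODEL_NAMES:
        frame[name] = preds[name]
    return ComparisonResult(reports=reports, predictions=frame)


def default_benchmark(
    seed: int = 0,
    n_cycles: int = 50,
    snr_db: float = 10.0,
    denoise: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """The standard synthetic benchmark: simulate ``n_cycles`` riding cycles
    at the given vibration SNR, denoise, extract per-sample features,
    collapse to per-(cycle, phase) group representatives (4 groups per
    cycle), and split half the cycles into training and half into testing.

    With the 50-cycle default this yields 200 groups, 100 train / 100 test.
    """
    rec = generate_recording(
        SimConfig(n_cycles=n_cycles, vibration_snr_db=snr_db, seed=seed)
    )
    if denoise and np.isfinite(snr_db):
        rec = denoise_recording(rec, ShrinkageSpec())
    groups = group_representatives(extract(rec))
    half = n_cycles // 2
    return split_cycles(groups, half, n_cycles - half, seed=seed)
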