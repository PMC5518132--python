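"""Benchmark harness: ROC/AUC and recall/precision/F1 on simulated screens.

Hit calling is evaluated separately per selection direction. For a given
direction, genes are ranked by that direction's p-value (ascending); the
positives are the true hits of that direction and the negatives are every
other gene — including true hits of the opposite direction, which a
direction-specific caller should not flag. Curves from repeated simulations
are combined by vertical averaging (TPR interpolated on a common FPR grid)
and summarized by the trapezoid AUC of the averaged curve. Classification
metrics are taken at a fixed BH level: recall is the fraction of true hits
recovered, precision the fraction of calls that are true (1 - precision is
the empirical FDR), and F1 their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .core import PBNPAConfig, PBNPAResult, pbnpa, pbnpa_replicates
from .simulate import SimulationConfig, TruthTable, simulate_screen

__all__ = [
    "ROCCurve",
    "EvaluationReport",
    "roc_curve",
    "average_roc",
    "recall_precision_f1",
    "called_genes",
    "run_benchmark",
]

DEFAULT_FPR_GRID = 1001

REPLICATE_STUDY_DIVISOR = 5.0  # low-quality (high-overdispersion) replicates


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvaluationReport:
    """Aggregated benchmark results for one direction of selection.

    ``roc`` is the vertically averaged curve on a fixed FPR grid and
    ``auc`` its trapezoid area. ``recall``/``precision``/``f1`` are means
    over datasets of the per-dataset metrics at the configured BH level,
    with standard errors of those means; ``per_dataset`` keeps the raw
    per-dataset values. ``negatives_include_opposite`` records the ROC
    labeling convention so it can be flipped and audited.
    """

    direction: str
    roc: ROCCurve
    auc: float
    recall: float
    precision: float
    f1: float
    recall_se: float
    precision_se: float
    f1_se: float
    n_datasets: int
    per_dataset: pd.DataFrame
    negatives_include_opposite: bool = True


def roc_curve(
    p_values: np.ndarray,
    truth_directions: np.ndarray,
    direction: str,
) -> ROCCurve:
    """ROC of ranking genes by a direction-specific p-value.

    Genes are ranked by ascending p-value; positives are the true hits of
    ``direction`` and negatives are all other genes. Raises if the truth
    labels contain only one class.
    """
    y_true = np.asarray(truth_directions) == direction
    if y_true.all() or not y_true.any():
        raise ValueError("truth labels contain a single class; ROC is undefined")
    score = -np.asarray(p_values, dtype=float)
    fpr, tpr, _ = _skm.roc_curve(y_true, score)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))


def average_roc(
    curves: Sequence[ROCCurve], grid_size: int = DEFAULT_FPR_GRID
) -> ROCCurve:
    """Vertically average ROC curves on a common equispaced FPR grid."""
    if not curves:
        raise ValueError("need at least one ROC curve to average")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    return ROCCurve(fpr=grid, tpr=mean_tpr, auc=float(np.trapezoid(mean_tpr, grid)))


def recall_precision_f1(
    called: Sequence[str] | set,
    truth: TruthTable,
    direction: str,
) -> tuple[float, float, float]:
    """Recall, precision and F1 of a called gene set for one direction.

    An empty call set reports (0, 0, 0) — precision is undefined there and
    is recorded as 0 by convention.
    """
    called = set(called)
    true_set = set(truth.genes_of(direction))
    if not true_set:
        raise ValueError(f"truth table contains no {direction}-direction genes")
    if not called:
        return 0.0, 0.0, 0.0
    tp = len(called & true_set)
    recall = tp / len(true_set)
    precision = tp / len(called)
    f1 = (
        2 * recall * precision / (recall + precision)
        if recall + precision > 0
        else 0.0
    )
    return recall, precision, f1


def called_genes(result: PBNPAResult, direction: str, fdr_level: float) -> set:
    """Genes significant in one direction at a BH level."""
    attr = "fdr_pos" if direction == "positive" else "fdr_neg"
    return {g.gene_id for g in result if getattr(g, attr) <= fdr_level}


def _dataset_seeds(master_seed: int | None, n: int) -> list[int]:
    """Deterministic per-dataset seeds spawned from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_benchmark(
    sim_config: SimulationConfig | None = None,
    pbnpa_config: PBNPAConfig | None = None,
    n_datasets: int = 50,
    directions: Sequence[str] = ("positive", "negative"),
    master_seed: int | None = None,
    grid_size: int = DEFAULT_FPR_GRID,
) -> dict[str, EvaluationReport]:
    """Simulate ``n_datasets`` screens, run the test on each, aggregate.

    Each dataset draws a fresh truth table and fresh counts from a seed
    derived deterministically from ``master_seed``; the test's permutation
    seed is derived from the same stream. Screens with several replicates
    are analyzed per replicate and Fisher-combined. Returns one
    :class:`EvaluationReport` per requested direction.
    """
    sim_config = sim_config or SimulationConfig()
    pbnpa_config = pbnpa_config or PBNPAConfig()
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    seeds = _dataset_seeds(master_seed, n_datasets)

    curves: dict[str, list[ROCCurve]] = {d: [] for d in directions}
    rows: dict[str, list[dict]] = {d: [] for d in directions}
    for k, seed in enumerate(seeds):
        cfg = SimulationConfig(**{**sim_config.to_dict(), "seed": seed})
        screen = simulate_screen(cfg)
        test_cfg = PBNPAConfig(
            n_permutations=pbnpa_config.n_permutations,
            removal_threshold=pbnpa_config.removal_threshold,
            pseudocount=pbnpa_config.pseudocount,
            fdr_level=pbnpa_config.fdr_level,
            seed=seed + 1,
        )
        result = (
            pbnpa_replicates(screen.tables, test_cfg)
            if len(screen.tables) > 1
            else pbnpa(screen.table, test_cfg)
        )
        gene_order = {g: i for i, g in enumerate(screen.truth.gene_ids)}
        order = [gene_order[g.gene_id] for g in result]
        truth_dir = screen.truth.direction[order]
        for d in directions:
            p = np.array([g.p_pos if d == "positive" else g.p_neg for g in result])
            curves[d].append(roc_curve(p, truth_dir, d))
            called = called_genes(result, d, test_cfg.fdr_level)
            rec, prec, f1 = recall_precision_f1(called, screen.truth, d)
            rows[d].append(
                {
                    "dataset": k,
                    "seed": seed,
                    "auc": curves[d][-1].auc,
                    "n_called": len(called),
                    "recall": rec,
                    "precision": prec,
                    "f1": f1,
                }
            )

    reports = {}
    for d in directions:
        df = pd.DataFrame(rows[d])
        avg = average_roc(curves[d], grid_size=grid_size)

        def _se(x: pd.Series) -> float:
            return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

        reports[d] = EvaluationReport(
            direction=d,
            roc=avg,
            auc=avg.auc,
            recall=float(df["recall"].mean()),
            precision=float(df["precision"].mean()),
            f1=float(df["f1"].mean()),
            recall_se=_se(df["recall"]),
            precision_se=_se(df["precision"]),
            f1_se=_se(df["f1"]),
            n_datasets=n_datasets,
            per_dataset=df,
        )
    return reports


def replicate_combination_benchmark(
    sim_config: SimulationConfig | None = None,
    pbnpa_config: PBNPAConfig | None = None,
    n_families: int = 10,
    replicate_subsets: Sequence[int] = (2, 3),
    direction: str = "positive",
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Measure the power gained by Fisher-combining replicate screens.

    Each "family" simulates one low-quality screen — by default three
    replicates sharing a single truth table, with every DM intensity divided
    by 5 so the counts are strongly overdispersed — then analyzes the first
    ``k`` replicates for each ``k`` in ``replicate_subsets``: the test runs
    independently per replicate, per-gene p-values are Fisher-combined, and
    BH is applied at the configured level. Returns one row per (family, k)
    with the number of called genes and how many of them are true hits of
    ``direction``.
    """
    if sim_config is None:
        sim_config = SimulationConfig(
            overdispersion_divisor=REPLICATE_STUDY_DIVISOR, n_replicates=3
        )
    pbnpa_config = pbnpa_config or PBNPAConfig()
    if max(replicate_subsets) > sim_config.n_replicates:
        raise ValueError("replicate subset larger than simulated replicates")
    seeds = _dataset_seeds(master_seed, n_families)
    rows = []
    for fam, seed in enumerate(seeds):
        cfg = SimulationConfig(**{**sim_config.to_dict(), "seed": seed})
        screen = simulate_screen(cfg)
        true_set = set(screen.truth.genes_of(direction))
        for k in replicate_subsets:
            test_cfg = PBNPAConfig(
                n_permutations=pbnpa_config.n_permutations,
                removal_threshold=pbnpa_config.removal_threshold,
                pseudocount=pbnpa_config.pseudocount,
                fdr_level=pbnpa_config.fdr_level,
                seed=seed + 1,
            )
            result = pbnpa_replicates(screen.tables[:k], test_cfg)
            called = called_genes(result, direction, test_cfg.fdr_level)
            rows.append(
                {
                    "family": fam,
                    "seed": seed,
                    "n_replicates": k,
                    "n_called": len(called),
                    "n_true": len(called & true_set),
                }
            )
    return pd.DataFrame(rows)
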