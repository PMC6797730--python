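"""Spike-in quantification benchmarking.

A spike-in mix (e.g. the 67-transcript SIRV E2 mix) has known relative
molar concentrations, so observed quantifications can be scored
directly. Beyond rank/linear correlations, competing technologies are
compared as predictors of the true concentration through log-linear
models

    log(concentration) = mu + beta * log(predictor + pseudocount) + error

evaluated by repeated cross-validation: each of ``n_repeats`` (default
30) rounds draws a fresh random 4/5 train / 1/5 test partition, shared
across all predictors, fits each model on the training spike-ins and
records the mean squared prediction error on the held-out ones. The
spread of the 30 test MSEs gives the reported interval per technology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import ComparisonResult, QuantTable, compare_quant
from .simulate import SpikeInDesign

__all__ = [
    "LogLinearModel",
    "CVModelResult",
    "spikein_correlation",
    "fit_log_linear",
    "cross_validate_predictors",
    "per_spikein_residuals",
    "ResidualReport",
]


@dataclass(frozen=True)
class LogLinearModel:
    """OLS fit of log concentration on log (predictor + pseudocount)."""

    mu: float
    beta: float
    predictor_name: str = ""
    pseudocount: float = 1.0

    def predict_log(self, predictor_values: np.ndarray) -> np.ndarray:
        return self.mu + self.beta * np.log(
            np.asarray(predictor_values, dtype=float) + self.pseudocount
        )


@dataclass(frozen=True)
class CVModelResult:
    """Cross-validated prediction error of one predictor."""

    predictor_name: str
    per_repeat_test_mse: tuple[float, ...]
    n_repeats: int
    train_frac: float
    excluded_ids: frozenset[str] = frozenset()

    @property
    def mse_min(self) -> float:
        return min(self.per_repeat_test_mse)

    @property
    def mse_max(self) -> float:
        return max(self.per_repeat_test_mse)

    @property
    def mse_mean(self) -> float:
        return float(np.mean(self.per_repeat_test_mse))

    @property
    def mse_ci95(self) -> tuple[float, float]:
        """mean +/- 1.96 * SE over repeats (alongside the [min, max] spread)."""
        arr = np.asarray(self.per_repeat_test_mse)
        half = 1.96 * arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        return (float(arr.mean() - half), float(arr.mean() + half))


def spikein_correlation(
    observed: QuantTable, design: SpikeInDesign, pseudocount: float = 1.0
) -> ComparisonResult:
    """Correlate observed quantification with the known concentrations.

    Evaluated over all design ids; observed ids must be a subset of the
    design, and spike-ins without an observed value count as 0.
    """
    unknown = sorted(set(observed.values) - set(design.entries))
    if unknown:
        raise KeyError(f"observed ids missing from the design: {unknown[:10]}")
    truth = QuantTable(
        level=observed.level, unit=observed.unit,
        values={t: design.entries[t] for t in design.ids()},
    )
    return compare_quant(
        observed, truth, pseudocount=pseudocount, restrict=design.ids()
    )


def fit_log_linear(
    pairs: Sequence[tuple[float, float]],
    pseudocount: float = 1.0,
    predictor_name: str = "",
) -> LogLinearModel:
    """OLS of log(concentration) on log(predictor + pseudocount), natural log."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to fit")
    conc = np.array([c for c, _ in pairs], dtype=float)
    pred = np.array([p for _, p in pairs], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    x = np.log(pred + pseudocount)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all values equal on the log scale")
    y = np.log(conc)
    beta, mu = np.polyfit(x, y, 1)
    return LogLinearModel(
        mu=float(mu), beta=float(beta),
        predictor_name=predictor_name, pseudocount=pseudocount,
    )


def cross_validate_predictors(
    design: SpikeInDesign,
    predictors: Mapping[str, QuantTable],
    n_repeats: int = 30,
    train_frac: float = 0.8,
    seed: int = 0,
    exclude: Iterable[str] = (),
    pseudocount: float = 1.0,
) -> dict[str, CVModelResult]:
    """Repeated random-split cross-validation of concentration predictors.

    The same partitions are reused for every predictor within a repeat,
    so MSE differences reflect the predictors, not the folds. Excluded
    ids never appear in any train or test set.
    """
    excluded = frozenset(exclude)
    ids = [t for t in design.ids() if t not in excluded]
    n = len(ids)
    for name, table in predictors.items():
        missing = [t for t in ids if t not in table.values]
        if missing:
            raise KeyError(f"predictor {name!r} missing ids: {missing[:10]}")
    n_train = int(train_frac * n)
    n_test = n - n_train
    if n_test < 2:
        raise ValueError(f"test fold of {n_test} spike-ins is too small")
    conc = np.array([design.entries[t] for t in ids], dtype=float)
    log_conc = np.log(conc)
    values = {
        name: np.array([table.values[t] for t in ids], dtype=float)
        for name, table in predictors.items()
    }
    rng = np.random.default_rng(seed)
    per_name: dict[str, list[float]] = {name: [] for name in predictors}
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        for name in sorted(predictors):
            pred = values[name]
            model = fit_log_linear(
                list(zip(conc[train_idx], pred[train_idx])),
                pseudocount=pseudocount,
                predictor_name=name,
            )
            err = model.predict_log(pred[test_idx]) - log_conc[test_idx]
            per_name[name].append(float(np.mean(err**2)))
    return {
        name: CVModelResult(
            predictor_name=name,
            per_repeat_test_mse=tuple(per_name[name]),
            n_repeats=n_repeats,
            train_frac=train_frac,
            excluded_ids=excluded,
        )
        for name in predictors
    }


@dataclass(frozen=True)
class ResidualReport:
    """Per-spike-in residuals and their cross-replicate reproducibility."""

    residuals: pd.DataFrame  # index: spike-in id, columns: (technology, replicate)
    reproducibility: Mapping[str, float]  # technology -> mean pairwise Spearman
    worst_predicted: Mapping[str, str]  # technology -> id with largest mean sq residual


def per_spikein_residuals(
    design: SpikeInDesign,
    tables: Mapping[tuple[str, str], QuantTable],
    pseudocount: float = 1.0,
) -> ResidualReport:
    """Full-data fit residuals per spike-in, compared across replicates.

    For each (technology, replicate) table a log-linear model is fitted
    on all spike-ins and its residuals (true minus predicted log
    concentration) are collected. Reproducibility of a technology is the mean Spearman
    correlation of residual vectors over its replicate pairs (NaN, i.e.
    undefined, with a single replicate). The worst-predicted spike-in
    per technology has the largest mean squared residual.
    """
    ids = design.ids()
    log_conc = np.log(np.array([design.entries[t] for t in ids]))
    columns: dict[tuple[str, str], np.ndarray] = {}
    for (tech, rep), table in sorted(tables.items()):
        pred = np.array([table.get(t) for t in ids], dtype=float)
        model = fit_log_linear(
            list(zip(np.exp(log_conc), pred)),
            pseudocount=pseudocount, predictor_name=tech,
        )
        columns[(tech, rep)] = log_conc - model.predict_log(pred)
    residuals = pd.DataFrame(columns, index=ids)
    residuals.columns = pd.MultiIndex.from_tuples(
        residuals.columns, names=["technology", "replicate"]
    )
    reproducibility: dict[str, float] = {}
    worst: dict[str, str] = {}
    for tech in sorted({t for t, _ in columns}):
        reps = [columns[key] for key in sorted(columns) if key[0] == tech]
        if len(reps) >= 2:
            rhos = [
                stats.spearmanr(reps[i], reps[j]).statistic
                for i in range(len(reps))
                for j in range(i + 1, len(reps))
            ]
            reproducibility[tech] = float(np.mean(rhos))
        else:
            reproducibility[tech] = float("nan")
        mean_sq = np.mean([r**2 for r in reps], axis=0)
        worst[tech] = ids[int(np.argmax(mean_sq))]
    return ResidualReport(
        residuals=residuals, reproducibility=reproducibility, worst_predicted=worst
    )
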