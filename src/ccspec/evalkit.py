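"""Metrics (MAE, MSE, MRE, R^2) and the repeated random-holdout harness.

Spectrum errors are averaged over wavelengths within a sample, then over
samples; R^2 is the coefficient of determination 1 - SS_res/SS_tot computed
on the pooled flattened values (it can be negative).  Validation draws a
fresh random 10% holdout on every repeat, so that over many repeats nearly
every sample gets its turn in the prediction set; this suits small datasets
better than k-fold splitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ccspec.spectra import Spectrum

__all__ = ["MetricReport", "spectrum_metrics", "matrix_metrics", "repeated_holdout"]

#: |true| below this is excluded from the relative-error mean.
MRE_GUARD = 1e-8


@dataclass(frozen=True)
class MetricReport:
    """Prediction-quality summary.

    r2 is the coefficient of determination (1 - SS_res/SS_tot, possibly
    negative), not a squared correlation.
    """

    mae: float
    mse: float
    mre: float
    r2: float
    n_samples: int
    per_repeat: tuple[dict, ...] | None = None

    def as_dict(self) -> dict:
        d = {
            "mae": self.mae,
            "mse": self.mse,
            "mre": self.mre,
            "r2": self.r2,
            "r2_definition": "coefficient_of_determination",
            "n_samples": self.n_samples,
        }
        if self.per_repeat is not None:
            d["per_repeat"] = list(self.per_repeat)
        return d


def matrix_metrics(true: np.ndarray, pred: np.ndarray) -> MetricReport:
    """Metrics for stacked per-sample vectors (rows = samples)."""
    true = np.atleast_2d(np.asarray(true, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if true.shape != pred.shape:
        raise ValueError(f"shape mismatch: {true.shape} vs {pred.shape}")
    err = pred - true
    # average over wavelengths within each sample, then over samples
    mae = float(np.mean(np.mean(np.abs(err), axis=1)))
    mse = float(np.mean(np.mean(err**2, axis=1)))
    mask = np.abs(true) > MRE_GUARD
    mre = float(np.mean(np.abs(err[mask]) / np.abs(true[mask]))) if mask.any() else 0.0
    flat_t, flat_p = true.ravel(), pred.ravel()
    ss_res = float(np.sum((flat_t - flat_p) ** 2))
    ss_tot = float(np.sum((flat_t - flat_t.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return MetricReport(mae, mse, mre, r2, true.shape[0])


def spectrum_metrics(true: Sequence[Spectrum], pred: Sequence[Spectrum]) -> MetricReport:
    """Metrics for matched lists of spectra (grids must agree)."""
    if len(true) != len(pred):
        raise ValueError(f"count mismatch: {len(true)} vs {len(pred)}")
    for t, p in zip(true, pred):
        if not t.same_grid(p):
            raise ValueError("grid mismatch between true and predicted spectrum")
    T = np.stack([s.absorbance for s in true])
    P = np.stack([s.absorbance for s in pred])
    return matrix_metrics(T, P)


def repeated_holdout(
    dataset: Sequence,
    train_fn: Callable,
    frac: float = 0.10,
    repeats: int = 50,
    seed: int = 0,
) -> MetricReport:
    """The random-resampling validation protocol.

    Each repeat draws floor(frac * n) samples without replacement as the
    prediction set, calls ``train_fn(train_subset)`` to get a predictor, and
    scores ``predictor(test_subset) -> (true_matrix, pred_matrix)``.  The
    report's headline numbers are the means over repeats, with per-repeat
    values attached.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError(f"holdout fraction must be in (0,1), got {frac}")
    n = len(dataset)
    k = int(np.floor(frac * n))
    if k < 1:
        raise ValueError(f"dataset of {n} too small for frac={frac}")
    rng = np.random.default_rng(seed)
    reports: list[MetricReport] = []
    for _ in range(repeats):
        test_idx = set(rng.choice(n, size=k, replace=False).tolist())
        train_set = [dataset[i] for i in range(n) if i not in test_idx]
        test_set = [dataset[i] for i in sorted(test_idx)]
        predictor = train_fn(train_set)
        true_m, pred_m = predictor(test_set)
        reports.append(matrix_metrics(np.asarray(true_m), np.asarray(pred_m)))
    per_repeat = tuple(
        {"mae": r.mae, "mse": r.mse, "mre": r.mre, "r2": r.r2} for r in reports
    )
    return MetricReport(
        mae=float(np.mean([r.mae for r in reports])),
        mse=float(np.mean([r.mse for r in reports])),
        mre=float(np.mean([r.mre for r in reports])),
        r2=float(np.mean([r.r2 for r in reports])),
        n_samples=n,
        per_repeat=per_repeat,
    )
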