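"""Reference synthetic benchmark protocols for both stages.

These run the full pipeline on the default synthetic world and measure
recovery quality: repeated-holdout spectrum error for stage 1, held-out
binary mixing error and the ternary-migration error ratio for stage 2, and
the descriptor-ablation comparison (full descriptors vs group-block-only vs
electronic-block-only).  Problem sizes default to desk scale; they are the
package's reference configuration for a single-CPU run.
"""

from __future__ import annotations

import numpy as np

from ccspec import cgc, mcmix
from ccspec.evalkit import matrix_metrics, repeated_holdout
from ccspec.molfeat import BLOCK_OFFSETS
from ccspec.spectra import UV_GRID, VIS_GRID
from ccspec.synth import make_mixture_corpora, make_stage1_corpus, make_world

__all__ = ["stage1_recovery", "mc_recovery", "ablation_ordering", "ABLATION_VARIANTS"]


def _stage1_train_fn(hidden_a, hidden_b, epochs, seed, mask=None):
    def train_fn(train_subset):
        recs = [(_masked(d, mask), s) for d, s in train_subset]
        m = cgc.train_stage1(
            recs, hidden_a=hidden_a, hidden_b=hidden_b, max_epochs=epochs, seed=seed
        )

        def predictor(test_subset):
            X = np.stack([_masked(d, mask) for d, _ in test_subset])
            T = np.stack([s.absorbance for _, s in test_subset])
            return T, cgc.predict_matrix(m, X)

        return predictor

    return train_fn


def _masked(d: np.ndarray, keep: np.ndarray | None) -> np.ndarray:
    if keep is None:
        return np.asarray(d, dtype=float)
    out = np.zeros_like(np.asarray(d, dtype=float))
    out[keep] = np.asarray(d, dtype=float)[keep]
    return out


def stage1_recovery(
    seed: int = 1,
    n: int = 130,
    repeats: int = 2,
    hidden_a: int = 8,
    hidden_b: int = 8,
    epochs: int = 30,
    frac: float = 0.10,
) -> dict:
    """Repeated-holdout spectrum recovery on the default UV synthetic world."""
    world = make_world(seed=seed, grid=UV_GRID)
    records = make_stage1_corpus(world, n)
    report = repeated_holdout(
        records,
        _stage1_train_fn(hidden_a, hidden_b, epochs, seed),
        frac=frac,
        repeats=repeats,
        seed=seed,
    )
    return {
        "mse": report.mse,
        "mae": report.mae,
        "r2": report.r2,
        "noise_variance": world.noise_sigma**2,
        "n": n,
        "repeats": repeats,
    }


def mc_recovery(
    seed: int = 1,
    n_binary: int = 140,
    n_ternary: int = 15,
    repeats: int = 2,
    hidden: int = 10,
    epochs: int = 40,
    frac: float = 0.10,
) -> dict:
    """Binary mixing recovery plus ternary migration on the visible grid.

    The ternary error uses the ordering-ensemble ('avg') mixing path as the
    headline number; single-path results are reported alongside.
    """
    world = make_world(seed=seed, grid=VIS_GRID)
    binary, multi = make_mixture_corpora(world, n_binary, n_ternary)

    def train_fn(train_subset):
        m = mcmix.train_mix(list(train_subset), hidden=hidden, max_epochs=epochs, seed=seed)

        def predictor(test_subset):
            T = np.stack([r.observed_mixture.absorbance for r in test_subset])
            P = np.stack([mcmix.predict_pair(m, r).absorbance for r in test_subset])
            return T, P

        return predictor

    report = repeated_holdout(binary, train_fn, frac=frac, repeats=repeats, seed=seed)

    final = mcmix.train_mix(binary, hidden=hidden, max_epochs=epochs, seed=seed)
    T3 = np.stack([r.observed_mixture.absorbance for r in multi])
    ternary = {}
    for path in mcmix.PATH_STRATEGIES:
        P3 = np.stack(
            [mcmix.predict_multicomponent(final, r, path).absorbance for r in multi]
        )
        ternary[path] = matrix_metrics(T3, P3).mae
    return {
        "binary_mae": report.mae,
        "binary_r2": report.r2,
        "ternary_mae": ternary["avg"],
        "ternary_mae_by_path": ternary,
        "migration_ratio": ternary["avg"] / report.mae,
        "noise_sigma": world.noise_sigma,
        "n_binary": n_binary,
        "n_ternary": n_ternary,
        "repeats": repeats,
    }


def _block_indices(*names: str) -> np.ndarray:
    idx: list[int] = []
    for name in names:
        lo, hi = BLOCK_OFFSETS[name]
        idx.extend(range(lo, hi))
    return np.asarray(sorted(idx), dtype=int)


#: Feature subsets for the ablation: the full CGC vector, the revised
#: group-contribution part (groups + conjugation + solvent) and the
#: electronic-descriptor part (electronic block + solvent).
ABLATION_VARIANTS = {
    "full": None,
    "group_only": _block_indices("group", "conjugation", "solvent"),
    "electronic_only": _block_indices("electronic", "solvent"),
}


def ablation_ordering(
    n_seeds: int = 10,
    n: int = 110,
    hidden_a: int = 8,
    hidden_b: int = 5,
    epochs: int = 25,
    test_frac: float = 0.15,
    base_seed: int = 100,
) -> dict:
    """Median held-out spectrum MSE per descriptor variant over seeds.

    Each seed draws a fresh world and corpus, trains the three variants on
    an identical split, and scores the held-out MSE; medians over seeds are
    returned together with per-seed values.
    """
    per_variant: dict[str, list[float]] = {k: [] for k in ABLATION_VARIANTS}
    for s in range(n_seeds):
        seed = base_seed + s
        world = make_world(seed=seed, grid=UV_GRID)
        records = make_stage1_corpus(world, n)
        n_test = max(2, int(round(test_frac * n)))
        train, test = records[n_test:], records[:n_test]
        for name, mask in ABLATION_VARIANTS.items():
            fn = _stage1_train_fn(hidden_a, hidden_b, epochs, seed, mask=mask)
            T, P = fn(train)(test)
            per_variant[name].append(matrix_metrics(T, P).mse)
    return {
        "median_mse": {k: float(np.median(v)) for k, v in per_variant.items()},
        "per_seed_mse": per_variant,
        "n_seeds": n_seeds,
        "n": n,
    }
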