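"""Molecule-contribution (MC) mixing: stage 2 of the protocol.

Beer-Lambert additivity makes a mixture spectrum the concentration-weighted
sum of its components' spectra; intermolecular interactions bend this into a
nonlinear superposition.  The analytic form models the deviation with a
pairwise interaction factor, polynomial in the difference between the two
components' group vectors,

    k_ij = c1*d + c2*d^2 + ...   with d = ||a_i - a_j||_1  (k_ii = 0),

entering as  L = sum_i L_i x_i + sum_{i<j} (x_i x_j / (x_i + x_j)) * X * k_ij,
where X is a fixed transformation vector over the wavelength grid.  The
learned model replaces the analytic correction with a network that maps the
two concentration-scaled pure spectra (86 inputs) to the mixed spectrum
(43 outputs); concentrations enter only through Beer-Lambert pre-scaling.
Multicomponent mixtures are predicted without extra training by mixing
sequentially along a virtual path, treating each intermediate mixture as a
pseudo-component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ccspec import brnet
from ccspec.spectra import (
    REFERENCE_CONCENTRATION,
    Spectrum,
    VIS_GRID,
)

__all__ = [
    "MixComponent",
    "MixtureRecord",
    "MCModel",
    "InteractionCoefficients",
    "default_bump_shape",
    "interaction_factor",
    "analytic_mixture",
    "build_pair_input",
    "train_mix",
    "predict_pair",
    "predict_multicomponent",
    "save_mix",
    "load_mix",
    "PATH_STRATEGIES",
]

PATH_STRATEGIES = ("given", "sorted", "avg")


@dataclass(frozen=True)
class MixComponent:
    """One mixture component: group vector, molar concentration, pure spectrum.

    The pure spectrum is referenced to 1e-4 mol/l; group_vector may be None
    for pseudo-components created along a virtual mixing path.
    """

    concentration_mol_per_l: float
    pure_spectrum: Spectrum
    group_vector: np.ndarray | None = None

    @property
    def x_rel(self) -> float:
        return self.concentration_mol_per_l / REFERENCE_CONCENTRATION


@dataclass(frozen=True)
class MixtureRecord:
    components: tuple[MixComponent, ...]
    observed_mixture: Spectrum | None = None

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("a mixture record needs at least one component")
        g = self.components[0].pure_spectrum
        for c in self.components[1:]:
            if not c.pure_spectrum.same_grid(g):
                raise ValueError("all component spectra must share one grid")
        if self.observed_mixture is not None and not self.observed_mixture.same_grid(g):
            raise ValueError("observed mixture grid differs from component grid")


@dataclass
class MCModel:
    """Learned binary mixing model: 2x43 spectra in, 43-point mixture out."""

    net: brnet.BayesNetState
    seed: int
    n_train: int

    @property
    def n_inputs(self) -> int:
        return self.net.config.layer_sizes[0]


@dataclass(frozen=True)
class InteractionCoefficients:
    """Polynomial coefficients (c1, c2, ...) for k_ij in powers of d."""

    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coeffs) < 1:
            raise ValueError("polynomial degree must be >= 1")
        if not all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")


def default_bump_shape(grid=VIS_GRID, center: float = 560.0, sigma: float = 60.0) -> np.ndarray:
    """Unit-height Gaussian transformation vector X over the grid."""
    wl = grid.wavelengths
    return np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))


def interaction_factor(
    a_i: np.ndarray, a_j: np.ndarray, coeffs: InteractionCoefficients
) -> float:
    """k_ij = sum_p c_p * d^p with d the L1 norm of the group-vector difference.

    Symmetric in its arguments and exactly zero for identical components.
    """
    a_i = np.asarray(a_i, dtype=float)
    a_j = np.asarray(a_j, dtype=float)
    if a_i.shape != a_j.shape:
        raise ValueError(f"group-vector length mismatch: {a_i.shape} vs {a_j.shape}")
    d = float(np.abs(a_i - a_j).sum())
    return float(sum(c * d ** (p + 1) for p, c in enumerate(coeffs.coeffs)))


def analytic_mixture(
    components: list[MixComponent] | MixtureRecord,
    coeffs: InteractionCoefficients,
    bump_shape: np.ndarray | None = None,
) -> Spectrum:
    """Evaluate the analytic superposition for a mixture.

    With all coefficients zero this is exact Beer-Lambert additivity;
    identical components mix additively because k vanishes at zero
    group-vector difference.
    """
    if isinstance(components, MixtureRecord):
        components = list(components.components)
    if not components:
        raise ValueError("no components")
    xs = [c.x_rel for c in components]
    if all(x == 0 for x in xs):
        raise ValueError("all concentrations are zero")
    grid_ref = components[0].pure_spectrum
    X = bump_shape if bump_shape is not None else default_bump_shape()
    if X.size != grid_ref.n_points:
        raise ValueError("transformation vector length does not match the grid")
    total = np.zeros(grid_ref.n_points)
    for c, x in zip(components, xs):
        total += c.pure_spectrum.absorbance * x
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            xi, xj = xs[i], xs[j]
            if xi + xj == 0:
                continue
            ai, aj = components[i].group_vector, components[j].group_vector
            if ai is None or aj is None:
                raise ValueError("analytic mixing needs group vectors for all components")
            k = interaction_factor(ai, aj, coeffs)
            total += (xi * xj / (xi + xj)) * k * X
    return grid_ref.with_absorbance(total, normalized=False)


# ---------------------------------------------------------------------------
# learned mixing


def _scaled(c: MixComponent) -> np.ndarray:
    return c.pure_spectrum.absorbance * c.x_rel


def build_pair_input(r: MixtureRecord) -> np.ndarray:
    """Concatenate the two concentration-scaled pure spectra (86 entries).

    Components are put in canonical order - larger total absorbance first,
    ties broken lexicographically on the scaled spectrum - so the learned
    model is exactly symmetric under component exchange.
    """
    if len(r.components) != 2:
        raise ValueError(f"pair input needs exactly 2 components, got {len(r.components)}")
    s = [_scaled(c) for c in r.components]
    key0 = (float(s[0].sum()), tuple(s[0]))
    key1 = (float(s[1].sum()), tuple(s[1]))
    first, second = (0, 1) if key0 >= key1 else (1, 0)
    return np.concatenate([s[first], s[second]])


def train_mix(
    records: list[MixtureRecord],
    hidden: int = 12,
    max_epochs: int = 60,
    seed: int = 0,
    augment_self: bool = False,
) -> MCModel:
    """Fit the 86 -> 43 mixing network on binary records with observed mixtures.

    With ``augment_self`` the training set is extended with virtual
    self-mixtures: a component mixed with itself at x/2 + x/2 must give its
    own spectrum at x (the interaction vanishes at zero group-vector
    difference).  These records anchor the learned rule to the additive
    limit, which real pairs (always distinct dyes) never probe, at the cost
    of some capacity for interaction modelling; off by default.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 binary mixture records")
    X, Y = [], []
    for i, r in enumerate(records):
        if r.observed_mixture is None:
            raise ValueError("training records need observed mixtures")
        X.append(build_pair_input(r))
        Y.append(r.observed_mixture.absorbance)
        if augment_self:
            c = r.components[i % len(r.components)]
            half = MixComponent(c.concentration_mol_per_l / 2.0, c.pure_spectrum)
            X.append(build_pair_input(MixtureRecord((half, half))))
            Y.append(c.pure_spectrum.absorbance * c.x_rel)
    X = np.stack(X)
    Y = np.stack(Y)
    cfg = brnet.NetConfig(
        layer_sizes=(X.shape[1], hidden, Y.shape[1]), max_epochs=max_epochs, seed=seed
    )
    net = brnet.train(brnet.init_net(cfg), X, Y)
    return MCModel(net=net, seed=seed, n_train=len(records))


def predict_pair(m: MCModel, r: MixtureRecord) -> Spectrum:
    """Predict the mixed spectrum of a binary record."""
    x = build_pair_input(r)
    out = brnet.predict(m.net, x[None, :])[0]
    grid_ref = r.components[0].pure_spectrum
    return grid_ref.with_absorbance(np.clip(out, 0.0, None), normalized=False)


def _sequential_mix(m: MCModel, comps: list[MixComponent]) -> Spectrum:
    cur = comps[0]
    for nxt in comps[1:]:
        pair = MixtureRecord(components=(cur, nxt))
        mixed = predict_pair(m, pair)
        x_sum = cur.concentration_mol_per_l + nxt.concentration_mol_per_l
        # pseudo-component: predicted mixture rescaled back to the reference
        pseudo_pure = mixed.with_absorbance(
            mixed.absorbance / (x_sum / REFERENCE_CONCENTRATION)
        )
        cur = MixComponent(concentration_mol_per_l=x_sum, pure_spectrum=pseudo_pure)
    return cur.pure_spectrum.with_absorbance(_scaled(cur), normalized=False)


def save_mix(m: MCModel, outdir) -> None:
    from pathlib import Path
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    brnet.save_net(m.net, outdir / "mix_net.json")
    (outdir / "mcmodel.json").write_text(
        json.dumps({"schema": 1, "seed": m.seed, "n_train": m.n_train})
    )


def load_mix(outdir) -> MCModel:
    from pathlib import Path
    import json

    outdir = Path(outdir)
    meta = json.loads((outdir / "mcmodel.json").read_text())
    return MCModel(
        net=brnet.load_net(outdir / "mix_net.json"),
        seed=meta["seed"],
        n_train=meta["n_train"],
    )


def predict_multicomponent(
    m: MCModel, record: MixtureRecord, path: str = "given"
) -> Spectrum:
    """Migrate the binary model to a multicomponent mixture.

    Components are pairwise-mixed sequentially along a virtual mixing path:
    'given' keeps the record order, 'sorted' mixes in order of decreasing
    concentration, 'avg' averages the predictions over all component
    orderings.  For two components every strategy reduces to the direct
    pair prediction.
    """
    comps = list(record.components)
    if len(comps) < 2:
        raise ValueError("need at least 2 components")
    if path not in PATH_STRATEGIES:
        raise ValueError(f"unknown path strategy {path!r}; choose from {PATH_STRATEGIES}")
    if path == "given":
        return _sequential_mix(m, comps)
    if path == "sorted":
        order = sorted(
            range(len(comps)),
            key=lambda i: (-comps[i].concentration_mol_per_l, i),
        )
        return _sequential_mix(m, [comps[i] for i in order])
    # average over all orderings
    from itertools import permutations

    preds = [
        _sequential_mix(m, [comps[i] for i in perm]).absorbance
        for perm in permutations(range(len(comps)))
    ]
    grid_ref = comps[0].pure_spectrum
    return grid_ref.with_absorbance(np.mean(preds, axis=0), normalized=False)
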