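"""Synthetic-data generator with the statistical structure both stages assume.

The generator defines a small "world" of spectroscopic rules: each abstract
group g contributes a Gaussian absorption band (centre mu_g, width sigma_g,
height h_g per unit count); conjugation red-shifts all bands by delta nm per
unit of the largest-count descriptor B(a); a latent per-molecule electronic
factor and the solvent polarity add further small band shifts.  Mixtures
superpose component spectra with the pairwise interaction term of the
analytic mixing rule (coefficients c1, c2 on the L1 group-vector distance,
spread over the grid by a Gaussian bump D(lambda)), plus measurement noise.

Everything is deterministic from the world seed; with noise off, generated
quantities are exactly reproducible and binary mixtures with zero
coefficients are bit-identical to Beer-Lambert additivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ccspec.mcmix import (
    InteractionCoefficients,
    MixComponent,
    MixtureRecord,
    analytic_mixture,
    default_bump_shape,
)
from ccspec.molfeat import BLOCK_OFFSETS, DESCRIPTOR_LENGTH
from ccspec.spectra import GridSpec, Spectrum, VIS_GRID, normalize_minmax

__all__ = [
    "SynthWorld",
    "make_world",
    "sample_group_vectors",
    "spectrum_from_groups",
    "mix_synthetic",
    "make_stage1_corpus",
    "make_mixture_corpora",
]

#: Allowed component concentrations (mol/l), as in the dye experiments.
CONCENTRATION_LEVELS = (0.75e-4, 1.0e-4, 1.25e-4)


@dataclass(frozen=True)
class SynthWorld:
    """Band parameters and interaction rules of one synthetic world."""

    grid: GridSpec
    mu: np.ndarray  # band centres (nm), one per group
    sigma: np.ndarray  # band widths (nm)
    h: np.ndarray  # band heights per unit count
    delta_shift_nm: float  # red-shift per unit B(a)
    electronic_shift_nm: float  # shift per unit latent electronic factor
    polarity_shift_nm: float  # shift per unit (polarity - 0.5)
    c1: float
    c2: float
    bump_center_nm: float
    bump_sigma_nm: float
    noise_sigma: float
    seed: int

    @property
    def n_groups(self) -> int:
        return int(self.mu.size)

    @property
    def coeffs(self) -> InteractionCoefficients:
        return InteractionCoefficients((self.c1, self.c2))

    @property
    def bump(self) -> np.ndarray:
        return default_bump_shape(self.grid, self.bump_center_nm, self.bump_sigma_nm)


def make_world(
    seed: int = 0,
    grid: GridSpec = VIS_GRID,
    n_groups: int = 20,
    delta_shift_nm: float = 4.0,
    electronic_shift_nm: float = 2.0,
    polarity_shift_nm: float = 2.0,
    c1: float = 0.01,
    c2: float = 0.002,
    bump_center_nm: float = 560.0,
    bump_sigma_nm: float = 60.0,
    noise_sigma: float = 0.01,
) -> SynthWorld:
    """Sample band parameters for a world; all later draws derive from seed."""
    rng = np.random.default_rng(seed)
    lo, hi = grid.start_nm, float(grid.wavelengths[-1])
    span = hi - lo
    mu = rng.uniform(lo + 0.1 * span, hi - 0.1 * span, size=n_groups)
    sigma = rng.uniform(0.05 * span, 0.15 * span, size=n_groups)
    h = rng.uniform(0.08, 0.30, size=n_groups)
    return SynthWorld(
        grid=grid,
        mu=mu,
        sigma=sigma,
        h=h,
        delta_shift_nm=delta_shift_nm,
        electronic_shift_nm=electronic_shift_nm,
        polarity_shift_nm=polarity_shift_nm,
        c1=c1,
        c2=c2,
        bump_center_nm=bump_center_nm,
        bump_sigma_nm=bump_sigma_nm,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _conj_a(a: np.ndarray) -> float:
    """Stand-in for the total-conjugation descriptor: total group count."""
    return float(np.sum(a))


def _conj_b(a: np.ndarray) -> float:
    """Stand-in for the largest-conjugated-system descriptor: max count."""
    return float(np.max(a)) if a.size else 0.0


def sample_group_vectors(world: SynthWorld, n: int, seed: int | None = None) -> np.ndarray:
    """Sparse non-negative integer group vectors: 2-6 active slots, counts 1-8."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(world.seed + 1 if seed is None else seed)
    G = world.n_groups
    out = np.zeros((n, G), dtype=int)
    for i in range(n):
        k = rng.integers(2, 7)
        slots = rng.choice(G, size=min(k, G), replace=False)
        out[i, slots] = rng.integers(1, 9, size=slots.size)
    return out


def spectrum_from_groups(
    world: SynthWorld,
    a: np.ndarray,
    electronic: float = 0.0,
    polarity: float = 0.5,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Sum of group bands, red-shifted by conjugation/electronic/solvent terms.

    With ``rng`` given, i.i.d. Gaussian measurement noise of the world's
    noise_sigma is added.
    """
    a = np.asarray(a, dtype=float)
    if a.size != world.n_groups:
        raise ValueError(f"group vector length {a.size} != {world.n_groups}")
    wl = world.grid.wavelengths
    shift = (
        world.delta_shift_nm * _conj_b(a)
        + world.electronic_shift_nm * electronic
        + world.polarity_shift_nm * (polarity - 0.5)
    )
    L = np.zeros_like(wl)
    for g in range(world.n_groups):
        if a[g] == 0:
            continue
        L += a[g] * world.h[g] * np.exp(
            -((wl - world.mu[g] - shift) ** 2) / (2.0 * world.sigma[g] ** 2)
        )
    if rng is not None and world.noise_sigma > 0:
        L = L + rng.normal(0.0, world.noise_sigma, size=L.shape)
    return world.grid.spectrum(L)


def mix_synthetic(
    world: SynthWorld,
    components: list[MixComponent],
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Superpose components with the world's interaction rule, plus noise.

    The noise-free, zero-coefficient limit is bit-identical to the analytic
    Beer-Lambert sum.
    """
    s = analytic_mixture(components, world.coeffs, world.bump)
    if rng is not None and world.noise_sigma > 0:
        s = s.with_absorbance(
            s.absorbance + rng.normal(0.0, world.noise_sigma, size=s.n_points)
        )
    return s


# ---------------------------------------------------------------------------
# corpora

#: Electronic-block slots used by the synthetic descriptors: the latent
#: electronic factor, then nonlinear summaries of the group vector.
_N_SYNTH_ELECTRONIC = 5


def _descriptor_from_groups(a: np.ndarray, electronic: float, polarity: float) -> np.ndarray:
    """Pack [a | A, B | electronic sub-block, zeros | polarity] into 151 slots."""
    d = np.zeros(DESCRIPTOR_LENGTH)
    d[: a.size] = a
    lo_c, _ = BLOCK_OFFSETS["conjugation"]
    d[lo_c] = _conj_a(a)
    d[lo_c + 1] = _conj_b(a)
    lo_e, _ = BLOCK_OFFSETS["electronic"]
    d[lo_e : lo_e + _N_SYNTH_ELECTRONIC] = [
        electronic,
        float(np.sum(a)),
        float(np.sum(a**2)),
        float(np.max(a)),
        float(np.count_nonzero(a)),
    ]
    d[-1] = polarity
    return d


def make_stage1_corpus(
    world: SynthWorld, n: int, seed: int | None = None
) -> list[tuple[np.ndarray, Spectrum]]:
    """(descriptor, normalized spectrum) pairs for the single-molecule stage.

    The world should live on the UV grid for stage-1 use; spectra are
    min-max normalized as the UV training protocol requires.
    """
    rng = np.random.default_rng((world.seed + 10) if seed is None else seed)
    A = sample_group_vectors(world, n, seed=int(rng.integers(2**31)))
    records = []
    for i in range(n):
        e = float(rng.normal())
        p = float(rng.uniform())
        s = spectrum_from_groups(world, A[i], electronic=e, polarity=p, rng=rng)
        records.append((_descriptor_from_groups(A[i], e, p), normalize_minmax(s)))
    return records


def _component(world, a, conc, rng) -> MixComponent:
    pure = spectrum_from_groups(world, a, rng=rng)
    return MixComponent(
        concentration_mol_per_l=conc, pure_spectrum=pure, group_vector=np.asarray(a, float)
    )


def make_mixture_corpora(
    world: SynthWorld,
    n_binary: int,
    n_ternary: int = 0,
    n_dyes: int = 36,
    seed: int | None = None,
) -> tuple[list[MixtureRecord], list[MixtureRecord]]:
    """Binary training records and multicomponent test records.

    A library of n_dyes group vectors is drawn once; each record picks
    distinct dyes and concentrations from the experimental levels, observes
    each pure spectrum with noise, and the mixture through the world's
    interaction rule with noise.  Ternary records never repeat a binary
    record's dye pair.
    """
    rng = np.random.default_rng((world.seed + 20) if seed is None else seed)
    lib = sample_group_vectors(world, n_dyes, seed=int(rng.integers(2**31)))
    binary: list[MixtureRecord] = []
    used_pairs: set[tuple[int, int]] = set()
    for _ in range(n_binary):
        i, j = map(int, rng.choice(n_dyes, size=2, replace=False))
        used_pairs.add((min(i, j), max(i, j)))
        comps = [
            _component(world, lib[i], float(rng.choice(CONCENTRATION_LEVELS)), rng),
            _component(world, lib[j], float(rng.choice(CONCENTRATION_LEVELS)), rng),
        ]
        obs = mix_synthetic(world, comps, rng=rng)
        binary.append(MixtureRecord(components=tuple(comps), observed_mixture=obs))
    multi: list[MixtureRecord] = []
    for _ in range(n_ternary):
        for _try in range(200):
            ids = sorted(map(int, rng.choice(n_dyes, size=3, replace=False)))
            pairs = {(ids[0], ids[1]), (ids[0], ids[2]), (ids[1], ids[2])}
            if not (pairs & used_pairs):
                break  # else: keep the last draw when the pair space is exhausted
        comps = [
            _component(world, lib[i], float(rng.choice(CONCENTRATION_LEVELS)), rng)
            for i in ids
        ]
        obs = mix_synthetic(world, comps, rng=rng)
        multi.append(MixtureRecord(components=tuple(comps), observed_mixture=obs))
    return binary, multi
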