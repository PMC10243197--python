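"""Mixture stage: interaction factor, analytic rule, learned mixing, paths."""

import numpy as np
import pytest

from ccspec.mcmix import (
    InteractionCoefficients,
    MixComponent,
    MixtureRecord,
    analytic_mixture,
    build_pair_input,
    interaction_factor,
    load_mix,
    predict_multicomponent,
    predict_pair,
    save_mix,
    train_mix,
)
from ccspec.spectra import Spectrum, VIS_GRID
from ccspec.synth import make_mixture_corpora, make_world


def comp(absorbance, conc=1.0e-4, gv=None):
    return MixComponent(conc, Spectrum(360.0, 10.0, np.asarray(absorbance, float)),
                        None if gv is None else np.asarray(gv, float))


class TestInteractionFactor:
    def test_vanishes_for_identical_vectors(self):
        c = InteractionCoefficients((0.3, 0.1, 0.05))
        a = np.array([1.0, 4.0, 0.0])
        assert interaction_factor(a, a, c) == 0.0

    def test_linear_term(self):
        c = InteractionCoefficients((1.0, 0.0))
        assert interaction_factor(np.array([3.0, 0.0]), np.array([0.0, 0.0]), c) == 3.0

    def test_symmetry(self, rng):
        c = InteractionCoefficients((0.01, 0.002))
        a, b = rng.integers(0, 8, 20).astype(float), rng.integers(0, 8, 20).astype(float)
        assert interaction_factor(a, b, c) == interaction_factor(b, a, c)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            interaction_factor(np.zeros(3), np.zeros(4), InteractionCoefficients((1.0,)))


class TestAnalyticMixture:
    def test_zero_coefficients_is_beer_lambert(self, rng):
        a = rng.uniform(0, 2, 43)
        b = rng.uniform(0, 2, 43)
        comps = [comp(a, 1.0e-4, np.ones(5)), comp(b, 1.25e-4, np.zeros(5))]
        out = analytic_mixture(comps, InteractionCoefficients((0.0, 0.0)))
        np.testing.assert_allclose(out.absorbance, a * 1.0 + b * 1.25, atol=1e-12)

    def test_single_component_identity(self, rng):
        a = rng.uniform(0, 2, 43)
        out = analytic_mixture([comp(a, 1.0e-4, np.ones(4))],
                               InteractionCoefficients((0.5,)))
        np.testing.assert_allclose(out.absorbance, a, atol=1e-15)

    def test_identical_components_additive(self, rng):
        a = rng.uniform(0, 2, 43)
        gv = np.array([2.0, 5.0])
        comps = [comp(a, 1.0e-4, gv), comp(a, 1.0e-4, gv)]
        out = analytic_mixture(comps, InteractionCoefficients((0.7, 0.3)))
        np.testing.assert_allclose(out.absorbance, 2 * a, atol=1e-12)

    def test_all_zero_concentrations_rejected(self, rng):
        comps = [comp(np.ones(43), 0.0, np.ones(3))]
        with pytest.raises(ValueError, match="zero"):
            analytic_mixture(comps, InteractionCoefficients((1.0,)))


class TestPairInput:
    def test_length_86(self, rng):
        r = MixtureRecord((comp(rng.uniform(0, 1, 43)), comp(rng.uniform(0, 1, 43))))
        assert build_pair_input(r).shape == (86,)

    def test_reference_concentration_scale_is_one(self):
        a = np.linspace(1, 2, 43)
        r = MixtureRecord((comp(a, 1.0e-4), comp(np.zeros(43), 1.0e-4)))
        np.testing.assert_array_equal(build_pair_input(r)[:43], a)

    def test_zero_spectra_give_zero_vector(self):
        r = MixtureRecord((comp(np.zeros(43)), comp(np.zeros(43))))
        np.testing.assert_array_equal(build_pair_input(r), np.zeros(86))

    def test_canonical_order_symmetric(self, rng):
        a, b = rng.uniform(0, 1, 43), rng.uniform(0, 1, 43)
        r1 = MixtureRecord((comp(a, 0.75e-4), comp(b, 1.25e-4)))
        r2 = MixtureRecord((comp(b, 1.25e-4), comp(a, 0.75e-4)))
        np.testing.assert_array_equal(build_pair_input(r1), build_pair_input(r2))

    def test_grid_mismatch_rejected(self, rng):
        c1 = comp(rng.uniform(0, 1, 43))
        c2 = MixComponent(1e-4, Spectrum(230.0, 3.0, rng.uniform(0, 1, 58)))
        with pytest.raises(ValueError, match="grid"):
            MixtureRecord((c1, c2))


@pytest.fixture(scope="module")
def trained():
    world = make_world(seed=31)
    binary, multi = make_mixture_corpora(world, 60, 6)
    model = train_mix(binary, hidden=8, max_epochs=25, seed=1)
    return world, binary, multi, model


class TestLearnedMixing:
    def test_too_few_records(self, trained):
        _, binary, _, _ = trained
        with pytest.raises(ValueError, match="at least 2"):
            train_mix(binary[:1])

    def test_duplicate_records_converge(self, trained):
        _, binary, _, _ = trained
        train_mix([binary[0]] * 6, hidden=4, max_epochs=4, seed=0)

    def test_additive_world_predicts_linear_sum(self):
        w = make_world(seed=8, c1=0.0, c2=0.0, noise_sigma=0.0)
        binary, _ = make_mixture_corpora(w, 80, 0)
        m = train_mix(binary[:70], hidden=8, max_epochs=40, seed=2)
        errs = []
        for r in binary[70:]:
            lin = sum(c.pure_spectrum.absorbance * c.x_rel for c in r.components)
            pred = predict_pair(m, r).absorbance
            errs.append(np.mean(np.abs(pred - lin)))
        assert np.mean(errs) < 0.15

    def test_exchange_symmetry_exact(self, trained):
        _, binary, _, model = trained
        r = binary[0]
        swapped = MixtureRecord(components=r.components[::-1])
        np.testing.assert_array_equal(
            predict_pair(model, r).absorbance, predict_pair(model, swapped).absorbance
        )

    def test_output_grid(self, trained):
        _, binary, _, model = trained
        out = predict_pair(model, binary[0])
        assert out.n_points == VIS_GRID.n


class TestMulticomponent:
    def test_two_components_equal_direct_pair(self, trained):
        _, binary, _, model = trained
        r = binary[0]
        direct = predict_pair(model, r).absorbance
        for path in ("given", "sorted", "avg"):
            np.testing.assert_allclose(
                predict_multicomponent(model, r, path).absorbance, direct, atol=1e-12
            )

    def test_four_components_output_length(self, trained):
        _, binary, multi, model = trained
        comps = multi[0].components + (binary[0].components[0],)
        r = MixtureRecord(components=comps)
        assert predict_multicomponent(model, r, "given").n_points == 43

    def test_unknown_strategy_rejected(self, trained):
        _, _, multi, model = trained
        with pytest.raises(ValueError, match="unknown path"):
            predict_multicomponent(model, multi[0], "zigzag")

    def test_self_mixing_consistency(self, trained):
        """Mixing a dye with itself at x/2 + x/2 recovers the pure spectrum."""
        world, binary, _, _ = trained
        model = train_mix(binary[:-6], hidden=8, max_epochs=25, seed=1)
        held = binary[-6:]
        T = np.stack([r.observed_mixture.absorbance for r in held])
        P = np.stack([predict_pair(model, r).absorbance for r in held])
        heldout_mae = float(np.mean(np.abs(P - T)))
        c = binary[0].components[0]
        half = MixComponent(0.5e-4, c.pure_spectrum, c.group_vector)
        out = predict_pair(model, MixtureRecord((half, half))).absorbance
        target = c.pure_spectrum.absorbance  # 2 * x/2 at reference
        assert np.mean(np.abs(out - target)) <= 2 * heldout_mae + 2 * world.noise_sigma


class TestSerialization:
    def test_round_trip(self, trained, tmp_path):
        _, binary, _, model = trained
        save_mix(model, tmp_path / "mc")
        loaded = load_mix(tmp_path / "mc")
        np.testing.assert_array_equal(
            predict_pair(model, binary[0]).absorbance,
            predict_pair(loaded, binary[0]).absorbance,
        )
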