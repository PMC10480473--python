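"""Monte Carlo photon transport: kernels, bookkeeping, statistical limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from skintherm import (
    McSettings,
    build_stack,
    fresnel_reflectance,
    make_grid,
    mc_centerline_profile,
    run_mc,
    sample_henyey_greenstein,
)
from skintherm.domain import SourceSpec

from conftest import homogeneous_stack


def mc_setup(mu_a_per_cm=10.0, mu_s_prime_per_cm=0.0, g=0.0, n=1.0,
             thickness_mm=5.0, dz=1e-4, dr=2e-3, waist=5e-3, power=0.1):
    """Narrow beam + wide rings: good innermost-ring statistics."""
    stack = homogeneous_stack(mu_a_per_cm=mu_a_per_cm,
                              mu_s_prime_per_cm=mu_s_prime_per_cm,
                              g=g, n=n, thickness_mm=thickness_mm)
    grid = make_grid(stack, dr=dr, dz=dz, r_max=15e-3)
    source = SourceSpec(power=power, waist=waist)
    return stack, grid, source


class TestHenyeyGreenstein:
    def test_isotropic_limit_closed_form(self):
        assert sample_henyey_greenstein(0.0, 0.75) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(g=hst.floats(0.0, 0.99), u=hst.floats(0.0, 1.0, exclude_max=True))
    def test_range(self, g, u):
        assert -1.0 <= sample_henyey_greenstein(g, u) <= 1.0

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(12345)
        u = rng.random(1_000_000)
        cs = np.array([sample_henyey_greenstein(g, ui) for ui in u])
        # var of HG cosine <= 1; 3 sigma of the sample mean
        assert abs(cs.mean() - g) < 3.0 / math.sqrt(len(u))

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            sample_henyey_greenstein(1.0, 0.5)


class TestFresnel:
    def test_matched_media(self):
        assert fresnel_reflectance(1.4, 1.4, 0.5) == 0.0

    def test_normal_incidence_closed_form(self):
        expect = ((1.0 - 1.4) / (1.0 + 1.4)) ** 2
        assert fresnel_reflectance(1.0, 1.4, 1.0) == pytest.approx(expect)

    def test_total_internal_reflection(self):
        cos_crit = math.sqrt(1.0 - (1.0 / 1.4) ** 2)
        assert fresnel_reflectance(1.4, 1.0, 0.5 * cos_crit) == 1.0

    def test_grazing_incidence_is_mirror(self):
        assert fresnel_reflectance(1.0, 1.4, 0.0) == pytest.approx(1.0)


class TestEnergyBookkeeping:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(),
            dict(mu_s_prime_per_cm=5.0, g=0.9),
            dict(mu_s_prime_per_cm=15.0, g=0.0, mu_a_per_cm=1.0),
            dict(n=1.4),
        ],
    )
    def test_weight_identity_exact(self, kw):
        """spec + diffuse + transmitted + absorbed = 1 + roulette_net,
        exactly, for any parameters; the roulette term itself is tiny."""
        stack, grid, source = mc_setup(**kw)
        t = run_mc(stack, source, grid, McSettings(n_photons=20_000, seed=11))
        total = (t.specular_reflected + t.diffuse_reflected + t.transmitted
                 + t.absorbed_total)
        assert total == pytest.approx(1.0 + t.roulette_net, abs=1e-9)
        assert abs(t.roulette_net) < 5e-3

    def test_specular_fraction_at_mismatched_surface(self):
        stack, grid, source = mc_setup(n=1.4)
        t = run_mc(stack, source, grid, McSettings(n_photons=10_000, seed=2))
        assert t.specular_reflected == pytest.approx(
            ((1 - 1.4) / (1 + 1.4)) ** 2, rel=1e-9
        )

    def test_reproducible_for_fixed_seed(self):
        stack, grid, source = mc_setup()
        a = run_mc(stack, source, grid, McSettings(n_photons=5_000, seed=99))
        b = run_mc(stack, source, grid, McSettings(n_photons=5_000, seed=99))
        assert np.array_equal(a.absorbed, b.absorbed)
        assert a.weight_fractions() == b.weight_fractions()

    def test_independent_seeds_agree_within_stderr(self):
        stack, grid, source = mc_setup(mu_s_prime_per_cm=5.0, g=0.5)
        a = run_mc(stack, source, grid, McSettings(n_photons=40_000, seed=1))
        b = run_mc(stack, source, grid, McSettings(n_photons=40_000, seed=2))
        fa, fb = a.layer_fractions(), b.layer_fractions()
        se = np.sqrt(a.layer_fraction_stderr() ** 2
                     + b.layer_fraction_stderr() ** 2)
        assert np.all(np.abs(fa - fb) <= 4.0 * np.maximum(se, 1e-12))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            McSettings(n_photons=0)
        with pytest.raises(ValueError):
            McSettings(roulette_survival=1.5)


class TestAgainstBeerLambert:
    def test_absorption_only_centerline_within_3_sigma(self):
        """No scattering, matched index: fluence is exactly exp(-mu_a z).

        Preregistered depths (1 and 2 mean free paths) are held to 3 sigma;
        across all populated cells a chi-square aggregate and a
        Bonferroni-corrected per-cell bound guard against both bias and
        isolated fluctuations.
        """
        stack, grid, source = mc_setup(mu_a_per_cm=10.0, dz=2e-4)
        t = run_mc(stack, source, grid, McSettings(n_photons=300_000, seed=5))
        prof = mc_centerline_profile(t)
        mu_a = 1000.0
        expect = np.exp(-mu_a * (prof.z - prof.z[0]))
        zscore = np.abs(prof.value - expect) / np.maximum(prof.stderr, 1e-12)
        for depth in (1.0 / mu_a, 2.0 / mu_a):
            i = int(np.argmin(np.abs(prof.z - depth)))
            assert zscore[i] <= 3.0
        mask = expect > 1e-3  # skip the statistically empty tail
        assert np.mean(zscore[mask] ** 2) < 2.0
        assert np.max(zscore[mask]) < 4.0  # ~3 sigma after multiplicity

    def test_log_slope_regression_recovers_mu_a(self):
        stack, grid, source = mc_setup(mu_a_per_cm=10.0, dz=2e-4)
        t = run_mc(stack, source, grid, McSettings(n_photons=300_000, seed=8))
        prof = mc_centerline_profile(t)
        mask = prof.value > 1e-2
        slope = np.polyfit(prof.z[mask], np.log(prof.value[mask]), 1)[0]
        assert slope == pytest.approx(-1000.0, rel=0.03)

    def test_absorbed_fractions_match_layered_closed_form(self, thz130):
        grid = make_grid(thz130.stack, dr=2e-3, dz=5e-5, r_max=60e-3)
        t = run_mc(thz130.stack, thz130.source, grid,
                   McSettings(n_photons=100_000, seed=3, match_indices=True))
        from skintherm import bl_layer_fractions

        expect = bl_layer_fractions(thz130.stack)
        got = t.layer_fractions()
        se = t.layer_fraction_stderr()
        for i, la in enumerate(thz130.stack.layers):
            assert abs(got[i] - expect[la.name]) <= 4.0 * max(se[i], 1e-4)


class TestSimilarityRelation:
    def test_g0_and_g09_agree_at_equal_reduced_scattering(self):
        """Layer absorbed fractions depend mainly on mu_s', not on (mu_s, g)
        separately.  The similarity relation is approximate: the diffuse
        reflectance of a matched-boundary slab retains a ~5-8% g-dependence
        (isotropic scattering backscatters more in the first events), so the
        coarse observables are required to agree at the 10% level, far closer
        than the 10x difference in the underlying mu_s."""
        a_stack, grid, source = mc_setup(mu_a_per_cm=2.0, mu_s_prime_per_cm=10.0,
                                         g=0.0)
        b_stack, _, _ = mc_setup(mu_a_per_cm=2.0, mu_s_prime_per_cm=10.0, g=0.9)
        a = run_mc(a_stack, source, grid, McSettings(n_photons=60_000, seed=21))
        b = run_mc(b_stack, source, grid, McSettings(n_photons=60_000, seed=22))
        fa, fb = a.layer_fractions()[0], b.layer_fractions()[0]
        assert abs(fa - fb) <= 0.10 * fa
        # and the isotropic slab must indeed reflect more
        assert a.diffuse_reflected > b.diffuse_reflected


def test_centerline_error_on_transparent_surface_layer():
    stack = build_stack(
        [
            dict(name="clear", thickness_mm=1.0, mu_a_per_cm=0.0,
                 mu_s_prime_per_cm=5.0),
            dict(name="dark", thickness_mm=1.0, mu_a_per_cm=10.0),
        ]
    )
    grid = make_grid(stack, dr=2e-3, dz=1e-4, r_max=15e-3)
    t = run_mc(stack, SourceSpec(power=0.1, waist=5e-3), grid,
               McSettings(n_photons=2_000, seed=1))
    with pytest.raises(ValueError):
        mc_centerline_profile(t)
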