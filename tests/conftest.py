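import numpy as np
import pytest

from skintherm import build_stack, make_grid, scenario


@pytest.fixture(scope="session")
def thz130():
    return scenario("thz_130ghz")


@pytest.fixture(scope="session")
def thz1t():
    return scenario("thz_1thz")


@pytest.fixture(scope="session")
def nir():
    return scenario("nir_1030nm")


@pytest.fixture(scope="session")
def thz130_field(thz130):
    """Solved diffusion field on the 130 GHz fixture grid (reused widely)."""
    from skintherm import solve_fluence

    grid = thz130.make_grid()
    return grid, solve_fluence(thz130.stack, thz130.source, grid, thz130.diffusion)


def homogeneous_stack(mu_a_per_cm=10.0, mu_s_prime_per_cm=0.0, g=0.0, n=1.4,
                      thickness_mm=5.0, perfused=True):
    return build_stack(
        [
            dict(
                name="slab",
                thickness_mm=thickness_mm,
                mu_a_per_cm=mu_a_per_cm,
                mu_s_prime_per_cm=mu_s_prime_per_cm,
                g=g,
                n=n,
                perfused=perfused,
            )
        ]
    )


@pytest.fixture
def slab():
    return homogeneous_stack()


def small_thermal_problem():
    """A fast-equilibrating thermal toy: thin slab, strong convection."""
    stack = homogeneous_stack(mu_a_per_cm=20.0, thickness_mm=1.0)
    grid = make_grid(stack, dr=2e-3, dz=1e-4, r_max=16e-3)
    from skintherm import SourceSpec, solve_fluence

    source = SourceSpec(power=0.05, waist=5e-3)
    q = solve_fluence(stack, source, grid).q_abs
    return stack, grid, q
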