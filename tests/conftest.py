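import numpy as np
import pytest

import lamdiff as ld


@pytest.fixture(scope="session")
def instrument():
    return ld.InstrumentConfig(seed=7)


@pytest.fixture(scope="session")
def gel_profile(instrument):
    model = ld.BilayerEDPModel.gel_default()
    stack = ld.LamellarStackModel.gel_default()
    return ld.synthesize_profile([(model, stack)], instrument, seed=7)


@pytest.fixture(scope="session")
def fluid_profile(instrument):
    model = ld.BilayerEDPModel.fluid_default()
    stack = ld.LamellarStackModel.fluid_default()
    return ld.synthesize_profile([(model, stack)], instrument, seed=8)


@pytest.fixture(scope="session")
def coexistence_profile(instrument):
    pops = [
        (ld.BilayerEDPModel.gel_default(), ld.LamellarStackModel.gel_default(phi=0.5)),
        (
            ld.BilayerEDPModel.fluid_default(),
            ld.LamellarStackModel.fluid_default(phi=0.5),
        ),
    ]
    meta = ld.SampleMeta(dha_molpercent=0.1, temperature=25.0, label="coex")
    return ld.synthesize_profile(pops, instrument, meta=meta, seed=9)


def random_gel_model(rng):
    """One realistic-jitter gel bilayer model (shared test helper)."""
    d = rng.uniform(4.85, 5.15)
    zh = rng.uniform(0.325, 0.345) * d
    sh = rng.uniform(0.115, 0.125)
    return ld.BilayerEDPModel(
        (
            ld.GaussianComponent(zh, sh, 1.0, 1),
            ld.GaussianComponent(-zh, sh, 1.0, 1),
            ld.GaussianComponent(
                0.0, rng.uniform(0.123, 0.130), rng.uniform(1.35, 1.45), -1
            ),
        ),
        d=d,
    )


def quadrature_form_factor(model, q):
    """Independent numerical-integration oracle for the bilayer form factor.

    F(q) = integral rho(z) cos(q z) dz on a fine real-space grid (Angstrom).
    """
    zmax = max(abs(c.center) + 8 * c.sigma for c in model.components) * 10.0
    z = np.linspace(-zmax, zmax, 40001)
    rho = model.density(z / 10.0)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return np.array([np.trapezoid(rho * np.cos(qi * z), z) for qi in q])
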