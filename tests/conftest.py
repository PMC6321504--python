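import numpy as np
import pytest

from fiberpol.photophysics import (
    AEDANS_S1,
    IntensityQuadruple,
    OrientationState,
    model_quadruple,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20181210)


@pytest.fixture(scope="session")
def atp_state_quadruple():
    """Noise-free quadruple of the weak-binding (MgATP) myosin-head state."""
    state = OrientationState(phi_e=51.2, n_disordered=0.576, theta_half=25.0)
    return state, model_quadruple(state, AEDANS_S1)


def mc_cone_dipoles(w, phi_deg, rng):
    """Sample dipoles uniformly on cones of half-angle phi about axes w."""
    ref = np.where(np.abs(w[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    u = np.cross(w, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(w, u)
    psi = rng.uniform(0.0, 2.0 * np.pi, len(w))
    p = np.radians(phi_deg)
    return (
        np.sin(p) * (np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v)
        + np.cos(p) * w
    )


def mc_quadruple_ordered(phi_a, phi_e, theta_half, n_draws, rng):
    """Monte-Carlo oracle for the ordered-branch photoselection average.

    Samples the same orientation distribution as the quadrature: filament
    polar deviation uniform on [0, theta_half], azimuth uniform, dipole
    azimuths uniform and independent on their cones.  Returns (components,
    standard errors of each mean).
    """
    if theta_half > 0:
        th = np.radians(rng.uniform(0.0, theta_half, n_draws))
    else:
        th = np.zeros(n_draws)
    beta = rng.uniform(0.0, 2.0 * np.pi, n_draws)
    w = np.stack(
        [np.sin(th) * np.cos(beta), np.sin(th) * np.sin(beta), np.cos(th)], axis=1
    )
    a = mc_cone_dipoles(w, phi_a, rng)
    e = mc_cone_dipoles(w, phi_e, rng)
    samples = np.stack(
        [
            a[:, 2] ** 2 * e[:, 2] ** 2,
            a[:, 2] ** 2 * e[:, 0] ** 2,
            a[:, 0] ** 2 * e[:, 0] ** 2,
            a[:, 0] ** 2 * e[:, 2] ** 2,
        ],
        axis=1,
    )
    return samples.mean(axis=0), samples.std(axis=0, ddof=1) / np.sqrt(n_draws)


def mc_quadruple_isotropic(gamma_deg, n_draws, rng, chunk=2_000_000):
    """Monte-Carlo oracle for a rigid random dipole pair at fixed angle gamma.

    Draws are processed in chunks to bound memory; returns (means, standard
    errors of the means).
    """
    g = np.radians(gamma_deg)
    total = 0
    s1 = np.zeros(4)
    s2 = np.zeros(4)
    while total < n_draws:
        n = min(chunk, n_draws - total)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = rng.normal(size=(n, 3))
        v -= (v * u).sum(axis=1, keepdims=True) * u
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        e = np.cos(g) * u + np.sin(g) * v
        samples = np.stack(
            [
                u[:, 2] ** 2 * e[:, 2] ** 2,
                u[:, 2] ** 2 * e[:, 0] ** 2,
                u[:, 0] ** 2 * e[:, 0] ** 2,
                u[:, 0] ** 2 * e[:, 2] ** 2,
            ],
            axis=1,
        )
        s1 += samples.sum(axis=0)
        s2 += (samples**2).sum(axis=0)
        total += n
    mean = s1 / total
    var = (s2 - total * mean**2) / (total - 1)
    return mean, np.sqrt(var / total)
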