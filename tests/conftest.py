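"""Shared fixtures and the Euler-Maruyama path-simulation oracle.

The path simulator integrates the stochastic differential equation
directly (per-trial drift/start/non-decision draws included) and is the
model-independent reference for the analytic density and CDF engines.
"""

import numpy as np
import pytest

from fastdm import ParameterSet, rescale_parameters


def em_first_passage(params: ParameterSet, n: int, dt: float, rng,
                     t_cap: float = 30.0):
    """Simulate first passages by Euler-Maruyama integration.

    Returns (responses, rts).  Trials still unabsorbed at ``t_cap`` are
    dropped (their probability is negligible for the parameter ranges
    used in tests).
    """
    p = rescale_parameters(params, 1.0)
    v = rng.normal(p.v, p.sv, n) if p.sv > 0 else np.full(n, p.v)
    zr = rng.uniform(p.zr - 0.5 * p.szr, p.zr + 0.5 * p.szr, n) \
        if p.szr > 0 else np.full(n, p.zr)
    t0 = rng.uniform(p.t0 - 0.5 * p.st0, p.t0 + 0.5 * p.st0, n) \
        if p.st0 > 0 else np.full(n, p.t0)

    x = zr * p.a
    t_dec = np.zeros(n)
    resp = np.full(n, -1)
    active = np.ones(n, bool)
    sq = np.sqrt(dt)
    n_steps = int(t_cap / dt)
    for _ in range(n_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        x[idx] += v[idx] * dt + sq * rng.standard_normal(idx.size)
        t_dec[idx] += dt
        hit_up = idx[x[idx] >= p.a]
        hit_lo = idx[x[idx] <= 0.0]
        resp[hit_up] = 1
        resp[hit_lo] = 0
        active[hit_up] = False
        active[hit_lo] = False
    done = resp >= 0
    rts = t_dec + t0 + np.where(resp == 1, -0.5 * p.d, 0.5 * p.d)
    return resp[done], rts[done]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def em_sampler():
    return em_first_passage
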