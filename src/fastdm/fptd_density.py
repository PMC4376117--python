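"""First-passage-time densities of the diffusion model.

The density of upper-threshold first passages of the basic model (no
inter-trial variability) has two classical series representations: a
"small-time" sum over mirror images of the starting point and a
"large-time" eigenfunction expansion.  The two series converge at
opposite ends of the time axis; for every evaluation point this module
bounds the number of terms each representation needs for a given
truncation error and evaluates the cheaper one.

The full model adds three inter-trial variabilities.  The normal drift
mixture integrates in closed form (the drift enters the density only
through the factor ``exp[(a-z) v - v^2 t / 2]``, which makes the mixture
a Gaussian integral).  The uniform starting-point and non-decision-time
mixtures are averaged numerically with the midpoint rule.
"""

from __future__ import annotations

import numpy as np

from .model_core import ParameterSet, PrecisionSettings, rescale_parameters

__all__ = [
    "density_small_time",
    "density_large_time",
    "choose_representation",
    "density_basic",
    "density_sv",
    "density_full",
]

_EPS_DEFAULT = 1e-6
_MAX_TERMS = 256


# ----------------------------------------------------------------------
# term-count bounds (Navarro & Fuss style) on the scaled time axis t/a^2

def _small_time_bound(ts: np.ndarray, eps: float) -> np.ndarray:
    """Terms needed by the small-time series for truncation error <= eps."""
    ts = np.asarray(ts, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        branch = 2.0 * np.sqrt(2.0 * np.pi * ts) * eps < 1.0
        val = 2.0 + np.sqrt(-2.0 * ts * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * ts)))
        val = np.maximum(val, np.sqrt(ts) + 1.0)
    return np.where(branch, val, 2.0)


def _large_time_bound(ts: np.ndarray, eps: float) -> np.ndarray:
    """Terms needed by the large-time series for truncation error <= eps."""
    ts = np.asarray(ts, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        branch = np.pi * ts * eps < 1.0
        val = np.sqrt(-2.0 * np.log(np.pi * ts * eps) / (np.pi**2 * ts))
        val = np.maximum(val, 1.0 / (np.pi * np.sqrt(ts)))
    return np.where(branch, val, 1.0 / (np.pi * np.sqrt(ts)))


def choose_representation(t_scaled: float, eps: float = _EPS_DEFAULT):
    """Pick the series representation that needs fewer terms.

    Parameters
    ----------
    t_scaled : float
        Decision time divided by ``a**2`` (dimensionless).
    eps : float
        Truncation error bound.

    Returns
    -------
    (str, int)
        ``("small", K)`` meaning the sum over ``n = -K..K`` of the
        small-time series, or ``("large", K)`` meaning ``n = 1..K`` of the
        large-time series.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    ks = float(_small_time_bound(np.asarray(t_scaled), eps))
    kl = float(_large_time_bound(np.asarray(t_scaled), eps))
    if ks <= kl:
        return "small", max(1, int(np.ceil((ks - 1.0) / 2.0)))
    return "large", max(1, int(np.ceil(kl)))


# ----------------------------------------------------------------------
# explicit partial sums (exposed for testing; the fast path is below)

def density_small_time(t, z, a, v, n_terms):
    """Partial sum of the small-time representation over ``n = -K..K``.

    ``z`` is the absolute starting point ``zr * a``; result is the density
    of upper-threshold passages at decision time ``t`` (s = 1 scale).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    if pos.any():
        tt = t[pos]
        n = np.arange(-n_terms, n_terms + 1)
        c = (1.0 + 2.0 * n)[:, None] * a - z
        with np.errstate(under="ignore"):
            series = np.sum(c * np.exp(-c * c / (2.0 * tt[None, :])), axis=0)
            pre = np.exp((a - z) * v - 0.5 * v * v * tt) / np.sqrt(2.0 * np.pi * tt**3)
        out[pos] = pre * series
    return float(out[0]) if scalar else out


def density_large_time(t, z, a, v, n_terms):
    """Partial sum of the large-time representation over ``n = 1..K``."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    if pos.any():
        tt = t[pos]
        n = np.arange(1, n_terms + 1, dtype=float)
        with np.errstate(under="ignore"):
            decay = np.exp(-0.5 * (np.pi**2 * n[:, None] ** 2 / a**2) * tt[None, :])
            series = np.sum(n[:, None] * np.sin(np.pi * (a - z) * n[:, None] / a) * decay, axis=0)
            pre = (np.pi / a**2) * np.exp((a - z) * v - 0.5 * v * v * tt)
        out[pos] = pre * series
    return float(out[0]) if scalar else out


# ----------------------------------------------------------------------
# vectorized engine

def _g_upper(t, z, a: float, v: float, eps: float) -> np.ndarray:
    """Vectorized basic-model density at the upper threshold (s = 1).

    ``t`` and ``z`` broadcast against each other; representation and term
    count are chosen element-wise.  Evaluation combines the drift
    prefactor and the series in log space so extreme drifts neither
    overflow nor produce spurious zeros.
    """
    t, z = np.broadcast_arrays(np.asarray(t, float), np.asarray(z, float))
    out = np.zeros(t.shape, float)
    pos = t > 0
    if not pos.any():
        return out
    tt = t[pos].ravel()
    zz = z[pos].ravel()
    ts = tt / (a * a)
    ks = _small_time_bound(ts, eps)
    kl = _large_time_bound(ts, eps)
    small = ks <= kl
    vals = np.zeros(tt.shape, float)
    lnpre = (a - zz) * v - 0.5 * v * v * tt

    if small.any():
        tsub = tt[small]
        zsub = zz[small]
        K = min(_MAX_TERMS, max(1, int(np.ceil((ks[small].max() - 1.0) / 2.0))))
        n = np.arange(-K, K + 1)
        c = (1.0 + 2.0 * n)[:, None] * a - zsub[None, :]
        with np.errstate(under="ignore"):
            series = np.sum(c * np.exp(-c * c / (2.0 * tsub[None, :])), axis=0)
        contrib = series / np.sqrt(2.0 * np.pi * tsub**3)
        good = contrib > 0
        res = np.zeros(tsub.shape)
        with np.errstate(under="ignore"):
            res[good] = np.exp(lnpre[small][good] + np.log(contrib[good]))
        vals[small] = res

    large = ~small
    if large.any():
        tsub = tt[large]
        zsub = zz[large]
        K = min(_MAX_TERMS, max(1, int(np.ceil(kl[large].max()))))
        n = np.arange(1, K + 1, dtype=float)
        with np.errstate(under="ignore"):
            decay = np.exp(-0.5 * (np.pi**2 / a**2) * n[:, None] ** 2 * tsub[None, :])
            series = np.sum(n[:, None] * np.sin(np.pi * (a - zsub)[None, :] * n[:, None] / a) * decay, axis=0)
        contrib = (np.pi / a**2) * series
        good = contrib > 0
        res = np.zeros(tsub.shape)
        with np.errstate(under="ignore"):
            res[good] = np.exp(lnpre[large][good] + np.log(contrib[good]))
        vals[large] = res

    out[pos] = vals.reshape(t[pos].shape)
    return out


def density_basic(t, params: ParameterSet, threshold: str = "upper",
                  eps: float = _EPS_DEFAULT):
    """Density of the basic model (variabilities ignored) at one threshold.

    The lower-threshold density follows from the reflection map
    ``v -> -v``, ``z -> a - z``.  Defined as 0 for ``t <= 0``.
    """
    p = rescale_parameters(params, 1.0)
    v, a, zr = p.v, p.a, p.zr
    if threshold == "lower":
        v, zr = -v, 1.0 - zr
    elif threshold != "upper":
        raise ValueError(f"threshold must be 'upper' or 'lower', got {threshold!r}")
    t_arr = np.asarray(t, float)
    res = _g_upper(t_arr, zr * a, a, v, eps)
    return float(res) if t_arr.ndim == 0 else res


def density_sv(t, z, a: float, v: float, sv: float, eps: float = _EPS_DEFAULT):
    """Basic density mixed over a normal drift distribution, in closed form.

    Both series share the drift-dependent factor
    ``exp[(a-z) v - v^2 t / 2]``; mixing over ``v' ~ N(v, sv^2)`` is a
    Gaussian integral of that factor::

        g'(t) = g0(t) / sqrt(1 + sv^2 t)
                * exp[ ((a-z)^2 sv^2 + 2 v (a-z) - v^2 t) / (2 (1 + sv^2 t)) ]

    where ``g0`` is the zero-drift density.  Reduces exactly to the basic
    density when ``sv = 0``.
    """
    if sv < 0:
        raise ValueError("sv must be nonnegative")
    t_in = np.asarray(t, float)
    scalar = t_in.ndim == 0 and np.asarray(z, float).ndim == 0
    t_b, z_b = np.broadcast_arrays(np.atleast_1d(t_in), np.asarray(z, float))
    if sv == 0.0:
        out = _g_upper(t_b, z_b, a, v, eps)
        return float(out.ravel()[0]) if scalar else out.reshape(np.broadcast(t_in, np.asarray(z)).shape)
    out = np.zeros(t_b.shape, float)
    pos = t_b > 0
    if pos.any():
        tt = t_b[pos]
        zz = z_b[pos]
        m = _g_upper(tt, zz, a, 0.0, eps)
        denom = 1.0 + sv * sv * tt
        expo = ((a - zz) ** 2 * sv * sv + 2.0 * v * (a - zz) - v * v * tt) / (2.0 * denom)
        good = m > 0
        vals = np.zeros(tt.shape)
        with np.errstate(under="ignore"):
            vals[good] = np.exp(np.log(m[good]) + expo[good] - 0.5 * np.log(denom[good]))
        out[pos] = vals
    return float(out.ravel()[0]) if scalar else out.reshape(np.broadcast(t_in, np.asarray(z)).shape)


def density_full(t_rt, params: ParameterSet, threshold: str = "upper",
                 precision=3.0):
    """Full-model density of *response times* at one threshold.

    Subtracts the threshold-specific non-decision time
    (``t0 -/+ d/2`` for upper/lower), applies the analytic drift mixture,
    and averages over the uniform starting-point and non-decision-time
    windows with the midpoint rule (at least four steps each, controlled
    by ``precision``).  Returns 0 wherever every realized non-decision
    time exceeds the response time.
    """
    prec = PrecisionSettings.coerce(precision)
    p = rescale_parameters(params, 1.0)
    v, a, zr, d = p.v, p.a, p.zr, p.d
    if threshold == "lower":
        v, zr, d = -v, 1.0 - zr, -d
    elif threshold != "upper":
        raise ValueError(f"threshold must be 'upper' or 'lower', got {threshold!r}")
    t0_thr = p.t0 - 0.5 * d

    m = prec.n_integration_steps
    if p.szr > 0:
        k = np.arange(1, m + 1)
        zr_nodes = zr - 0.5 * p.szr + p.szr * (k - 0.5) / m
    else:
        zr_nodes = np.array([zr])
    if p.st0 > 0:
        k = np.arange(1, m + 1)
        offsets = -0.5 * p.st0 + p.st0 * (k - 0.5) / m
    else:
        offsets = np.array([0.0])

    t_in = np.asarray(t_rt, float)
    scalar = t_in.ndim == 0
    t_arr = np.atleast_1d(t_in)
    # axes: (z-node, t0-node, time)
    tdec = t_arr[None, None, :] - t0_thr - offsets[None, :, None]
    zgrid = (zr_nodes * a)[:, None, None]
    g = density_sv(np.broadcast_to(tdec, (len(zr_nodes), len(offsets), t_arr.size)),
                   zgrid, a, v, p.sv, prec.eps_series)
    out = g.mean(axis=(0, 1))
    return float(out[0]) if scalar else out.reshape(t_in.shape)
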