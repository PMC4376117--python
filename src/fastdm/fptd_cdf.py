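"""Predicted cumulative distributions via the backward Kolmogorov PDE.

The probability ``F+(t, z)`` that a diffusion started at ``z`` has been
absorbed at the upper threshold by time ``t`` solves

    dF/dt = 1/2 d2F/dz2 + v dF/dz,   F(t, 0) = 0,  F(t, a) = 1,

with the discontinuous initial condition ``F(0, z) = 0`` for ``z < a``
and ``F(0, a) = 1``.  The solver discretizes ``z`` with second-order
central differences and steps in time with Crank-Nicolson; the first few
steps use backward Euler to damp the oscillations that Crank-Nicolson
would otherwise excite from the discontinuous initial data (Rannacher
start-up).  The lower-threshold CDF solves the same equation with the
boundary values swapped, so one pass produces both; time stepping stops
once the probability mass still inside the corridor falls below the
precision target.

One PDE solution carries every starting point at once, so the uniform
starting-point mixture costs only column averaging.  Normal drift
variability enters through Gauss-Hermite nodes (one PDE solution per
node) and the uniform non-decision-time window through midpoint shifts
along the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConvergenceError
from .model_core import ParameterSet, PrecisionSettings, rescale_parameters

__all__ = ["PdeGrid", "PredictedDistribution", "solve_pde_cdf", "cdf_full", "combined_cdf"]


@dataclass(frozen=True)
class PdeGrid:
    """Finite-difference solution ``F(t_i, z_j)`` of the absorption CDF."""

    t: np.ndarray
    z: np.ndarray
    F: np.ndarray  # shape (len(t), len(z))


def _operator(v: float, dz: float, n_int: int):
    """Tridiagonal coefficients of L = 1/2 d2/dz2 + v d/dz (interior)."""
    alpha = 0.5 / dz**2
    beta = v / (2.0 * dz)
    return alpha - beta, -2.0 * alpha, alpha + beta


def _banded(lo, di, up, c: float, n_int: int):
    """Matrix I - c*L in solve_banded layout."""
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -c * up
    ab[1, :] = 1.0 - c * di
    ab[2, :-1] = -c * lo
    return ab


def _solve_pair(v: float, a: float, precision: float):
    """Solve for upper- and lower-absorption CDFs on a shared grid.

    Returns ``(t, z, F_up, F_lo)``; stepping continues until the survival
    probability ``1 - F_up - F_lo`` is below the residual target at every
    starting point.
    """
    prec = PrecisionSettings(precision)
    nz = prec.n_z_steps(a)
    dz = a / nz
    dt = 0.1 * a * dz
    n_int = nz - 1
    z = np.linspace(0.0, a, nz + 1)
    lo, di, up = _operator(v, dz, n_int)

    f_up = np.zeros(n_int)
    f_lo = np.zeros(n_int)
    b_up = np.zeros(n_int)
    b_up[-1] = up  # F(t, a) = 1 feeds the last interior point
    b_lo = np.zeros(n_int)
    b_lo[0] = lo  # F(t, 0) = 1 for the lower-absorption problem

    def be_substep(f, b, h, ab):
        return solve_banded((1, 1), ab, f + h * b)

    def cn_substep(f, b, h, ab):
        r = f + 0.5 * h * (di * f)
        r[:-1] += 0.5 * h * up * f[1:]
        r[1:] += 0.5 * h * lo * f[:-1]
        return solve_banded((1, 1), ab, r + h * b)

    rows_up = [np.concatenate(([0.0], f_up, [1.0]))]
    rows_lo = [np.concatenate(([1.0], f_lo, [0.0]))]
    target = prec.cdf_residual_target
    t_cap = 200.0 * a * a + 10.0
    n_cap = int(np.ceil(t_cap / dt))

    # the discontinuous initial condition needs damping and a fine start:
    # the first output step is taken as backward-Euler substeps, the next
    # few as refined Crank-Nicolson substeps, before full steps take over
    schedule = {1: ("be", 16), 2: ("cn", 8), 3: ("cn", 4), 4: ("cn", 2)}
    ab_cache: dict[tuple, np.ndarray] = {}

    def get_ab(c):
        if c not in ab_cache:
            ab_cache[c] = _banded(lo, di, up, c, n_int)
        return ab_cache[c]

    step = 0
    residual = 1.0
    while step < n_cap:
        step += 1
        kind, n_sub = schedule.get(step, ("cn", 1))
        h = dt / n_sub
        if kind == "be":
            ab = get_ab(h)
            for _ in range(n_sub):
                f_up = be_substep(f_up, b_up, h, ab)
                f_lo = be_substep(f_lo, b_lo, h, ab)
        else:
            ab = get_ab(0.5 * h)
            for _ in range(n_sub):
                f_up = cn_substep(f_up, b_up, h, ab)
                f_lo = cn_substep(f_lo, b_lo, h, ab)
        rows_up.append(np.concatenate(([0.0], f_up, [1.0])))
        rows_lo.append(np.concatenate(([1.0], f_lo, [0.0])))
        residual = float(np.max(1.0 - f_up - f_lo))
        if residual < target:
            break
    else:
        raise ConvergenceError(
            f"absorption CDF did not account for all probability mass by "
            f"t = {t_cap:.1f} s (residual {residual:.2e})",
            residual=residual,
        )
    t = np.arange(len(rows_up)) * dt
    return t, z, np.asarray(rows_up), np.asarray(rows_lo)


@lru_cache(maxsize=128)
def _pde_pair_cached(v: float, a: float, precision: float):
    t, z, f_up, f_lo = _solve_pair(v, a, precision)
    for arr in (t, z, f_up, f_lo):
        arr.setflags(write=False)
    return t, z, f_up, f_lo


def solve_pde_cdf(params_basic: ParameterSet, t_max: float | None = None,
                  precision=3.0) -> PdeGrid:
    """Upper-threshold CDF of the basic model on a full (t, z) grid.

    Reading off the column at ``z = zr * a`` gives the upper-threshold
    CDF of the model; the grid extends until the unaccounted probability
    mass drops below the precision target (or to ``t_max`` if that is
    shorter).  Raises :class:`ConvergenceError` if mass remains
    unaccounted at the safety cap.
    """
    prec = PrecisionSettings.coerce(precision)
    p = rescale_parameters(params_basic, 1.0)
    t, z, f_up, _ = _pde_pair_cached(p.v, p.a, prec.precision)
    if t_max is not None and t_max < t[-1]:
        keep = t <= t_max
        return PdeGrid(t[keep], z, f_up[keep])
    return PdeGrid(t, z, f_up)


def _column_average(t, z, F, zr: float, szr: float, a: float, n_steps: int):
    """Average PDE columns over the uniform starting-point window."""
    if szr > 0:
        k = np.arange(1, n_steps + 1)
        z_nodes = (zr - 0.5 * szr + szr * (k - 0.5) / n_steps) * a
    else:
        z_nodes = np.array([zr * a])
    cols = np.empty((len(t), len(z_nodes)))
    for j, zv in enumerate(z_nodes):
        i = np.searchsorted(z, zv) - 1
        i = min(max(i, 0), len(z) - 2)
        w = (zv - z[i]) / (z[i + 1] - z[i])
        cols[:, j] = (1.0 - w) * F[:, i] + w * F[:, i + 1]
    return cols.mean(axis=1)


def _basic_cdf_interp(v, a, zr, szr, precision, prec: PrecisionSettings,
                      side: str):
    """(t_grid, F_grid) of the szr-averaged basic CDF at one threshold.

    One PDE pass carries both absorption problems, so either side is a
    column average of an already-cached grid.
    """
    t, z, f_up, f_lo = _pde_pair_cached(v, a, precision)
    F = f_up if side == "upper" else f_lo
    return t, _column_average(t, z, F, zr, szr, a, prec.n_integration_steps)


def cdf_full(t_rt, params: ParameterSet, threshold: str = "upper",
             precision=3.0):
    """Full-model CDF of response times at one threshold.

    ``cdf_full(np.inf, ...)`` gives the total response probability at the
    threshold.
    """
    prec = PrecisionSettings.coerce(precision)
    p = rescale_parameters(params, 1.0)
    if threshold not in ("upper", "lower"):
        raise ValueError(f"threshold must be 'upper' or 'lower', got {threshold!r}")
    a = p.a
    t0_thr = p.t0 - 0.5 * p.d if threshold == "upper" else p.t0 + 0.5 * p.d

    if p.sv > 0:
        x, w = np.polynomial.hermite.hermgauss(prec.n_hermite)
        drifts = p.v + np.sqrt(2.0) * p.sv * x
        weights = w / np.sqrt(np.pi)
    else:
        drifts = np.array([p.v])
        weights = np.array([1.0])

    grids = [_basic_cdf_interp(dv, a, p.zr, p.szr, prec.precision, prec,
                               threshold) for dv in drifts]

    m = prec.n_integration_steps
    if p.st0 > 0:
        k = np.arange(1, m + 1)
        offsets = -0.5 * p.st0 + p.st0 * (k - 0.5) / m
    else:
        offsets = np.array([0.0])

    t_in = np.asarray(t_rt, float)
    scalar = t_in.ndim == 0
    t_arr = np.atleast_1d(t_in).ravel()
    tdec = t_arr[None, :] - t0_thr - offsets[:, None]  # (n_t0, n)
    out = np.zeros(tdec.shape)
    for wgt, (tg, fg) in zip(weights, grids):
        out += wgt * np.interp(tdec, tg, fg, left=0.0, right=fg[-1])
    res = out.mean(axis=0)
    if scalar:
        return float(res[0])
    return res.reshape(t_in.shape)


@dataclass
class PredictedDistribution:
    """Combined CDF over signed response times.

    Lower-threshold response times carry a negative sign, so both
    response distributions merge into one monotone cumulative function:
    ``G(tau) = P(lower and RT >= -tau)`` accumulated from below for
    ``tau < 0`` and ``P(lower) + P(upper and RT <= tau)`` for
    ``tau > 0``.  ``G`` equals ``P(lower)`` at the sign boundary.
    """

    signed_t: np.ndarray
    cdf: np.ndarray
    p_upper: float
    params: ParameterSet = field(repr=False, default=None)
    precision: float = 3.0

    def evaluate(self, tau):
        """Combined CDF at signed time(s) ``tau``."""
        return np.interp(tau, self.signed_t, self.cdf, left=0.0, right=float(self.cdf[-1]))

    def quantile(self, q):
        """Signed time(s) at which the combined CDF reaches ``q``."""
        cdf = self.cdf
        keep = np.concatenate(([True], np.diff(cdf) > 0))
        return np.interp(q, cdf[keep], self.signed_t[keep])


def combined_cdf(params: ParameterSet, precision=3.0,
                 n_grid: int = 2000) -> PredictedDistribution:
    """Predicted combined CDF of the full model on a signed-time grid."""
    prec = PrecisionSettings.coerce(precision)
    p = rescale_parameters(params, 1.0)

    # probe the basic-model grids to size the response-time axis
    if p.sv > 0:
        x, _ = np.polynomial.hermite.hermgauss(prec.n_hermite)
        probe_drifts = p.v + np.sqrt(2.0) * p.sv * x
    else:
        probe_drifts = [p.v]
    t_dec_end = 0.0
    for dv in probe_drifts:
        t_dec_end = max(t_dec_end, _pde_pair_cached(dv, p.a, prec.precision)[0][-1])

    pad = 0.5 * p.st0 + 0.5 * abs(p.d)
    t_lo = max(0.0, p.t0 - pad)
    t_hi = p.t0 + pad + t_dec_end
    t_grid = np.linspace(t_lo, t_hi, n_grid + 1)

    f_up = cdf_full(t_grid, p, "upper", prec)
    f_lo = cdf_full(t_grid, p, "lower", prec)
    p_up = float(cdf_full(np.inf, p, "upper", prec))
    p_lo = float(cdf_full(np.inf, p, "lower", prec))

    signed = np.concatenate((-t_grid[::-1], t_grid))
    values = np.concatenate(((p_lo - f_lo)[::-1], p_lo + f_up))
    # enforce monotonicity against rounding noise at the splice
    values = np.maximum.accumulate(values)
    return PredictedDistribution(signed, values, p_up, params=params,
                                 precision=prec.precision)
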